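"""Prediction-error fMRI regressors and a single-voxel GLM.

Feedback events are modeled as stick (delta) functions at their onsets on a
fine microtime grid; a parallel stick train carries the mean-centered
trial-wise prediction errors as parametric modulation. Both are convolved
with the canonical double-gamma hemodynamic response function and decimated
to the TR grid. The per-subject quantity carried to the group level is the
OLS coefficient of the PE-modulated regressor — the "BOLD PE signal": how
strongly a voxel's time series co-varies with the model's teaching signal.

The whole stage is a one-voxel abstraction: no volumes, smoothing or
cluster statistics — the group statistics only consume a per-subject scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ScanProtocol", "GlmResult", "canonical_hrf", "build_design",
    "build_session_designs", "simulate_bold", "fit_glm", "subject_pe_beta",
]

DESIGN_COLUMNS = ["onset", "pe_mod", "const"]


@dataclass(frozen=True)
class ScanProtocol:
    """EPI acquisition timing."""

    tr_s: float = 2.3
    n_volumes_per_session: int = 310
    n_sessions: int = 2
    microtime_resolution: int = 16

    def __post_init__(self) -> None:
        if min(self.tr_s, self.n_volumes_per_session,
               self.n_sessions, self.microtime_resolution) <= 0:
            raise ValueError("all protocol fields must be positive")

    @property
    def session_duration_s(self) -> float:
        return self.tr_s * self.n_volumes_per_session

    @property
    def dt(self) -> float:
        return self.tr_s / self.microtime_resolution


@dataclass(frozen=True)
class GlmResult:
    """Per-subject GLM estimates (sessions averaged).

    ``t_beta_pe`` is a naive OLS t-value: serial correlation in the noise is
    ignored, so the betas are unbiased but the t is optimistic under AR noise.
    """

    beta_pe: float
    beta_onset: float
    residual_variance: float
    t_beta_pe: float
    dof: int
    naive_t: bool = True


def canonical_hrf(
    tr_s: float, microtime_resolution: int = 16, duration_s: float = 32.0
) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the microtime grid.

    Difference of two gamma densities: a response peaking at 6 s and an
    undershoot peaking at 16 s scaled by 1/6, on a 32-s support. Normalized
    to unit peak, so an isolated unit-PE event produces a unit-height
    response and regression betas are in PE units.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    dt = tr_s / microtime_resolution
    t = np.arange(0.0, duration_s, dt)
    h = scipy.stats.gamma.pdf(t, 6.0) - scipy.stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def build_design(
    onsets: np.ndarray,
    pe: np.ndarray,
    protocol: ScanProtocol,
    center_pe: bool = True,
    nuisance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Design matrix for one session: onset, PE-modulated, constant columns.

    Sticks are placed at the feedback onsets on the microtime grid; the
    modulated sticks carry (by default mean-centered) PE values. Both are
    convolved with the canonical HRF and decimated to the TR grid. Optional
    ``nuisance`` columns (volumes x k) are appended as given.
    """
    onsets = np.asarray(onsets, dtype=float)
    pe = np.asarray(pe, dtype=float)
    if onsets.shape != pe.shape:
        raise ValueError("onsets and pe must align")
    bad = np.nonzero(onsets >= protocol.session_duration_s)[0]
    if bad.size:
        raise ValueError(
            f"trial {bad[0]} onset {onsets[bad[0]]:.2f}s is beyond the end of "
            f"the scan ({protocol.session_duration_s:.2f}s)"
        )
    if np.any(onsets < 0):
        raise ValueError("negative onset")

    mt = protocol.microtime_resolution
    n_fine = protocol.n_volumes_per_session * mt
    idx = np.floor(onsets / protocol.dt).astype(int)
    stick = np.zeros(n_fine)
    np.add.at(stick, idx, 1.0)
    mod = np.zeros(n_fine)
    pe_vals = pe - pe.mean() if center_pe else pe
    np.add.at(mod, idx, pe_vals)

    hrf = canonical_hrf(protocol.tr_s, mt)
    cols = {
        "onset": np.convolve(stick, hrf)[:n_fine][::mt],
        "pe_mod": np.convolve(mod, hrf)[:n_fine][::mt],
        "const": np.ones(protocol.n_volumes_per_session),
    }
    X = pd.DataFrame(cols, columns=DESIGN_COLUMNS)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != len(X):
            nuisance = nuisance.T
        for j in range(nuisance.shape[1]):
            X[f"nuis{j}"] = nuisance[:, j]
    return X


def build_session_designs(
    events: pd.DataFrame, pe: np.ndarray, protocol: ScanProtocol, center_pe: bool = True
) -> list[pd.DataFrame]:
    """Per-session designs from a subject's event table and PE sequence
    (mean-centering is applied within each session)."""
    pe = np.asarray(pe, dtype=float)
    if len(pe) != len(events):
        raise ValueError("PE sequence and events must align")
    designs = []
    for sess in sorted(events["session"].unique()):
        m = (events["session"] == sess).to_numpy()
        designs.append(build_design(
            events.loc[m, "onset_s"].to_numpy(), pe[m], protocol, center_pe=center_pe
        ))
    return designs


def simulate_bold(
    design: pd.DataFrame,
    signal_scale: float,
    noise_sd: float,
    ar1_coef: float,
    rng: np.random.Generator,
    baseline: float = 100.0,
) -> np.ndarray:
    """Forward model for one session: scaled PE regressor + baseline + AR(1) noise.

    The AR(1) innovation variance is set so the marginal noise SD equals
    ``noise_sd``; ``ar1_coef=0`` gives white noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not -1 < ar1_coef < 1:
        raise ValueError("ar1_coef must lie in (-1, 1)")
    n = len(design)
    signal = signal_scale * design["pe_mod"].to_numpy() + baseline
    if noise_sd == 0:
        return signal
    innov = rng.standard_normal(n) * noise_sd * np.sqrt(1.0 - ar1_coef**2)
    noise = np.empty(n)
    noise[0] = rng.standard_normal() * noise_sd
    for t in range(1, n):
        noise[t] = ar1_coef * noise[t - 1] + innov[t]
    return signal + noise


def _ols(y: np.ndarray, X: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid / dof)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, cov, s2, dof


def fit_glm(series, designs) -> GlmResult:
    """OLS fit of the PE design, one or more sessions.

    Each session is fitted separately; betas are averaged across sessions and
    the t-value of the PE beta uses the variance of the session mean.
    """
    if isinstance(designs, pd.DataFrame):
        designs = [designs]
        series = [np.asarray(series, dtype=float)]
    else:
        series = [np.asarray(s, dtype=float) for s in series]
    if len(series) != len(designs):
        raise ValueError("series/designs length mismatch")
    betas_pe, betas_on, var_pe, s2s, dofs = [], [], [], [], []
    for y, X in zip(series, designs):
        Xm = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else DESIGN_COLUMNS
        beta, cov, s2, dof = _ols(y, Xm)
        j_pe, j_on = cols.index("pe_mod"), cols.index("onset")
        betas_pe.append(beta[j_pe])
        betas_on.append(beta[j_on])
        var_pe.append(cov[j_pe, j_pe])
        s2s.append(s2)
        dofs.append(dof)
    k = len(betas_pe)
    beta_pe = float(np.mean(betas_pe))
    se = float(np.sqrt(np.sum(var_pe)) / k)
    return GlmResult(
        beta_pe=beta_pe,
        beta_onset=float(np.mean(betas_on)),
        residual_variance=float(np.mean(s2s)),
        t_beta_pe=beta_pe / se,
        dof=int(np.sum(dofs)),
    )


def subject_pe_beta(
    events: pd.DataFrame,
    pe: np.ndarray,
    series: list[np.ndarray],
    protocol: ScanProtocol,
    center_pe: bool = True,
) -> GlmResult:
    """Convenience: build per-session designs and fit the GLM in one call."""
    designs = build_session_designs(events, pe, protocol, center_pe=center_pe)
    return fit_glm(series, designs)
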