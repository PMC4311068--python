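"""Hierarchical (empirical-Bayes) estimation of Rescorla-Wagner parameters.

Per-subject parameters are estimated as maximum-a-posteriori (MAP) values in
the unconstrained space theta = (logit eps, log beta_rew, log beta_pun) under
a Gaussian population prior N(mu, Sigma). The prior itself is set empirically
by expectation-maximization over the whole cohort:

  E-step  theta_i = argmax_theta  log p(A_i | theta) + log N(theta; mu, Sigma)
          with a Laplace (inverse-Hessian) approximation to each subject's
          posterior covariance;
  M-step  mu    <- mean_i theta_i
          Sigma <- mean_i [ (theta_i - mu)(theta_i - mu)^T + H_i^{-1} ].

Treating subjects as draws from the population shrinks noisy individual
estimates toward the group, the standard random-effects compromise between
independent per-subject fits and one shared parameter vector.

The module exposes a statsmodels-style surface: ``RescorlaWagnerModel`` /
``HierarchicalRWModel`` are built from event tables and their ``fit()``
returns results objects carrying estimates, uncertainties and ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from . import rw
from .rw import AgentParams, PETrace

__all__ = [
    "PopulationPrior", "SubjectFit", "FitError",
    "map_fit_subject", "em_fit_population", "compute_pe_sequences",
    "RescorlaWagnerModel", "HierarchicalRWModel", "HierarchicalRWResults",
]

#: broad default EM initialization in transformed space
DEFAULT_INIT_MU = np.zeros(3)
DEFAULT_INIT_SIGMA = 6.25 * np.eye(3)
PARAM_NAMES = ("eps_prime", "log_beta_rew", "log_beta_pun")


class FitError(RuntimeError):
    pass


@dataclass
class PopulationPrior:
    """Gaussian population prior over transformed parameters."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ValueError("sigma must be positive definite")
        self._chol = scipy.linalg.cho_factor(self.sigma, lower=True)
        self._logdet = 2.0 * np.sum(np.log(np.diag(self._chol[0])))

    @classmethod
    def broad(cls, scale: float = 1e6) -> "PopulationPrior":
        """Near-flat prior: MAP under it is essentially the MLE."""
        return cls(np.zeros(3), scale * np.eye(3))

    def logpdf(self, theta: np.ndarray) -> float:
        d = np.asarray(theta, dtype=float) - self.mu
        sol = scipy.linalg.cho_solve(self._chol, d)
        return float(-0.5 * (d @ sol + self._logdet + 3 * np.log(2 * np.pi)))

    def grad_logpdf(self, theta: np.ndarray) -> np.ndarray:
        d = np.asarray(theta, dtype=float) - self.mu
        return -scipy.linalg.cho_solve(self._chol, d)

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        return rng.multivariate_normal(self.mu, self.sigma, size=n)

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {"mu": self.mu.tolist(), "sigma": self.sigma.tolist(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationPrior":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mu"]), np.array(d["sigma"]))


@dataclass
class SubjectFit:
    """One subject's MAP fit and local curvature."""

    subject: str
    theta_map: np.ndarray
    params: AgentParams
    loglik: float                 # data log-likelihood term at theta_map
    log_posterior: float          # loglik + log prior at theta_map
    hessian: np.ndarray           # curvature of the negative log posterior
    grad_norm: float
    n_trials: int

    @property
    def laplace_cov(self) -> np.ndarray:
        return np.linalg.inv(self.hessian)


def _neg_log_posterior(theta, actions, outcomes, prior):
    ll, g = rw.loglik_and_grad(actions, outcomes, theta)
    lp = prior.logpdf(theta)
    gp = prior.grad_logpdf(theta)
    return -(ll + lp), -(g + gp)


def _numeric_hessian(f_grad, theta, h=1e-4):
    """Central finite differences of the (analytic) gradient; symmetrized."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (f_grad(tp) - f_grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def _ensure_pd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w = np.linalg.eigvalsh(mat)
    if w.min() <= floor:
        mat = mat + (floor - w.min() + 1e-8) * np.eye(mat.shape[0])
    return mat


def map_fit_subject(
    events,
    prior: PopulationPrior,
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
    subject: str = "s0",
    gtol: float = 1e-6,
) -> SubjectFit:
    """MAP estimate of one subject's transformed parameters.

    Runs L-BFGS-B from the prior mean, ``x0`` if given, and ``n_restarts - 1``
    draws from the prior (RL likelihoods can be multimodal); keeps the best
    optimum. The Hessian of the negative log posterior is taken by finite
    differences of the analytic gradient and floored to positive definite.
    """
    if isinstance(events, pd.DataFrame):
        actions, outcomes = rw.actions_outcomes(events)
    else:
        actions, outcomes = np.asarray(events[0], int), np.asarray(events[1], int)
    if len(actions) == 0:
        raise ValueError("no trials to fit")
    if len(actions) < 20:
        warnings.warn(f"subject {subject}: only {len(actions)} trials; "
                      "estimates will lean heavily on the prior")
    rng = rng or np.random.default_rng(0)

    starts = [prior.mu.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    while len(starts) < max(n_restarts, 1):
        starts.append(prior.sample(rng))

    best = None
    failures = []
    for s in starts:
        res = scipy.optimize.minimize(
            _neg_log_posterior, np.clip(s, -24.0, 24.0),
            args=(actions, outcomes, prior),
            jac=True, method="L-BFGS-B", bounds=[(-25.0, 25.0)] * 3,
            options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
        )
        if not np.all(np.isfinite(res.x)):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"subject {subject}: all restarts failed: {failures}")

    theta = best.x
    _, g = _neg_log_posterior(theta, actions, outcomes, prior)
    H = _numeric_hessian(
        lambda t: _neg_log_posterior(t, actions, outcomes, prior)[1], theta
    )
    H = _ensure_pd(H)
    ll, _ = rw.loglik_and_grad(actions, outcomes, theta)
    return SubjectFit(
        subject=subject,
        theta_map=theta,
        params=rw.from_theta(theta),
        loglik=float(ll),
        log_posterior=float(ll + prior.logpdf(theta)),
        hessian=H,
        grad_norm=float(np.linalg.norm(g)),
        n_trials=len(actions),
    )


def em_fit_population(
    all_events: Sequence,
    init: PopulationPrior | None = None,
    max_iter: int = 100,
    tol: float = 1e-3,
    n_restarts: int = 5,
    diagonal: bool = True,
    rng: np.random.Generator | None = None,
    subject_ids: Sequence[str] | None = None,
) -> tuple[PopulationPrior, list[SubjectFit], dict]:
    """Laplace-approximation EM for the population prior.

    Alternates per-subject MAP fits (E-step, with Laplace posterior
    covariances) and moment updates of (mu, Sigma) (M-step). Stops when the
    largest absolute change in mu and Sigma entries drops below ``tol`` or
    after ``max_iter`` iterations. Restarts are used in the first E-step;
    later E-steps warm-start from the previous optimum.

    Returns ``(prior, fits, info)`` where ``info`` records the penalized
    objective trace (sum over subjects of log-posterior at the current
    prior), iteration count and convergence flag.
    """
    if len(all_events) < 2:
        raise ValueError("EM needs at least 2 subjects")
    prior = init or PopulationPrior(DEFAULT_INIT_MU.copy(), DEFAULT_INIT_SIGMA.copy())
    rng = rng or np.random.default_rng(0)
    ids = list(subject_ids) if subject_ids is not None else [
        f"s{i:03d}" for i in range(len(all_events))
    ]

    fits: list[SubjectFit] = []
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        warm = [f.theta_map for f in fits] if fits else [None] * len(all_events)
        fits = [
            map_fit_subject(
                ev, prior,
                n_restarts=n_restarts if it == 1 else 2,
                rng=rng, x0=w, subject=sid,
            )
            for ev, w, sid in zip(all_events, warm, ids)
        ]
        trace.append(sum(f.log_posterior for f in fits))

        thetas = np.array([f.theta_map for f in fits])
        mu_new = thetas.mean(axis=0)
        dev = thetas - mu_new
        sigma_new = (
            dev.T @ dev + sum(f.laplace_cov for f in fits)
        ) / len(fits)
        if diagonal:
            sigma_new = np.diag(np.diag(sigma_new))
        w = np.linalg.eigvalsh(sigma_new)
        if w.min() <= 1e-8:
            warnings.warn("non-PD Sigma update; adding diagonal jitter")
            sigma_new = _ensure_pd(sigma_new)

        delta = max(
            np.abs(mu_new - prior.mu).max(),
            np.abs(sigma_new - prior.sigma).max(),
        )
        prior = PopulationPrior(mu_new, sigma_new)
        if not np.all(np.isfinite(mu_new)) or not np.all(np.isfinite(sigma_new)):
            raise FitError("EM diverged: non-finite prior update")
        if delta < tol:
            converged = True
            break

    info = {"em_iterations": it, "converged": converged, "objective_trace": trace}
    return prior, fits, info


def compute_pe_sequences(fits: Sequence[SubjectFit], all_events: Sequence) -> list[PETrace]:
    """Trial-wise PE traces at each subject's MAP parameters."""
    if len(fits) != len(all_events):
        raise ValueError("fits and event tables are misaligned")
    traces = []
    for f, ev in zip(fits, all_events):
        if isinstance(ev, pd.DataFrame) and "subject" in ev.columns:
            sid = str(ev["subject"].iloc[0])
            if sid != f.subject:
                raise ValueError(f"subject id mismatch: fit {f.subject} vs events {sid}")
        _, trace = rw.sequence_loglik(ev, f.params)
        traces.append(trace)
    return traces


def _quartile_summary(fits: Sequence[SubjectFit]) -> pd.DataFrame:
    """Cohort quartiles of the natural-space estimates.

    Column labels follow the usual reporting convention for these fits: the
    punishment column is labeled "-beta_pun" because punishment enters the
    effective reinforcement negatively, but it carries the positive magnitude
    of the sensitivity; LL is the magnitude of the choice log-likelihood.
    """
    tab = pd.DataFrame({
        "beta_rew": [f.params.beta_rew for f in fits],
        "-beta_pun": [f.params.beta_pun for f in fits],
        "LL": [abs(f.loglik) for f in fits],
        "epsilon": [f.params.epsilon for f in fits],
    })
    out = tab.quantile([0.25, 0.5, 0.75])
    out.index = ["25th percentile", "Median", "75th percentile"]
    return out


class RescorlaWagnerModel:
    """Single-subject RW/softmax model built from an event table."""

    def __init__(self, events: pd.DataFrame, subject: str = "s0"):
        self.events = events
        self.subject = subject

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RescorlaWagnerModel":
        from . import task
        return cls(task.read_events(path), subject=Path(path).stem)

    def loglik(self, params: AgentParams) -> float:
        return rw.sequence_loglik(self.events, params)[0]

    def fit(
        self,
        prior: PopulationPrior | None = None,
        seed: int = 0,
        n_restarts: int = 5,
    ) -> SubjectFit:
        """MAP fit (near-flat prior by default, i.e. a regularized MLE)."""
        prior = prior or PopulationPrior.broad()
        return map_fit_subject(
            self.events, prior, n_restarts=n_restarts,
            rng=np.random.default_rng(seed), subject=self.subject,
        )


class HierarchicalRWModel:
    """Cohort-level RW model with an empirical (EM-estimated) Gaussian prior."""

    def __init__(self, events_by_subject: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]):
        if isinstance(events_by_subject, Mapping):
            self.subject_ids = list(events_by_subject)
            self.events = [events_by_subject[k] for k in self.subject_ids]
        else:
            self.events = list(events_by_subject)
            self.subject_ids = [f"s{i:03d}" for i in range(len(self.events))]

    @classmethod
    def from_directory(cls, path: str | Path, pattern: str = "*.tsv") -> "HierarchicalRWModel":
        from . import task
        files = sorted(Path(path).glob(pattern))
        if not files:
            raise FileNotFoundError(f"no event files matching {pattern} in {path}")
        return cls({f.stem: task.read_events(f) for f in files})

    def fit(
        self,
        seed: int = 0,
        method: str = "em",
        prior: PopulationPrior | None = None,
        max_iter: int = 100,
        tol: float = 1e-3,
        n_restarts: int = 5,
        diagonal: bool = True,
    ) -> "HierarchicalRWResults":
        """Fit the cohort.

        ``method="em"`` runs the full empirical-Bayes EM; ``method="map"``
        performs one E-step under a fixed prior (near-flat by default),
        i.e. independent per-subject fits.
        """
        rng = np.random.default_rng(seed)
        if method == "em":
            pri, fits, info = em_fit_population(
                self.events, init=prior, max_iter=max_iter, tol=tol,
                n_restarts=n_restarts, diagonal=diagonal, rng=rng,
                subject_ids=self.subject_ids,
            )
        elif method == "map":
            pri = prior or PopulationPrior.broad()
            fits = [
                map_fit_subject(ev, pri, n_restarts=n_restarts, rng=rng, subject=sid)
                for ev, sid in zip(self.events, self.subject_ids)
            ]
            info = {"em_iterations": 0, "converged": True,
                    "objective_trace": [sum(f.log_posterior for f in fits)]}
        else:
            raise ValueError(f"unknown method {method!r}")
        return HierarchicalRWResults(self, pri, fits, info)


class HierarchicalRWResults:
    """Estimates, prior, and diagnostics from a cohort fit."""

    def __init__(self, model, prior, fits, info):
        self.model = model
        self.prior = prior
        self.fits: list[SubjectFit] = fits
        self.em_iterations: int = info["em_iterations"]
        self.converged: bool = info["converged"]
        self.objective_trace: list[float] = info["objective_trace"]

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([f.params.epsilon for f in self.fits])

    @property
    def beta_rews(self) -> np.ndarray:
        return np.array([f.params.beta_rew for f in self.fits])

    @property
    def beta_puns(self) -> np.ndarray:
        return np.array([f.params.beta_pun for f in self.fits])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([f.theta_map for f in self.fits])

    def summary_frame(self) -> pd.DataFrame:
        return _quartile_summary(self.fits)

    def summary(self) -> str:
        head = (
            f"Hierarchical Rescorla-Wagner fit: {len(self.fits)} subjects, "
            f"EM iterations={self.em_iterations}, converged={self.converged}\n"
            f"prior mu = {np.array2string(self.prior.mu, precision=3)}\n"
            f"prior sigma diag = "
            f"{np.array2string(np.diag(self.prior.sigma), precision=3)}\n\n"
        )
        return head + self.summary_frame().to_string(float_format="%.2f")

    def pe_traces(self) -> list[PETrace]:
        return compute_pe_sequences(self.fits, self.model.events)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "subject": [f.subject for f in self.fits],
            "epsilon": self.epsilons,
            "beta_rew": self.beta_rews,
            "beta_pun": self.beta_puns,
            "neg_loglik": [-f.loglik for f in self.fits],
            "n_trials": [f.n_trials for f in self.fits],
        }).to_csv(path, index=False, float_format="%.8g")

    def prior_to_json(self, path: str | Path) -> None:
        self.prior.to_json(
            path, em_iterations=self.em_iterations, converged=self.converged
        )
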