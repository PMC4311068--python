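"""Group-level moderation statistics.

Tests whether chronic life stress (SLES, a 0-42 count of stressful life
events) moderates the association between the per-subject BOLD PE signal
(``pe_beta``) and fluid IQ. The regression is hierarchical two-step entry:

  step 1   fluid_iq ~ pe_beta + sles_code            (R^2 base)
  step 2   fluid_iq ~ pe_beta + sles_code + pe_beta*sles_code   (R^2 full)

with SLES coded either by median split (below-or-at median -> 1, above -> 2)
or as a continuous z-score. The added interaction term is judged by the
F-change test

  F = ((R^2_full - R^2_base)/q) / ((1 - R^2_full)/(n - k - 1)),

and influence is screened with Cook's distance (< 1) and standardized
residuals (|z| < 3); flagged points are reported, never dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "pearson_r", "median_split_code", "moderation_regression", "subgroup_r2",
    "ModerationModel", "ModerationResults",
]

COHORT_COLUMNS = ["subject", "sles", "fluid_iq", "age", "pe_beta"]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two aligned samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def median_split_code(sles) -> np.ndarray:
    """Dichotomize SLES at the sample median: low group 1, high group 2.

    Values exactly at the median go to the low group. A degenerate split
    (everyone equal) returns all ones with a warning.
    """
    sles = np.asarray(sles, dtype=float)
    if len(sles) < 2:
        raise ValueError("need at least 2 subjects to split")
    med = np.median(sles)
    code = np.where(sles > med, 2, 1)
    if len(np.unique(code)) == 1:
        warnings.warn("degenerate median split: all subjects in one group")
    return code


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the first column that adds no rank
        for j in range(1, arr.shape[1] + 1):
            if np.linalg.matrix_rank(arr[:, :j]) < j:
                raise ValueError(
                    f"collinear predictors: column {X.columns[j - 1]!r} is "
                    "linearly dependent on the preceding columns"
                )


def _standardized(params: pd.Series, X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """SPSS-style standardized coefficients b_j * sd(X_j) / sd(y)."""
    sy = np.std(y, ddof=1)
    out = {}
    for name in X.columns:
        if name == "const":
            continue
        out[name] = params[name] * np.std(X[name].to_numpy(), ddof=1) / sy
    return pd.Series(out)


@dataclass
class ModerationResults:
    """Two-step moderation fit: coefficients, fit statistics, influence."""

    coding: str
    n: int
    params: pd.Series               # unstandardized, full model (incl. const)
    std_params: pd.Series           # standardized betas, full model
    tvalues: pd.Series              # full model
    pvalues: pd.Series
    r2_base: float
    r2_full: float
    f_change: float
    f_change_p: float
    f_change_df: tuple[int, int]
    cooks_distance: np.ndarray
    resid_z: np.ndarray
    base_params: pd.Series = field(repr=False, default=None)
    base_std_params: pd.Series = field(repr=False, default=None)
    base_tvalues: pd.Series = field(repr=False, default=None)

    @property
    def influence_flags(self) -> np.ndarray:
        return (self.cooks_distance >= 1.0) | (np.abs(self.resid_z) >= 3.0)

    def summary(self) -> str:
        lines = [
            f"Moderation regression (coding={self.coding}, n={self.n})",
            f"step 1  R^2 = {self.r2_base:.3f}",
            f"step 2  R^2 = {self.r2_full:.3f}   "
            f"F-change({self.f_change_df[0]}, {self.f_change_df[1]}) = "
            f"{self.f_change:.2f}, p = {self.f_change_p:.4f}",
            "",
            "full model (standardized beta, t, p):",
        ]
        for name in self.std_params.index:
            lines.append(
                f"  {name:<16s} beta = {self.std_params[name]:6.2f}   "
                f"T = {self.tvalues[name]:5.2f}   p = {self.pvalues[name]:.4f}"
            )
        lines.append(
            f"influence: max Cook's D = {self.cooks_distance.max():.3f}, "
            f"max |z| = {np.abs(self.resid_z).max():.2f}, "
            f"{int(self.influence_flags.sum())} flagged"
        )
        return "\n".join(lines)

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.std_params.index,
            "beta_std": self.std_params.values,
            "b": [self.params[t] for t in self.std_params.index],
            "t": [self.tvalues[t] for t in self.std_params.index],
            "p": [self.pvalues[t] for t in self.std_params.index],
        })

    def to_json_dict(self) -> dict:
        return {
            "coding": self.coding,
            "n": self.n,
            "r2_base": self.r2_base,
            "r2_full": self.r2_full,
            "f_change": self.f_change,
            "f_change_p": self.f_change_p,
            "std_params": self.std_params.to_dict(),
            "tvalues": {k: self.tvalues[k] for k in self.std_params.index},
            "max_cooks_distance": float(self.cooks_distance.max()),
            "max_abs_resid_z": float(np.abs(self.resid_z).max()),
        }

    def plot_subgroups(self, cohort: pd.DataFrame, ax=None):
        """Fluid IQ against the PE beta, split at the SLES median, with
        per-subgroup least-squares lines and R^2 labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        split = median_split_code(cohort["sles"])
        styles = {1: dict(marker="o", color="tab:blue", alpha=0.5, label="low SLES"),
                  2: dict(marker="^", color="tab:red", label="high SLES")}
        for g, st in styles.items():
            sub = cohort[split == g]
            ax.scatter(sub["pe_beta"], sub["fluid_iq"], **st)
            if len(sub) >= 3 and sub["pe_beta"].std() > 0:
                b, a = np.polyfit(sub["pe_beta"], sub["fluid_iq"], 1)
                xx = np.linspace(sub["pe_beta"].min(), sub["pe_beta"].max(), 2)
                r2 = pearson_r(sub["pe_beta"], sub["fluid_iq"])[0] ** 2
                ax.plot(xx, a + b * xx, color=st["color"],
                        label=f"{st['label']} fit (R$^2$={r2:.2f})")
        ax.set_xlabel("BOLD PE signal (beta)")
        ax.set_ylabel("fluid IQ (z)")
        ax.legend()
        return ax


class ModerationModel:
    """Two-step (hierarchical-entry) moderation regression of fluid IQ.

    ``coding="median_split"`` uses the dichotomous 1/2 SLES code;
    ``coding="continuous_z"`` uses z-scored SLES. The interaction multiplies
    the SLES code with the raw (uncentered) PE beta; ``center_pe=True``
    centers it first. ``age_covariate`` adds age to both steps.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        coding: str = "median_split",
        age_covariate: bool = False,
        center_pe: bool = False,
    ):
        if coding not in ("median_split", "continuous_z"):
            raise ValueError(f"unknown sles coding {coding!r}")
        required = {"sles", "fluid_iq", "pe_beta"} | ({"age"} if age_covariate else set())
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        cohort = cohort.dropna(subset=sorted(required))
        if len(cohort) < 4:
            raise ValueError("need at least 4 complete subjects")
        self.cohort = cohort.reset_index(drop=True)
        self.coding = coding
        self.age_covariate = age_covariate
        self.center_pe = center_pe

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ModerationModel":
        return cls(pd.read_csv(path), **kwargs)

    def _design(self) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
        c = self.cohort
        if self.coding == "median_split":
            code = median_split_code(c["sles"]).astype(float)
        else:
            code = scipy.stats.zscore(c["sles"].to_numpy(dtype=float), ddof=1)
        pe = c["pe_beta"].to_numpy(dtype=float)
        pe_int = pe - pe.mean() if self.center_pe else pe
        X1 = pd.DataFrame({"const": 1.0, "pe_beta": pe, "sles_code": code})
        if self.age_covariate:
            X1["age"] = c["age"].to_numpy(dtype=float)
        X2 = X1.copy()
        X2["pe_x_sles"] = pe_int * code
        y = c["fluid_iq"].to_numpy(dtype=float)
        return X1, X2, y

    def fit(self) -> ModerationResults:
        X1, X2, y = self._design()
        _check_full_rank(X2)
        m1 = sm.OLS(y, X1).fit()
        m2 = sm.OLS(y, X2).fit()
        n, k = len(y), X2.shape[1] - 1  # predictors in the full model
        q = X2.shape[1] - X1.shape[1]
        df2 = n - k - 1
        if df2 < 1:
            raise ValueError(
                f"n={n} leaves no residual degrees of freedom for the "
                f"full model ({k} predictors); need n >= {k + 2}"
            )
        r2b, r2f = float(m1.rsquared), float(m2.rsquared)
        denom = (1.0 - r2f) / df2
        if denom <= 0:  # perfect full-model fit
            f_change = np.inf
        else:
            f_change = ((r2f - r2b) / q) / denom
        p = float(scipy.stats.f.sf(f_change, q, df2))
        infl = OLSInfluence(m2)
        return ModerationResults(
            coding=self.coding,
            n=n,
            params=m2.params,
            std_params=_standardized(m2.params, X2, y),
            tvalues=m2.tvalues,
            pvalues=m2.pvalues,
            r2_base=r2b,
            r2_full=r2f,
            f_change=float(f_change),
            f_change_p=p,
            f_change_df=(q, df2),
            cooks_distance=np.asarray(infl.cooks_distance[0]),
            resid_z=np.asarray(infl.resid_studentized_internal),
            base_params=m1.params,
            base_std_params=_standardized(m1.params, X1, y),
            base_tvalues=m1.tvalues,
        )


def moderation_regression(
    cohort: pd.DataFrame, sles_coding: str = "median_split", **kwargs
) -> ModerationResults:
    """Functional wrapper around :class:`ModerationModel`."""
    return ModerationModel(cohort, coding=sles_coding, **kwargs).fit()


def subgroup_r2(cohort: pd.DataFrame, split: np.ndarray) -> tuple[float, float]:
    """Simple-regression R^2 of fluid IQ on the PE beta within each SLES
    subgroup (low=1, high=2). Errors if a subgroup has n < 3 or a constant
    predictor."""
    split = np.asarray(split)
    out = []
    for g in (1, 2):
        sub = cohort[split == g]
        if len(sub) < 3:
            raise ValueError(f"subgroup {g} has n={len(sub)} < 3")
        r, _ = pearson_r(sub["pe_beta"], sub["fluid_iq"])
        out.append(r * r)
    return out[0], out[1]
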