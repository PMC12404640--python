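"""Group and behavioral statistics for boundary-controllability analyses.

Conventions follow the analysis environment the field uses (R):

* the rank-sum statistic ``W`` is the Mann-Whitney U of the first sample
  (ties counted 1/2), as ``wilcox.test`` reports it;
* the MAD is scaled by 1.4826 by default (normal-consistency constant);
* FDR correction is Benjamini-Hochberg step-up;
* the group-by-region test on ordinal controllability ranks is a
  proportional-odds (cumulative-logit) model on rank deciles, with
  interaction contrasts against the region of interest as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "RegressionResult",
    "OrdinalModelResult",
    "GroupSummary",
    "wilcoxon_ranksum",
    "fdr_adjust",
    "group_summary",
    "linear_model",
    "pearson",
    "ordinal_group_region_model",
]

MAD_SCALE = 1.4826


@dataclass
class WilcoxonResult:
    w: float
    p_raw: float
    method: str
    p_fdr: float | None = None


def wilcoxon_ranksum(x, y, exact_threshold: int = 8) -> WilcoxonResult:
    """Two-sided rank-sum test; W = Mann-Whitney U of the first sample.

    Uses the exact permutation distribution when the smaller sample has at
    most ``exact_threshold`` observations and there are no ties, otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= exact_threshold and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return WilcoxonResult(w=float(res.statistic), p_raw=float(res.pvalue), method=method)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values, order-preserving on positions."""
    p = np.asarray(pvals, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupSummary:
    groups: dict[str, dict[str, float]]  # name -> {median, mad, n}


def group_summary(values, groups, mad_scale: float = MAD_SCALE) -> GroupSummary:
    """Median and (scaled) median absolute deviation per group."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        if len(v) == 0:
            raise ValueError(f"empty group {g!r}")
        out[str(g)] = {
            "median": float(np.median(v)),
            "mad": float(sps.median_abs_deviation(v, scale=1 / mad_scale)),
            "n": int(len(v)),
        }
    return GroupSummary(groups=out)


@dataclass
class RegressionResult:
    r2: float
    f_stat: float
    df1: int
    df2: int
    f_p: float
    terms: dict[str, dict[str, float]]  # name -> {beta, t, p}
    n: int
    n_dropped: int = 0

    def term(self, name: str) -> dict[str, float]:
        return self.terms[name]


def linear_model(y, predictors: pd.DataFrame | dict, zscore_y: bool = False,
                 zscore_x: bool = False) -> RegressionResult:
    """Ordinary least squares of an outcome on named predictors.

    Rows with any missing value are dropped listwise (count recorded).
    Optional z-scoring standardizes the outcome and/or the predictors
    within the analysis sample before fitting.
    """
    X = pd.DataFrame(predictors).copy()
    yv = pd.Series(np.asarray(y, float), index=X.index, name="y")
    keep = ~(X.isna().any(axis=1) | yv.isna())
    n_dropped = int((~keep).sum())
    X, yv = X[keep], yv[keep]
    if len(X) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the design")
    if zscore_y:
        yv = (yv - yv.mean()) / yv.std(ddof=1)
    if zscore_x:
        X = (X - X.mean()) / X.std(ddof=1)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(yv, design).fit()
    terms = {
        name: {
            "beta": float(fit.params[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        }
        for name in design.columns
    }
    return RegressionResult(
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        f_p=float(fit.f_pvalue),
        terms=terms,
        n=int(fit.nobs),
        n_dropped=n_dropped,
    )


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided t-test p and df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), len(x) - 2


@dataclass
class OrdinalModelResult:
    contrasts: dict[str, dict[str, float]]  # region -> {estimate, t, p}
    reference_region: str
    loglik: float
    converged: bool
    n_bins: int


def ordinal_group_region_model(
    long_table: pd.DataFrame,
    reference_region: str = "rPTr",
    n_bins: int = 10,
) -> OrdinalModelResult:
    """Proportional-odds model of BC rank on group, region, and interaction.

    ``long_table`` needs columns ``subject``, ``group`` (PWA/control),
    ``region``, ``bc_rank``.  Ranks are binned into ordered quantile
    categories of the pooled distribution before fitting a cumulative-logit
    model.  The returned contrasts are the group-by-region interaction
    coefficients with ``reference_region`` as the reference: a negative
    estimate means the PWA-minus-control shift at that region is smaller
    than the shift at the reference region.
    """
    df = long_table.copy()
    required = {"group", "region", "bc_rank"}
    if not required <= set(df.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    regions = list(pd.unique(df["region"]))
    if reference_region not in regions or len(regions) < 2:
        raise ValueError("need the reference region plus at least one other")
    if set(pd.unique(df["group"])) != {"PWA", "control"}:
        raise ValueError("group column must contain PWA and control")
    binned = pd.qcut(df["bc_rank"].rank(method="average"), q=n_bins,
                     labels=False, duplicates="drop")
    endog = pd.Categorical(binned, ordered=True)
    df["is_pwa"] = (df["group"] == "PWA").astype(float)
    others = [r for r in regions if r != reference_region]
    cols = {}
    for r in others:
        cols[f"region[{r}]"] = (df["region"] == r).astype(float)
        cols[f"pwa:region[{r}]"] = df["is_pwa"] * (df["region"] == r)
    cols["pwa"] = df["is_pwa"]
    exog = pd.DataFrame(cols)
    model = OrderedModel(endog, exog, distr="logit")
    fit = model.fit(method="bfgs", disp=False, maxiter=500)
    converged = bool(fit.mle_retvals.get("converged", True))
    contrasts = {
        r: {
            "estimate": float(fit.params[f"pwa:region[{r}]"]),
            "t": float(fit.tvalues[f"pwa:region[{r}]"]),
            "p": float(fit.pvalues[f"pwa:region[{r}]"]),
        }
        for r in others
    }
    return OrdinalModelResult(
        contrasts=contrasts,
        reference_region=reference_region,
        loglik=float(fit.llf),
        converged=converged,
        n_bins=int(pd.Series(binned).nunique()),
    )
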