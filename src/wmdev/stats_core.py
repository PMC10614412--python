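"""Statistical primitives shared across the pipeline.

Every routine returns plain results that serialize to the report tables.
The group-comparison tests mirror the demographics-table conventions:
Wilcoxon rank-sum (two-sided) for continuous variables, Pearson chi-square
for categorical ones, pooled-variance t-tests for subgroup contrasts, and
Benjamini-Hochberg FDR over the four diffusion metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "two_sample_t",
    "chi_square_independence",
    "pearson_corr",
    "partial_corr",
    "fdr_bh",
]

#: Largest combined sample size for which the rank-sum test enumerates the
#: exact null distribution (only when there are no ties).
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    df_or_n: tuple | float
    tails: str = "two_sided"
    method: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"non-finite test statistic: {self.statistic}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_sample(x, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"sample {name!r} needs >= {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return arr


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample size is at
    most ``EXACT_RANKSUM_MAX_N`` and there are no ties; otherwise the normal
    approximation with midranks and tie-corrected variance. The reported
    statistic is the rank-sum of ``x`` (midranks under ties).
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_x = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0:  # every value tied: no evidence either way
        return TestResult(w_x, 1.0, (x.size, y.size), method="degenerate_all_tied")
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_RANKSUM_MAX_N
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=w_x,
        p_value=float(min(res.pvalue, 1.0)),
        df_or_n=(x.size, y.size),
        method="exact" if exact else "normal_tie_corrected",
    )


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-sided t-test; statistic is mean(x) − mean(y) scaled.

    Degenerate variance: identical group means give t=0, p=1; different
    means with zero pooled variance are an error (infinite statistic).
    """
    x = _as_sample(x, "x", min_n=2)
    y = _as_sample(y, "y", min_n=2)
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return TestResult(0.0, 1.0, df, method="pooled_t",
                              notes={"degenerate": "zero pooled variance"})
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue), df, method="pooled_t",
                      notes={"equal_var_assumed": True})


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on a 2-by-k count table.

    No continuity correction (matches the demographics-table convention for
    sex and handedness counts); df = (rows−1)(cols−1).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table entries must be nonnegative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return TestResult(float(chi2), float(p), int(dof), method="pearson_chi2")


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p via the t transform (n−2 df)."""
    x = _as_sample(x, "x", min_n=3)
    y = _as_sample(y, "y", min_n=3)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance sample in correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are replaced by their least-squares residuals against an
    intercept plus the covariate columns (constant columns dropped); the
    residual correlation is tested with n − 2 − k degrees of freedom where k
    is the number of retained covariates. With no covariates this reduces
    exactly to :func:`pearson_corr`.
    """
    x = _as_sample(x, "x", min_n=3)
    y = _as_sample(y, "y", min_n=3)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must align with samples")
        keep = [j for j in range(cov.shape[1]) if np.ptp(cov[:, j]) > 0]
        cov = cov[:, keep]
    if cov.shape[1] == 0:
        return pearson_corr(x, y)
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix rank-deficient after dropping constants")
    k = cov.shape[1]
    if n - 2 - k < 1:
        raise ValueError("too few observations for the covariate count")
    coef, _, _, _ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    if rx.std() <= 1e-10 * max(x.std(), 1e-30) or \
            ry.std() <= 1e-10 * max(y.std(), 1e-30):
        raise ValueError("zero residual variance: variable collinear with covariates")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); a hypothesis is rejected iff
    its adjusted p is at most ``q``. With a single p-value this is the
    unadjusted test.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
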