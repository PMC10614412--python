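"""Deviation-based subtype discovery among autistic children.

Clusters the subjects × 4 bias-free deviation matrix with k-means, selects
the number of clusters by the mean silhouette coefficient over k = 2..10,
and runs the subgroup comparisons: age, each metric's deviation (FDR over
the four tests), ADOS scores, sex/handedness chi-square, head motion, and
the partial correlation of deviation with age.

Cluster labels are reported with subgroup 1 the younger cluster (lower mean
age) so that the "overgrowth first, delayed later" ordering is stable
across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .stats_core import (chi_square_independence, fdr_bh, partial_corr,
                         two_sample_t)
from .features import covariate_matrix
from .synthetic_cohort import METRICS

__all__ = [
    "ClusterSelection",
    "kmeans_cluster",
    "silhouette_select_k",
    "subgroup_compare",
    "deviation_age_correlation",
]


@dataclass
class ClusterSelection:
    k_range: tuple
    silhouette_by_k: dict
    chosen_k: int
    labels: np.ndarray          # 1-based cluster assignment
    centroids: np.ndarray
    inertia: float


def kmeans_cluster(deviation_matrix, k: int, seed: int = 0, n_init: int = 50):
    """Best-of-``n_init`` Lloyd's k-means with k-means++ seeding.

    Returns (labels in 1..k, centroids, inertia). Deterministic given seed.
    """
    x = np.atleast_2d(np.asarray(deviation_matrix, dtype=float))
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] <= k:
        raise ValueError("need more subjects than clusters")
    if not np.all(np.isfinite(x)):
        raise ValueError("deviation matrix contains missing values")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                random_state=seed).fit(x)
    labels = km.labels_ + 1
    if np.unique(labels).size < k:
        raise RuntimeError("k-means converged with an empty cluster")
    return labels, km.cluster_centers_, float(km.inertia_)


def mean_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette with the singleton convention s(i)=0."""
    return float(np.mean(silhouette_samples(x, labels)))


def silhouette_select_k(deviation_matrix, k_range=range(2, 11), seed: int = 0,
                        n_init: int = 50) -> ClusterSelection:
    """Choose k maximizing the mean silhouette; ties go to the smaller k."""
    x = np.atleast_2d(np.asarray(deviation_matrix, dtype=float))
    ks = sorted(k_range)
    if x.shape[0] <= max(ks):
        raise ValueError("need more subjects than the largest k")
    scores, fits = {}, {}
    for k in ks:
        labels, cents, inertia = kmeans_cluster(x, k, seed=seed, n_init=n_init)
        scores[k] = mean_silhouette(x, labels)
        fits[k] = (labels, cents, inertia)
    chosen = max(ks, key=lambda k: (scores[k], -k))
    labels, cents, inertia = fits[chosen]
    return ClusterSelection(tuple(ks), scores, chosen, labels, cents, inertia)


def order_clusters_by_age(labels: np.ndarray, records) -> np.ndarray:
    """Relabel clusters so that label 1 has the lowest mean age."""
    ages = np.array([r.age for r in records])
    uniq = np.unique(labels)
    mean_ages = {c: ages[labels == c].mean() for c in uniq}
    remap = {c: i + 1 for i, c in enumerate(sorted(uniq, key=mean_ages.get))}
    return np.array([remap[c] for c in labels])


def subgroup_compare(labels, records, deviation_frame: pd.DataFrame,
                     fdr_q: float = 0.05) -> pd.DataFrame:
    """Compare the two developmental subgroups on phenotype and deviations.

    t-tests (subgroup 1 minus subgroup 2) on age, head motion, the four
    bias-free deviations (BH-FDR over 4 tests) and ADOS total/social
    (subjects with missing ADOS excluded); chi-square on sex and handedness.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(
            f"expected exactly 2 subgroups, got {uniq.size}; rerun the "
            "clustering with k=2 or extend the comparison configuration")
    g1 = labels == uniq[0]
    g2 = labels == uniq[1]
    rows = []

    def add_t(var, a, b, extra=None):
        res = two_sample_t(a, b)
        rows.append({"variable": var, "test": "t", "statistic": res.statistic,
                     "p": res.p_value,
                     "mean_1": float(np.mean(a)), "mean_2": float(np.mean(b)),
                     **(extra or {})})

    ages = np.array([r.age for r in records])
    add_t("age_years", ages[g1], ages[g2])
    motion = np.array([r.head_motion for r in records])
    add_t("head_motion_mm", motion[g1], motion[g2])

    dev_ps = []
    for m in METRICS:
        vals = deviation_frame[m].to_numpy()
        add_t(f"deviation_{m}", vals[g1], vals[g2])
        dev_ps.append(rows[-1]["p"])
    reject, p_adj = fdr_bh(dev_ps, q=fdr_q)
    for i, m in enumerate(METRICS):
        for row in rows:
            if row["variable"] == f"deviation_{m}":
                row["p_fdr"] = float(p_adj[i])
                row["significant_fdr"] = bool(reject[i])

    for score in ("ados_total", "ados_social"):
        vals = np.array([getattr(r, score) if getattr(r, score) is not None
                         else np.nan for r in records])
        ok = ~np.isnan(vals)
        if (ok & g1).sum() >= 2 and (ok & g2).sum() >= 2:
            add_t(score, vals[ok & g1], vals[ok & g2],
                  extra={"n_excluded_missing": int((~ok).sum())})

    for var, attr, levels in (("sex", "sex", ("M", "F")),
                              ("handedness", "handedness", ("R", "L", "M"))):
        tab = np.array([[sum(1 for r, m_ in zip(records, g) if m_ and
                             getattr(r, attr) == lv) for lv in levels]
                        for g in (g1, g2)])
        tab = tab[:, tab.sum(axis=0) > 0]
        try:
            res = chi_square_independence(tab)
            rows.append({"variable": var, "test": "chi2",
                         "statistic": res.statistic, "p": res.p_value})
        except ValueError:
            rows.append({"variable": var, "test": "chi2",
                         "statistic": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def deviation_age_correlation(deviation_frame: pd.DataFrame, records,
                              covariates=("sex", "handedness", "head_motion"),
                              fdr_q: float = 0.05) -> pd.DataFrame:
    """Partial correlation of each metric's bias-free deviation with age.

    Age is the variable of interest; the default nuisance set is sex,
    handedness and head motion. BH-FDR over the four metric tests.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 subjects")
    ages = np.array([r.age for r in records])
    cov = covariate_matrix(records, include=covariates)
    rows = []
    for m in METRICS:
        vals = deviation_frame[m].to_numpy()
        try:
            r, p = partial_corr(vals, ages, cov)
        except ValueError as err:
            raise ValueError(f"metric {m}: {err}") from err
        rows.append({"metric": m, "r": r, "p": p})
    reject, p_adj = fdr_bh([row["p"] for row in rows], q=fdr_q)
    for row, rej, pa in zip(rows, reject, p_adj):
        row["p_fdr"] = float(pa)
        row["significant_fdr"] = bool(rej)
    return pd.DataFrame(rows)
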