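"""Feature extraction from skeleton-space metric volumes.

Turns per-subject scalar maps into the three feature granularities used
downstream — the skeleton-wide mean, per-bundle means (the default input
to the age model), and the flattened voxel vector — plus nuisance
residualization and the case-control exploration (group t-tests on global
means and per-group age correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import TestResult, pearson_corr, two_sample_t
from .synthetic_cohort import METRICS

__all__ = [
    "FeatureTable",
    "extract_features",
    "regress_nuisance",
    "case_control_compare",
    "age_correlation_by_group",
    "covariate_matrix",
]

FEATURE_KINDS = ("global_mean", "bundle_means", "voxel_vector")


@dataclass
class FeatureTable:
    """Subjects-by-features matrix for one diffusion metric.

    ``values`` rows align with ``subject_ids``; column labels are bundle
    names (``bundle_<k>``) or C-order voxel indices into the masked grid.
    """

    subject_ids: list
    metric: str
    feature_kind: str
    values: np.ndarray
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("rows must align with subject_ids")
        if self.feature_names and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.feature_names or None)

    def subset(self, ids) -> "FeatureTable":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in ids]
        return FeatureTable(list(ids), self.metric, self.feature_kind,
                            self.values[rows], list(self.feature_names))


def extract_features(volumes, kind: str = "bundle_means") -> dict:
    """Extract one :class:`FeatureTable` per metric from a volume list.

    ``global_mean``: mean over skeleton voxels. ``bundle_means``: mean
    within each nonzero label. ``voxel_vector``: skeleton voxels flattened
    in C order (the order is recorded in the feature names).
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    if not volumes:
        raise ValueError("no volumes")
    mask = volumes[0].skeleton_mask.astype(bool)
    labels = volumes[0].bundle_labels
    for v in volumes:
        if not np.array_equal(v.skeleton_mask.astype(bool), mask) or \
           not np.array_equal(v.bundle_labels, labels):
            raise ValueError("volumes must share skeleton and bundle labels")
    label_ids = [int(k) for k in np.unique(labels) if k != 0]
    for k in label_ids:
        if not np.any(labels == k):
            raise ValueError(f"empty bundle label {k}")
    ids = [v.subject_id for v in volumes]
    out = {}
    for m in METRICS:
        stack = np.stack([v.metric_maps[m] for v in volumes])  # subjects × grid
        if kind == "global_mean":
            vals = stack[:, mask].mean(axis=1, keepdims=True)
            names = ["global_mean"]
        elif kind == "bundle_means":
            vals = np.column_stack([stack[:, labels == k].mean(axis=1)
                                    for k in label_ids])
            names = [f"bundle_{k}" for k in label_ids]
        else:
            vals = stack[:, mask]  # C-order flattening of masked voxels
            names = [f"voxel_{i}" for i in range(vals.shape[1])]
        out[m] = FeatureTable(ids, m, kind, vals, names)
    return out


def regress_nuisance(features: FeatureTable, covariates) -> FeatureTable:
    """Replace every feature column with its residual against the covariates.

    The design is [intercept | covariates]; residuals are exactly orthogonal
    to every covariate column. Applying the operation twice is a no-op.
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != features.values.shape[0]:
        raise ValueError("covariate rows must align with subjects")
    design = np.column_stack([np.ones(cov.shape[0]), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, _, _, _ = np.linalg.lstsq(design, features.values, rcond=None)
    resid = features.values - design @ coef
    return FeatureTable(list(features.subject_ids), features.metric,
                        features.feature_kind, resid, list(features.feature_names))


def case_control_compare(features_a: dict, features_b: dict) -> dict:
    """Two-sided pooled t-test per metric on the global-mean feature.

    Statistic sign follows group A minus group B.
    """
    if set(features_a) != set(features_b):
        raise ValueError("metric sets differ between groups")
    results = {}
    for m in features_a:
        ta, tb = features_a[m], features_b[m]
        a = ta.values.mean(axis=1) if ta.feature_kind != "global_mean" else ta.values[:, 0]
        b = tb.values.mean(axis=1) if tb.feature_kind != "global_mean" else tb.values[:, 0]
        results[m] = two_sample_t(a, b)
    return results


def age_correlation_by_group(features: dict, records) -> dict:
    """Pearson r and p between age and each metric's global mean, per group."""
    by_group: dict[str, list] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    out: dict[str, dict] = {}
    for g, recs in by_group.items():
        if len(recs) < 3:
            raise ValueError(f"group {g} has fewer than 3 subjects")
        ids = [r.subject_id for r in recs]
        ages = np.array([r.age for r in recs])
        out[g] = {}
        for m, table in features.items():
            sub = table.subset(ids)
            vals = sub.values.mean(axis=1) if sub.feature_kind != "global_mean" \
                else sub.values[:, 0]
            out[g][m] = pearson_corr(ages, vals)
    return out


_SEX_CODE = {"M": 1.0, "F": 0.0}
_HAND_CODE = {"R": 0.0, "L": 1.0, "M": 0.5}


def covariate_matrix(records, include=("sex", "handedness", "head_motion"),
                     include_age: bool = False) -> np.ndarray:
    """Numeric nuisance design used across the pipeline.

    Sex is coded M=1/F=0, handedness R=0/L=1/mixed=0.5, motion in mm;
    age (years) is prepended when requested.
    """
    cols = []
    if include_age:
        cols.append([r.age for r in records])
    for name in include:
        if name == "sex":
            cols.append([_SEX_CODE[r.sex] for r in records])
        elif name == "handedness":
            cols.append([_HAND_CODE[r.handedness] for r in records])
        elif name == "head_motion":
            cols.append([r.head_motion for r in records])
        elif name == "age":
            cols.append([r.age for r in records])
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(records), 0))
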