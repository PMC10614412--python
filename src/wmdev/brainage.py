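"""Developmental age prediction and the bias-free deviation index.

Per diffusion metric, a regressor (support-vector regression by default,
random-forest regression as the robustness alternative) is trained on the
typically developing children to predict chronological age from white-
matter features. Because regression-to-the-mean makes raw brain-age gaps
age-dependent (overestimated in the youngest, underestimated in the
oldest), the gap is corrected Beheshti-style: on a held-out control test
set the raw deviation (predicted − true age) is regressed on true age
Omega, and the fitted trend alpha*Omega + beta is subtracted:

    bias_free = (predicted − Omega) − (alpha*Omega + beta)

The corrected value is the per-subject, per-metric white-matter atypical
development index: positive = accelerated maturation, negative = delayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import FeatureTable
from .stats_core import wilcoxon_rank_sum

__all__ = [
    "BiasModel",
    "DeviationIndex",
    "ModelPerformance",
    "age_matched_split",
    "fit_age_model",
    "cross_validate",
    "estimate_bias",
    "compute_deviation_index",
]


@dataclass(frozen=True)
class BiasModel:
    """Linear age trend of the raw deviation on a held-out control set."""

    metric: str
    alpha: float  # slope, years of deviation per year of age
    beta: float   # intercept, years

    def predicted_bias(self, ages) -> np.ndarray:
        return self.alpha * np.asarray(ages, dtype=float) + self.beta


@dataclass
class DeviationIndex:
    """Per-subject raw and bias-free deviations for one metric (years)."""

    subject_ids: list
    metric: str
    raw: np.ndarray
    bias_free: np.ndarray


@dataclass
class ModelPerformance:
    metric: str
    mse: float           # years^2, mean over folds
    mape: float          # percent, mean over folds
    fold_mse: list
    fold_mape: list


def age_matched_split(td_records, fraction: float = 0.5, seed: int = 0,
                      p_threshold: float = 0.1, max_attempts: int = 200):
    """Split controls into train/test halves with matched age distributions.

    Random splits are drawn until the rank-sum p of the age difference
    exceeds the threshold; if no draw succeeds within ``max_attempts`` the
    deterministic fallback interleaves the age-sorted subjects, which always
    yields closely matched halves.
    """
    if len(td_records) < 8:
        raise ValueError("need at least 8 control subjects to split")
    ids = [r.subject_id for r in td_records]
    ages = np.array([r.age for r in td_records])
    n_train = int(round(len(ids) * fraction))
    n_train = min(max(n_train, 1), len(ids) - 1)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        perm = rng.permutation(len(ids))
        tr, te = perm[:n_train], perm[n_train:]
        if np.ptp(ages) == 0 or wilcoxon_rank_sum(ages[tr], ages[te]).p_value > p_threshold:
            return [ids[i] for i in tr], [ids[i] for i in te]
    order = np.argsort(ages, kind="stable")
    tr = [ids[i] for i in order[0::2]][:n_train]
    te = [s for s in ids if s not in set(tr)]
    return tr, te


def _strip_constant(values: np.ndarray):
    keep = np.ptp(values, axis=0) > 0
    if not keep.any():
        raise ValueError("all feature columns are constant")
    return values[:, keep], keep


class AgePredictor:
    """Feature-standardized regressor mapping features to age (years).

    Standardization statistics come from the training set only and travel
    with the predictor; constant training columns are dropped.
    """

    def __init__(self, model: str = "svr", seed: int = 0,
                 svr_params: dict | None = None, rfr_params: dict | None = None):
        if model not in ("svr", "rfr"):
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.seed = seed
        self.svr_params = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1,
                           **(svr_params or {})}
        self.rfr_params = {"n_estimators": 500, "max_depth": None,
                           **(rfr_params or {})}
        self._pipe: Pipeline | None = None
        self._keep: np.ndarray | None = None

    def fit(self, features: np.ndarray, ages) -> "AgePredictor":
        features = np.atleast_2d(np.asarray(features, dtype=float))
        ages = np.asarray(ages, dtype=float)
        if features.shape[0] < 5:
            raise ValueError("need at least 5 training subjects")
        x, self._keep = _strip_constant(features)
        if self.model == "svr":
            reg = SVR(**self.svr_params)
        else:
            reg = RandomForestRegressor(random_state=self.seed, **self.rfr_params)
        self._pipe = Pipeline([("scale", StandardScaler()), ("reg", reg)])
        self._pipe.fit(x, ages)
        return self

    def predict(self, features) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("predictor is not fitted")
        x = np.atleast_2d(np.asarray(features, dtype=float))[:, self._keep]
        return self._pipe.predict(x)


def fit_age_model(train: FeatureTable, ages, model: str = "svr", seed: int = 0,
                  **model_params) -> AgePredictor:
    """Train the per-metric developmental predictor on control subjects."""
    return AgePredictor(model=model, seed=seed, **model_params).fit(
        train.values, ages)


def fold_scores(predicted, true_ages) -> tuple[float, float]:
    """MSE (years^2) and MAPE (%) of predictions against true ages."""
    predicted = np.asarray(predicted, dtype=float)
    true_ages = np.asarray(true_ages, dtype=float)
    err = predicted - true_ages
    return (float(np.mean(err ** 2)),
            float(np.mean(np.abs(err) / true_ages) * 100.0))


def cross_validate(features: FeatureTable, ages, model: str = "svr",
                   k: int = 5, seed: int = 0, **model_params) -> ModelPerformance:
    """k-fold cross-validated MSE (years^2) and MAPE (%).

    Each subject is scored exactly once, by the model trained on the other
    k−1 folds; the reported numbers are means over folds.
    """
    ages = np.asarray(ages, dtype=float)
    n = features.values.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_mse, fold_mape = [], []
    tested = np.zeros(n, dtype=bool)
    for tr, te in kf.split(features.values):
        pred = AgePredictor(model=model, seed=seed, **model_params).fit(
            features.values[tr], ages[tr]).predict(features.values[te])
        mse, mape = fold_scores(pred, ages[te])
        fold_mse.append(mse)
        fold_mape.append(mape)
        tested[te] = True
    assert tested.all()
    return ModelPerformance(features.metric, float(np.mean(fold_mse)),
                            float(np.mean(fold_mape)), fold_mse, fold_mape)


def estimate_bias(predictor: AgePredictor, test: FeatureTable, test_ages) -> BiasModel:
    """Least-squares fit of raw deviation on true age over held-out controls."""
    ages = np.asarray(test_ages, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 test subjects to estimate bias")
    deviation = predictor.predict(test.values) - ages
    design = np.column_stack([ages, np.ones_like(ages)])
    (alpha, beta), _, _, _ = np.linalg.lstsq(design, deviation, rcond=None)
    return BiasModel(test.metric, float(alpha), float(beta))


def compute_deviation_index(predictor: AgePredictor, bias: BiasModel,
                            features: FeatureTable, ages) -> DeviationIndex:
    """Raw and bias-free deviations for arbitrary subjects (typically ASD)."""
    if bias.metric != features.metric:
        raise ValueError(f"bias model metric {bias.metric!r} != features "
                         f"metric {features.metric!r}")
    ages = np.asarray(ages, dtype=float)
    raw = predictor.predict(features.values) - ages
    bias_free = raw - bias.predicted_bias(ages)
    return DeviationIndex(list(features.subject_ids), features.metric, raw, bias_free)


def deviation_matrix(indices: dict) -> pd.DataFrame:
    """Stack per-metric bias-free deviations into a subjects × metrics frame."""
    frames = {m: pd.Series(d.bias_free, index=d.subject_ids)
              for m, d in indices.items()}
    return pd.DataFrame(frames)
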