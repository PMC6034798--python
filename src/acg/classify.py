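"""Gradient-boosted classification of hypertension status with repeated CV.

One feature vector per subject (exam-aggregated) is the unit of
classification, so a subject can never straddle a train/test boundary.
Features are z-scored with training-fold statistics only, the model is a
gradient-boosted tree ensemble, and evaluation is stratified 5-fold
cross-validation repeated 10 times: each subject's out-of-fold scores are
averaged across repeats and a single ROC is swept over the averaged
scores.  The operating point defaults to Youden's J
(sensitivity + specificity - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "RocResult",
    "FeatureScaler",
    "normalize_features",
    "roc_result",
    "cross_validate",
    "FEATURE_COLUMN_PREFIXES",
]

log = logging.getLogger(__name__)

FEATURE_COLUMN_PREFIXES = ("ToA_", "ATT_", "FFT_")


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 200
    learning_rate: float = 0.05
    max_depth: int = 3
    subsample: float = 0.8
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    threshold_rule: str = "youden"
    fixed_threshold: Optional[float] = None

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.cv_repeats < 1:
            raise ValueError("need at least 1 repeat")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.threshold_rule not in ("youden", "fixed"):
            raise ValueError("threshold rule must be 'youden' or 'fixed'")


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC and a single operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    scores: np.ndarray
    labels: np.ndarray

    @property
    def roc_points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


class FeatureScaler:
    """Per-feature z-scoring with a zero-variance guard.

    Statistics are learned from the training data passed to :meth:`fit`
    and applied unchanged to held-out data; constant features transform to
    all-zero columns (with a logged warning) instead of dividing by zero.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        constant = sd == 0
        if np.any(constant):
            log.warning("constant feature column(s) %s scaled to zero", np.nonzero(constant)[0])
        self.scale_ = np.where(constant, 1.0, sd)
        self._constant = constant
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        z = (np.asarray(x, dtype=float) - self.mean_) / self.scale_
        z[:, self._constant] = 0.0
        return z

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric feature column of a table (self-fitted).

    Inside cross-validation use :class:`FeatureScaler` per fold instead;
    this convenience applies to whole-table reporting only.
    """
    out = table.copy()
    cols = [c for c in table.columns if table[c].dtype.kind in "fi"]
    scaler = FeatureScaler().fit(table[cols].values)
    out[cols] = scaler.transform(table[cols].values)
    return out


def feature_matrix(table: pd.DataFrame):
    """Split a features table into (X, y, subject_ids); labels 1 = hypertension."""
    cols = [c for c in table.columns if c.startswith(FEATURE_COLUMN_PREFIXES)]
    x = table[cols].to_numpy(dtype=float)
    y = (table["group"] == "hypertension").to_numpy(dtype=int)
    return x, y, table.get("subject_id", pd.Series(range(len(table)))).to_numpy()


def roc_result(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold_rule: str = "youden",
    fixed_threshold: Optional[float] = None,
) -> RocResult:
    """ROC sweep over unique scores with trapezoidal AUC.

    Tied scores collapse to a single threshold, which makes the trapezoid
    area equal to the concordant-pair fraction with half credit for ties.
    The curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if threshold_rule == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold rule needs a threshold")
        idx = int(np.argmin(np.abs(thr[1:] - fixed_threshold)) + 1)
    else:
        idx = int(np.argmax(tpr - fpr))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        sensitivity=float(tpr[idx]),
        specificity=float(1.0 - fpr[idx]),
        threshold=float(thr[idx]),
        scores=scores,
        labels=labels,
    )


def cross_validate(
    features,
    labels: Optional[Sequence[int]] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> RocResult:
    """Repeated stratified k-fold CV returning the pooled out-of-fold ROC.

    ``features`` may be a features table (with ``group`` labels) or a raw
    matrix with explicit ``labels``.  For every repeat each subject is
    scored exactly once out of fold; scores are averaged across repeats
    before the ROC sweep.  Bit-reproducible for a fixed ``config.seed``.
    """
    if isinstance(features, pd.DataFrame):
        x, y, _ = feature_matrix(features)
    else:
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    if counts.min() < config.cv_folds:
        raise ValueError("minority class smaller than the number of folds")

    score_sum = np.zeros(len(y))
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed + rep
        )
        for train, test in skf.split(x, y):
            scaler = FeatureScaler().fit(x[train])
            model = GradientBoostingClassifier(
                n_estimators=config.n_trees,
                learning_rate=config.learning_rate,
                max_depth=config.max_depth,
                subsample=config.subsample,
                random_state=(config.seed + 7919 * rep) % (2**31 - 1),
            )
            model.fit(scaler.transform(x[train]), y[train])
            score_sum[test] += model.predict_proba(scaler.transform(x[test]))[:, 1]
    scores = score_sum / config.cv_repeats
    return roc_result(
        scores, y, threshold_rule=config.threshold_rule, fixed_threshold=config.fixed_threshold
    )
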