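"""Interpretable baselines and classical ML models on HRV features.

Three baselines, all fitted by exhaustive search maximising training
accuracy with deterministic tie-breaks (the smallest cutoffs win, then
direction +1):

* single-feature double-threshold classifier (one of the 11 features,
  two cutoffs mapping the value axis to the three ordinal classes);
* a fixed rule template on MeanRR and RMSSD — fatigued when both are
  low, normal when both are high, slight fatigue otherwise;
* an equal-weight scoring system over three sign-aligned z-scored
  features (default +MeanHR, -RMSSD, +LF/HF) with two score cutoffs.

Classical models (logistic regression, RBF-kernel SVM one-vs-rest,
random forest) wrap scikit-learn with training-set standardization baked
into the returned pipeline, so ``predict`` is self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

DEFAULT_WEIGHTED_FEATURES = ("MeanHR", "RMSSD", "LF_HF")
WEIGHTED_SIGNS = {"MeanHR": +1.0, "RMSSD": -1.0, "LF_HF": +1.0}


def _as_array(features, name: str) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if name not in features.columns:
            raise ValueError(f"feature {name!r} missing from table")
        return features[name].to_numpy(dtype=float)
    raise TypeError("features must be a DataFrame with named columns")


def _cutoff_candidates(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    if u.size < 2:
        return u
    return (u[:-1] + u[1:]) / 2.0


def _best_pair_accuracy(values: np.ndarray, labels: np.ndarray, direction: int,
                        candidates: np.ndarray) -> tuple[float, float, float]:
    """Best (accuracy, c1, c2) for pred = [lo if v<=c1, mid if v<=c2, hi]."""
    lo_class, hi_class = (0, 2) if direction == +1 else (2, 0)
    order = np.argsort(candidates)
    cands = candidates[order]
    # prefix counts of each class at value <= c for every candidate cutoff
    counts = np.zeros((3, cands.size))
    for k in range(3):
        counts[k] = np.searchsorted(np.sort(values[labels == k]), cands, side="right")
    n_hi_total = float((labels == hi_class).sum())
    A = counts[lo_class]            # correct lows for c1 = cands[i]
    B = counts[1]                   # mids below each cutoff
    C = counts[hi_class]
    # accuracy(i, j>=i) = A[i] + (B[j] - B[i]) + (n_hi - C[j])
    left = (A - B)[:, None]
    right = (B - C)[None, :] + n_hi_total
    acc = left + right
    i_idx, j_idx = np.triu_indices(cands.size)
    flat = acc[i_idx, j_idx]
    best = int(np.argmax(flat))  # argmax returns the first max: smallest (i, j)
    return float(flat[best]) / labels.size, float(cands[i_idx[best]]), float(cands[j_idx[best]])


@dataclass
class ThresholdModel:
    """Single-feature ordinal classifier with two cutoffs."""

    feature: str
    direction: int  # +1: larger value means more fatigued
    c1: float
    c2: float
    training_accuracy: float = float("nan")
    majority_class: int | None = None  # degenerate fallback

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.c1 > self.c2:
            raise ValueError("cutoffs must satisfy c1 <= c2")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if self.majority_class is not None:
            return np.full(len(features), self.majority_class)
        v = _as_array(features, self.feature)
        lo, hi = (0, 2) if self.direction == +1 else (2, 0)
        pred = np.full(v.size, 1)
        pred[v <= self.c1] = lo
        pred[v > self.c2] = hi
        return pred


def fit_threshold_classifier(features: pd.DataFrame, labels: np.ndarray,
                             feature_name: str) -> ThresholdModel:
    """Fit the optimal two-cutoff classifier for one feature by exhaustive
    search over midpoints of sorted unique training values and both
    directions.  Ties break to (smaller c1, smaller c2, direction +1)."""
    labels = np.asarray(labels, dtype=int)
    v = _as_array(features, feature_name)
    if np.unique(v).size < 2:
        counts = np.bincount(labels, minlength=3)
        warnings.warn(f"feature {feature_name!r} is constant; predicting majority class",
                      stacklevel=2)
        return ThresholdModel(feature=feature_name, direction=+1, c1=0.0, c2=0.0,
                              training_accuracy=counts.max() / labels.size,
                              majority_class=int(np.argmax(counts)))
    cands = _cutoff_candidates(v)
    best = None
    for direction in (+1, -1):
        acc, c1, c2 = _best_pair_accuracy(v, labels, direction, cands)
        key = (-acc, c1, c2, -direction)
        if best is None or key < best[0]:
            best = (key, ThresholdModel(feature=feature_name, direction=direction,
                                        c1=c1, c2=c2, training_accuracy=acc))
    return best[1]


@dataclass
class RuleModel:
    """Hand-crafted rule template on MeanRR (ms) and RMSSD (ms):
    fatigued if both low, normal if both high, slight otherwise."""

    a: float  # MeanRR fatigued bound
    b: float  # RMSSD fatigued bound
    c: float  # MeanRR normal bound (>= a)
    d: float  # RMSSD normal bound (>= b)
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        if self.a > self.c or self.b > self.d:
            raise ValueError("rule bounds must satisfy a <= c and b <= d")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        mr = _as_array(features, "MeanRR")
        rm = _as_array(features, "RMSSD")
        pred = np.full(mr.size, 1)
        pred[(mr < self.a) & (rm < self.b)] = 2
        pred[(mr >= self.c) & (rm >= self.d)] = 0
        return pred

    def describe(self) -> str:
        return (
            f"fatigued if MeanRR < {self.a:.1f} ms and RMSSD < {self.b:.1f} ms\n"
            f"normal   if MeanRR >= {self.c:.1f} ms and RMSSD >= {self.d:.1f} ms; else slight"
        )


def fit_rule_based(features: pd.DataFrame, labels: np.ndarray,
                   n_grid: int = 16) -> RuleModel:
    """Fit the (a, b, c, d) rule bounds by grid search over training-value
    quantiles, maximising training accuracy with deterministic tie-breaks."""
    labels = np.asarray(labels, dtype=int)
    mr = _as_array(features, "MeanRR")
    rm = _as_array(features, "RMSSD")
    qs = np.linspace(0.0, 1.0, n_grid)
    mr_grid = np.unique(np.quantile(mr, qs))
    rm_grid = np.unique(np.quantile(rm, qs))
    best = None
    for ai, a in enumerate(mr_grid):
        mr_lt_a = mr < a
        for ci in range(ai, mr_grid.size):
            c = mr_grid[ci]
            mr_ge_c = mr >= c
            for bi, b in enumerate(rm_grid):
                rm_lt_b = rm < b
                for di in range(bi, rm_grid.size):
                    d = rm_grid[di]
                    pred = np.full(mr.size, 1)
                    pred[mr_lt_a & rm_lt_b] = 2
                    pred[mr_ge_c & (rm >= d)] = 0
                    acc = float(np.mean(pred == labels))
                    key = (-acc, a, b, c, d)
                    if best is None or key < best[0]:
                        best = (key, (a, b, c, d, acc))
    a, b, c, d, acc = best[1]
    return RuleModel(a=a, b=b, c=c, d=d, training_accuracy=acc)


@dataclass
class WeightedScoreModel:
    """Equal-weight score over three sign-aligned z-scored features."""

    feature_names: tuple[str, str, str]
    means: np.ndarray
    sds: np.ndarray
    signs: np.ndarray
    c1: float
    c2: float
    training_accuracy: float = float("nan")

    def score(self, features: pd.DataFrame) -> np.ndarray:
        cols = np.column_stack([_as_array(features, n) for n in self.feature_names])
        z = (cols - self.means) / self.sds
        return (z * self.signs).mean(axis=1)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        s = self.score(features)
        pred = np.full(s.size, 1)
        pred[s <= self.c1] = 0
        pred[s > self.c2] = 2
        return pred


def fit_weighted_score(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_names: tuple[str, str, str] = DEFAULT_WEIGHTED_FEATURES,
) -> WeightedScoreModel:
    """Fit the two score cutoffs of the equal-weight model by exhaustive
    2-D grid over score midpoints (training-accuracy maximising)."""
    labels = np.asarray(labels, dtype=int)
    cols = np.column_stack([_as_array(features, n) for n in feature_names])
    means = cols.mean(axis=0)
    sds = cols.std(axis=0)
    zero_var = sds < 1e-12
    if zero_var.any():
        warnings.warn(f"zero-variance features {np.array(feature_names)[zero_var]}: "
                      "their z-scores are set to 0", stacklevel=2)
        sds = np.where(zero_var, 1.0, sds)
    signs = np.array([WEIGHTED_SIGNS.get(n, +1.0) for n in feature_names])
    model = WeightedScoreModel(feature_names=tuple(feature_names), means=means, sds=sds,
                               signs=signs, c1=0.0, c2=0.0)
    s = model.score(features)
    cands = _cutoff_candidates(s)
    acc, c1, c2 = _best_pair_accuracy(s, labels, +1, cands)
    model.c1, model.c2, model.training_accuracy = c1, c2, acc
    return model


CLASSICAL_KINDS = ("logreg", "svm_rbf", "rf")


def fit_classical(kind: str, features: pd.DataFrame, labels: np.ndarray,
                  seed: int = 0, feature_names: list[str] | None = None) -> Pipeline:
    """Fit a classical model on the HRV feature table.

    ``logreg`` and ``svm_rbf`` standardize with training statistics inside
    the pipeline; the SVM uses a one-vs-rest RBF kernel; the random forest
    uses 500 trees with a fixed seed.  Returns a fitted scikit-learn
    pipeline whose ``predict`` accepts a feature table.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    from fatiguecg.hrv import FEATURE_NAMES

    feature_names = list(feature_names or FEATURE_NAMES)
    X = features[feature_names].to_numpy(dtype=float)
    if kind == "logreg":
        pipe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    elif kind == "svm_rbf":
        pipe = make_pipeline(StandardScaler(), OneVsRestClassifier(SVC(kernel="rbf")))
    elif kind == "rf":
        pipe = make_pipeline(RandomForestClassifier(n_estimators=500, random_state=seed))
    else:
        raise ValueError(f"kind must be one of {CLASSICAL_KINDS}")
    pipe.fit(X, labels)
    pipe.feature_names_ = feature_names  # so predict_table is self-contained
    return pipe


def predict_classical(pipe: Pipeline, features: pd.DataFrame) -> np.ndarray:
    return pipe.predict(features[list(pipe.feature_names_)].to_numpy(dtype=float))
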