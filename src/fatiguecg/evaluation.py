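"""Evaluation protocol: metrics, split strategies, cross-validation,
McNemar paired tests, segment-duration sensitivity, and ablations.

Metrics are computed one-vs-rest per class (TP/TN/FP/FN) and macro
(unweighted) averaged; every report stores its confusion matrix so all
metrics are recomputable.  Three split strategies are provided:

* ``segment``  -- per-class stratified random split (test count per class
  = floor(fraction x class n), matching the published 719/963/958 ->
  143/192/191 example);
* ``session``  -- whole 10-minute sessions assigned to train or test, so
  the 20 segments of one session never straddle the boundary;
* ``subject``  -- leave-k-subjects-out (default k=2), repeated with
  distinct seeded subject draws.

Leakage invariants are asserted on every constructed split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fatiguecg.data_model import FatigueClass, Segment, StudyManifest
from fatiguecg.preprocess import FilterSpec, preprocess_study


# ---------------------------------------------------------------------------
# metrics

@dataclass
class Metrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame  # rows per class: precision, recall, f1, support


def metrics_from_confusion(cm: np.ndarray) -> Metrics:
    """Accuracy and one-vs-rest precision/recall/F1 per class plus their
    unweighted (macro) means.  Zero denominators yield 0 with a warning."""
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    n = cm.sum()
    accuracy = float(np.trace(cm) / n)
    rows = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        if tp + fp == 0 or tp + fn == 0:
            warnings.warn(f"class {k}: zero denominator; precision/recall set to 0",
                          stacklevel=2)
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        rows.append({"class": k, "precision": precision, "recall": recall,
                     "f1": f1, "support": cm[k, :].sum()})
    per_class = pd.DataFrame(rows).set_index("class")
    return Metrics(
        accuracy=accuracy,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        per_class=per_class,
    )


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
    return cm


@dataclass
class EvalReport:
    """Confusion matrix plus derived metrics for one evaluated split."""

    cm: np.ndarray
    split: str
    metrics: Metrics = field(init=False)
    paired_tests: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metrics = metrics_from_confusion(self.cm)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "confusion_matrix": np.asarray(self.cm).tolist(),
            "accuracy": self.metrics.accuracy,
            "macro_precision": self.metrics.macro_precision,
            "macro_recall": self.metrics.macro_recall,
            "macro_f1": self.metrics.macro_f1,
        }


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray, split: str = "",
                         n_classes: int = 3) -> EvalReport:
    return EvalReport(cm=confusion_matrix(y_true, y_pred, n_classes), split=split)


# ---------------------------------------------------------------------------
# splits

STRATEGIES = ("segment", "session", "subject")


@dataclass
class SplitPlan:
    strategy: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    repeat: int = 0
    test_subjects: tuple[str, ...] = ()

    def validate(self, meta: pd.DataFrame) -> None:
        """Assert the no-leakage invariants for this plan."""
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        assert not (train & test), "train and test overlap"
        if self.strategy == "session":
            tr = set(map(tuple, meta.iloc[self.train_idx][["subject_id", "day", "session"]].to_numpy()))
            te = set(map(tuple, meta.iloc[self.test_idx][["subject_id", "day", "session"]].to_numpy()))
            assert not (tr & te), "a session appears on both sides of the split"
        if self.strategy == "subject":
            tr = set(meta.iloc[self.train_idx]["subject_id"])
            te = set(meta.iloc[self.test_idx]["subject_id"])
            assert not (tr & te), "a subject appears on both sides of the split"


def segment_meta(segments: Sequence[Segment]) -> pd.DataFrame:
    """Metadata table (subject_id, day, session, segment_index, label) for a
    list of segments, positionally aligned."""
    return pd.DataFrame(
        {
            "subject_id": [s.provenance[0] for s in segments],
            "day": [s.provenance[1] for s in segments],
            "session": [s.provenance[2] for s in segments],
            "segment_index": [s.provenance[3] for s in segments],
            "label": [int(s.label) for s in segments],
        }
    )


def split_segments(
    meta: pd.DataFrame,
    strategy: str = "segment",
    test_fraction: float = 0.2,
    seed: int = 0,
    repeats: int = 1,
    k_subjects: int = 2,
) -> list[SplitPlan]:
    """Build seed-deterministic train/test split plans over a segment table.

    ``segment``: stratified per class, floor(test_fraction x class n) test
    segments per class.  ``session``: whole sessions, stratified by session
    label.  ``subject``: leave-``k_subjects``-out with ``repeats`` distinct
    draws.  Every returned plan has been leakage-checked.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    rng = np.random.default_rng(seed)
    plans: list[SplitPlan] = []
    if strategy == "segment":
        for rep in range(repeats):
            test_parts = []
            for k in sorted(meta["label"].unique()):
                idx = meta.index[meta["label"] == k].to_numpy()
                n_test = int(np.floor(test_fraction * idx.size))
                test_parts.append(rng.permutation(idx)[:n_test])
            test = np.sort(np.concatenate(test_parts))
            train = np.setdiff1d(meta.index.to_numpy(), test)
            plans.append(SplitPlan(strategy, train, test, seed, rep))
    elif strategy == "session":
        sessions = meta.groupby(["subject_id", "day", "session"], sort=True)["label"].first()
        for rep in range(repeats):
            test_keys: list[tuple] = []
            for k in sorted(sessions.unique()):
                keys = sessions.index[sessions == k].to_numpy()
                n_test = int(np.floor(test_fraction * keys.size))
                chosen = rng.permutation(keys)[:n_test]
                test_keys.extend(map(tuple, chosen))
            key_arr = list(map(tuple, meta[["subject_id", "day", "session"]].to_numpy()))
            mask = np.array([k in set(test_keys) for k in key_arr])
            test = meta.index.to_numpy()[mask]
            train = meta.index.to_numpy()[~mask]
            plans.append(SplitPlan(strategy, train, test, seed, rep))
    else:  # subject
        subjects = np.array(sorted(meta["subject_id"].unique()))
        if subjects.size <= k_subjects:
            raise ValueError(f"need more than {k_subjects} subjects, have {subjects.size}")
        chosen: set[tuple[str, ...]] = set()
        max_combos = len(list(itertools.combinations(range(subjects.size), k_subjects)))
        if repeats > max_combos:
            raise ValueError(f"cannot draw {repeats} distinct subject combinations")
        rep = 0
        while rep < repeats:
            combo = tuple(sorted(rng.choice(subjects, size=k_subjects, replace=False)))
            if combo in chosen:
                continue
            chosen.add(combo)
            mask = meta["subject_id"].isin(combo).to_numpy()
            test = meta.index.to_numpy()[mask]
            train = meta.index.to_numpy()[~mask]
            plans.append(SplitPlan(strategy, train, test, seed, rep, test_subjects=combo))
            rep += 1
    for plan in plans:
        plan.validate(meta)
    return plans


# ---------------------------------------------------------------------------
# cross-validation

FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""A model spec: (X_train, y_train, X_test) -> predicted classes."""


def kfold_cv(model_spec: FitPredict, X: np.ndarray, y: np.ndarray, k: int = 10,
             seed: int = 0) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold cross-validation; each sample is tested exactly once.

    Falls back to unstratified folds with a warning when some class has
    fewer than ``k`` members.  Returns per-fold reports and a summary with
    mean +- sd of accuracy and macro F1.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(y, dtype=int)
    if k > y.size:
        raise ValueError(f"k={k} exceeds dataset size {y.size}")
    min_class = np.bincount(y).min()
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} < k={k} members; "
                      "falling back to non-stratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    reports = []
    for fold, (train, test) in enumerate(folds):
        preds = model_spec(X[train], y[train], X[test])
        reports.append(evaluate_predictions(y[test], preds, split=f"fold{fold}",
                                            n_classes=int(y.max()) + 1))
    accs = np.array([r.accuracy for r in reports])
    f1s = np.array([r.metrics.macro_f1 for r in reports])
    summary = {"accuracy_mean": float(accs.mean()), "accuracy_sd": float(accs.std(ddof=1)),
               "macro_f1_mean": float(f1s.mean()), "macro_f1_sd": float(f1s.std(ddof=1))}
    return reports, summary


# ---------------------------------------------------------------------------
# McNemar

@dataclass
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    p: float
    method: str  # "exact-binomial" or "chi2-cc"


def mcnemar_test(preds_a: np.ndarray, preds_b: np.ndarray, labels: np.ndarray,
                 exact_threshold: int = 25) -> McNemarResult:
    """McNemar's paired test on two classifiers' discordant predictions.

    Uses the exact two-sided binomial tail when ``b + c < exact_threshold``
    (p = min(1, 2 P[X <= min(b, c)]), X ~ Binomial(b+c, 1/2)), otherwise
    the chi-square statistic with continuity correction
    ((|b - c| - 1)^2 / (b + c), 1 df).
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    labels = np.asarray(labels)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction and label arrays must have equal length")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p=1.0, method="exact-binomial")
    if n < exact_threshold:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b=b, c=c, statistic=float(min(b, c)), p=p,
                             method="exact-binomial")
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(b=b, c=c, statistic=float(statistic), p=p, method="chi2-cc")


# ---------------------------------------------------------------------------
# duration sensitivity & ablation

DEFAULT_DURATIONS = (10, 15, 20, 30, 60, 90, 120)

SegmentsModelSpec = Callable[[list[Segment], list[Segment]], np.ndarray]
"""(train segments, test segments) -> predicted classes for the test set."""


def duration_sensitivity(
    manifest: StudyManifest,
    model_spec: SegmentsModelSpec,
    durations: Sequence[float] = DEFAULT_DURATIONS,
    test_fraction: float = 0.2,
    seed: int = 0,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Re-segment the study at several window durations and evaluate the
    same model spec under an identical session-level split.

    The session-to-split assignment is drawn once (stratified by session
    label) and reused for every duration, so only the windowing changes.
    """
    durations = list(durations)
    session_len = min(manifest.load_record(r).duration_s for r in manifest)
    too_long = [d for d in durations if d > session_len]
    if too_long:
        raise ValueError(f"durations {too_long} exceed session length {session_len:.0f} s")
    # fixed session-level assignment, stratified by label
    rows = pd.DataFrame({
        "subject_id": [r.subject_id for r in manifest],
        "day": [r.day for r in manifest],
        "session": [r.session for r in manifest],
        "label": [int(r.label) for r in manifest],
    })
    rng = np.random.default_rng(seed)
    test_keys: set[tuple] = set()
    for k in sorted(rows["label"].unique()):
        sub = rows[rows["label"] == k]
        n_test = int(np.floor(test_fraction * len(sub)))
        chosen = rng.permutation(len(sub))[:n_test]
        for _, r in sub.iloc[chosen].iterrows():
            test_keys.add((r["subject_id"], r["day"], r["session"]))

    results = []
    for duration in durations:
        segments, _ = preprocess_study(manifest, window_s=duration, spec=filter_spec)
        train = [s for s in segments if s.session_key not in test_keys]
        test = [s for s in segments if s.session_key in test_keys]
        preds = model_spec(train, test)
        y_true = np.array([int(s.label) for s in test])
        report = evaluate_predictions(y_true, preds, split=f"session-fixed/{duration}s")
        results.append({"duration_s": duration, "accuracy": report.accuracy,
                        "macro_f1": report.metrics.macro_f1,
                        "macro_precision": report.metrics.macro_precision,
                        "macro_recall": report.metrics.macro_recall,
                        "n_test": len(test)})
    return pd.DataFrame(results)


def run_ablation(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config=None,
    epochs: int | None = None,
) -> dict[str, EvalReport]:
    """Train the full C-BL model and both ablation variants on one split
    with identical data, seed and budget; report side by side."""
    from fatiguecg.cbl import CBLConfig, CBLModel, predict_class, train

    config = config or CBLConfig()
    reports: dict[str, EvalReport] = {}
    for kind in ("cnn_only", "bilstm_only", "full"):
        model = CBLModel(config, kind=kind)
        train(model, X[train_idx], y[train_idx], epochs=epochs)
        preds = predict_class(model, X[test_idx])
        reports[kind] = evaluate_predictions(y[test_idx], preds, split=f"ablation/{kind}")
    return reports


def ablation_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variant": kind, **{k: v for k, v in r.to_dict().items() if k != "confusion_matrix"}}
         for kind, r in reports.items()]
    )
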