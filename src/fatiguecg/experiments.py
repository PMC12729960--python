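"""End-to-end study workflows: the desk-scale evaluation campaign.

These functions tie the whole pipeline together on the default synthetic
study — generation, preprocessing, feature extraction, every classifier
family, split-strategy comparisons, ablations, paired tests — and return
plain dictionaries of the numbers they measured.  They exist so that the
same campaign can be run identically from the test suite, the acceptance
script, and the examples.

Problem sizes (the package's desk-scale defaults): 6 subjects x 4 days
x 3 sessions of 600 s at 200 Hz for the model campaign, 50 single
sessions for the detector benchmark, and 120 epochs for the CNN-BiLSTM
(its loss has plateaued well before that at this data volume; the
published budget of 2000 epochs belongs to the much harder clinical
recordings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fatiguecg.cbl import (
    CBLConfig,
    CBLModel,
    predict_class,
    segments_to_matrix,
    standardize_segments,
    train,
)
from fatiguecg.classifiers import (
    fit_classical,
    fit_rule_based,
    fit_threshold_classifier,
    fit_weighted_score,
    predict_classical,
)
from fatiguecg.data_model import FatigueClass
from fatiguecg.evaluation import (
    evaluate_predictions,
    mcnemar_test,
    segment_meta,
    split_segments,
)
from fatiguecg.hrv import FEATURE_NAMES, features_table, pan_tompkins, rr_from_peaks
from fatiguecg.preprocess import clean_signal, preprocess_study
from fatiguecg.synth import (
    SUBJECT_HR_JITTER_BPM,
    BeatTemplate,
    NoiseParams,
    SynthClassParams,
    default_class_params,
    generate_rr_series,
    generate_study,
    synthesize_ecg,
)

DESK_SUBJECTS = 6
DESK_DAYS = 4
DESK_EPOCHS = 120


def beat_f1(detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.050) -> float:
    """Beat-level F1: greedy one-to-one matching within ``tol_s``."""
    detected = np.sort(np.asarray(detected_s))
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for rt in np.asarray(truth_s):
        if detected.size == 0:
            break
        i = int(np.argmin(np.abs(detected - rt)))
        if not used[i] and abs(detected[i] - rt) <= tol_s:
            used[i] = True
            tp += 1
    fn = len(truth_s) - tp
    fp = detected.size - tp
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def detection_benchmark(seed: int, n_sessions: int = 50,
                        session_duration_s: float = 600.0) -> dict:
    """Pan-Tompkins beat-level F1 vs ground truth on ``n_sessions``
    sessions, rendered both noiseless and with default wearable noise."""
    rng = np.random.default_rng(seed)
    params = list(default_class_params().values())
    scores = {"zero_noise": [], "default_noise": []}
    for _ in range(n_sessions):
        p = params[int(rng.integers(3))]
        jitter = rng.uniform(-SUBJECT_HR_JITTER_BPM, SUBJECT_HR_JITTER_BPM)
        cp = SynthClassParams(p.mean_hr_bpm + jitter, p.sdnn_target_ms,
                              p.lf_hf_ratio, p.rmssd_scale, t_amp_mv=p.t_amp_mv)
        rr = generate_rr_series(cp, session_duration_s, seed=0, rng=rng)
        template = BeatTemplate().with_wave_amplitude("T", p.t_amp_mv)
        for key, noise in (("zero_noise", NoiseParams.silent()),
                           ("default_noise", NoiseParams())):
            rec, truth = synthesize_ecg(rr, fs=200.0, template=template,
                                        noise=noise, rng=rng)
            peaks = pan_tompkins(clean_signal(rec.samples, rec.fs), rec.fs)
            scores[key].append(beat_f1(peaks.times_s, truth.r_times_s))
    return {k: float(np.mean(v)) for k, v in scores.items()}


def _svm_spec(feature_names: list[str]):
    def spec(train_table: pd.DataFrame, test_table: pd.DataFrame) -> np.ndarray:
        model = fit_classical("svm_rbf", train_table,
                              train_table["label"].to_numpy(int),
                              feature_names=feature_names)
        return predict_classical(model, test_table)

    return spec


def split_strategy_benchmark(features: pd.DataFrame, seed: int) -> dict:
    """Mean accuracy of the SVM feature classifier under segment-,
    session- and subject-wise splits, averaged over 5 seeded repeats per
    strategy (leave-2-subjects-out draws for the subject strategy)."""
    spec = _svm_spec(list(FEATURE_NAMES))
    out = {}
    for strategy, repeats in (("segment", 5), ("session", 5), ("subject", 5)):
        accs = []
        for plan in split_segments(features, strategy, seed=seed, repeats=repeats):
            tr = features.iloc[plan.train_idx]
            te = features.iloc[plan.test_idx]
            preds = spec(tr, te)
            accs.append(float((preds == te["label"].to_numpy(int)).mean()))
        out[strategy] = float(np.mean(accs))
    return out


def model_benchmark(seed: int, n_subjects: int = DESK_SUBJECTS, n_days: int = DESK_DAYS,
                    epochs: int = DESK_EPOCHS, with_interpret: bool = True) -> dict:
    """The full desk-scale campaign on one seeded synthetic study.

    Returns every quantity the campaign measures: rejection rate, baseline
    and classical accuracies, C-BL and ablation accuracies on a shared
    stratified segment split, split-strategy accuracies, McNemar paired
    tests of C-BL against each baseline, and per-class Grad-CAM activation
    areas of the trained model.
    """
    results: dict = {"seed": seed, "n_subjects": n_subjects, "n_days": n_days,
                     "epochs": epochs}
    manifest, _ = generate_study(n_subjects=n_subjects, n_days=n_days, seed=seed)
    segments, report = preprocess_study(manifest)
    results["n_segments"] = len(report.entries)
    results["rejection_rate_pct"] = 100.0 * report.rejection_rate

    features, unusable = features_table(segments)
    results["n_unusable"] = len(unusable)
    y_feat = features["label"].to_numpy(int)

    # shared stratified segment split (8:2)
    meta = segment_meta(segments)
    plan = split_segments(meta, "segment", test_fraction=0.2, seed=seed)[0]
    tr_tab, te_tab = features.iloc[plan.train_idx], features.iloc[plan.test_idx]
    y_tr, y_te = y_feat[plan.train_idx], y_feat[plan.test_idx]

    acc = lambda p: float((p == y_te).mean())
    preds: dict[str, np.ndarray] = {}

    # simple baselines
    thr = fit_threshold_classifier(tr_tab, y_tr, "RMSSD")
    preds["threshold_rmssd"] = thr.predict(te_tab)
    # best single feature selected on TRAINING accuracy, evaluated held-out
    best_train, best_model, best_feat = -1.0, None, None
    for name in FEATURE_NAMES:
        m = fit_threshold_classifier(tr_tab, y_tr, name)
        if m.training_accuracy > best_train:
            best_train, best_model, best_feat = m.training_accuracy, m, name
    best_thr_acc = acc(best_model.predict(te_tab))
    results["threshold_best_feature"] = best_feat
    preds["rule"] = fit_rule_based(tr_tab, y_tr).predict(te_tab)
    preds["weighted"] = fit_weighted_score(tr_tab, y_tr).predict(te_tab)

    # classical ML
    for kind in ("logreg", "svm_rbf", "rf"):
        model = fit_classical(kind, tr_tab, y_tr, seed=seed)
        preds[kind] = predict_classical(model, te_tab)

    # C-BL and ablations on the same split, identical seed/budget.
    X, y = segments_to_matrix(segments)
    Xs = standardize_segments(X)
    cbl_models = {}
    for kind in ("full", "cnn_only", "bilstm_only"):
        model = CBLModel(CBLConfig(seed=seed), kind=kind)
        # identical budget and protocol per variant; a 10% stratified
        # validation slice of the training data drives checkpoint selection
        train(model, Xs[plan.train_idx], y[plan.train_idx], epochs=epochs,
              standardized=True, val_fraction=0.1)
        preds[f"cbl_{kind}"] = predict_class(model, Xs[plan.test_idx],
                                             standardized=True)
        cbl_models[kind] = model

    for name, p in preds.items():
        results[f"acc_{name}"] = acc(p)
    results["acc_threshold_best"] = best_thr_acc
    results["report_cbl"] = evaluate_predictions(y_te, preds["cbl_full"],
                                                 split="segment").to_dict()

    # McNemar: C-BL against every baseline on the shared test set
    results["mcnemar"] = {}
    for name in ("threshold_rmssd", "rule", "weighted", "logreg", "svm_rbf", "rf",
                 "cbl_cnn_only", "cbl_bilstm_only"):
        res = mcnemar_test(preds["cbl_full"], preds[name], y_te)
        results["mcnemar"][name] = {"b": res.b, "c": res.c, "p": res.p,
                                    "method": res.method}

    # split-strategy comparison (SVM feature classifier; the ordering
    # probes the leakage structure of the splits)
    results["split_accuracy"] = split_strategy_benchmark(features, seed)

    if with_interpret:
        from fatiguecg.interpret import class_mean_activation_area

        test_segments = [segments[i] for i in plan.test_idx[:120]]
        areas = class_mean_activation_area(cbl_models["full"], test_segments)
        results["activation_area_pct"] = {
            int(k): float(v) for k, v in areas["mean_area_pct"].items()
        }
        results["activation_ordering_holds"] = bool(areas.attrs["ordering_holds"])
    return results


def duration_benchmark(seed: int, durations=(10, 30), n_subjects: int = 3,
                       n_days: int = 2) -> pd.DataFrame:
    """Segment-duration sensitivity with the SVM feature classifier under a
    fixed session-level split (spectral features are dropped below the
    20 s Welch minimum; the time-domain and Poincare features remain)."""
    from fatiguecg.evaluation import duration_sensitivity

    manifest, _ = generate_study(n_subjects=n_subjects, n_days=n_days, seed=seed)
    robust = ["MeanRR", "SDNN", "RMSSD", "pNN50", "MeanHR", "SD1", "SD2"]

    def spec(train_segments, test_segments):
        tr, _ = features_table(train_segments)
        te, _ = features_table(test_segments)
        model = fit_classical("svm_rbf", tr, tr["label"].to_numpy(int),
                              feature_names=robust)
        return predict_classical(model, te)

    return duration_sensitivity(manifest, spec, durations=durations, seed=seed)
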