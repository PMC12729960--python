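"""Metrics, split strategies, cross-validation, McNemar, orchestration."""

import math

import numpy as np
import pandas as pd
import pytest

from fatiguecg.evaluation import (
    EvalReport,
    confusion_matrix,
    duration_sensitivity,
    evaluate_predictions,
    kfold_cv,
    mcnemar_test,
    metrics_from_confusion,
    run_ablation,
    ablation_frame,
    segment_meta,
    split_segments,
)


class TestMetrics:
    def test_binary_accuracy_8896(self):
        """128/143 and 170/192 correct gives 88.96% to two decimals."""
        cm = np.array([[128, 15], [22, 170]])
        assert round(100 * metrics_from_confusion(cm).accuracy, 2) == 88.96

    def test_binary_accuracy_7258(self):
        """140/192 and 138/191 correct gives 72.58%."""
        cm = np.array([[140, 52], [53, 138]])
        assert round(100 * metrics_from_confusion(cm).accuracy, 2) == 72.58

    def test_perfect_diagonal(self):
        m = metrics_from_confusion(np.diag([10, 20, 30]))
        assert (m.accuracy, m.macro_precision, m.macro_recall, m.macro_f1) == (1, 1, 1, 1)

    def test_zero_denominator_warns_and_zeroes(self):
        cm = np.array([[5, 0, 0], [5, 0, 0], [5, 0, 0]])  # classes 1,2 never predicted
        with pytest.warns(UserWarning, match="denominator"):
            m = metrics_from_confusion(cm)
        assert m.per_class.loc[1, "precision"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((3, 3)))

    def test_report_metrics_recomputable_from_stored_cm(self, rng):
        y = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        report = evaluate_predictions(y, p)
        again = metrics_from_confusion(report.cm)
        assert again.accuracy == report.metrics.accuracy
        assert again.macro_f1 == report.metrics.macro_f1


def _meta_from_counts(counts):
    """Minimal metadata table with the requested per-class totals."""
    rows = []
    for k, n in enumerate(counts):
        for i in range(n):
            rows.append({"subject_id": f"s{i % 12}", "day": 1 + (i // 36) % 14,
                         "session": ("morning", "noon", "evening")[i % 3],
                         "segment_index": i, "label": k})
    return pd.DataFrame(rows)


class TestSplits:
    def test_stratified_floor_counts_match_published_split(self):
        """Class totals (719, 963, 958) at 20% give test counts
        (143, 192, 191)."""
        meta = _meta_from_counts([719, 963, 958])
        plan = split_segments(meta, "segment", test_fraction=0.2, seed=0)[0]
        test_labels = meta.iloc[plan.test_idx]["label"]
        assert test_labels.value_counts().sort_index().tolist() == [143, 192, 191]
        assert len(plan.train_idx) + len(plan.test_idx) == 2640

    def test_session_strategy_never_splits_a_session(self, small_segments):
        segments, _ = small_segments
        meta = segment_meta(segments)
        plan = split_segments(meta, "session", seed=4)[0]
        train_keys = set(map(tuple, meta.iloc[plan.train_idx][["subject_id", "day", "session"]].to_numpy()))
        test_keys = set(map(tuple, meta.iloc[plan.test_idx][["subject_id", "day", "session"]].to_numpy()))
        assert train_keys.isdisjoint(test_keys)
        assert test_keys  # non-empty

    def test_subject_strategy_distinct_reproducible_draws(self):
        meta = _meta_from_counts([240, 240, 240])
        plans = split_segments(meta, "subject", seed=3, repeats=5, k_subjects=2)
        combos = [p.test_subjects for p in plans]
        assert len(set(combos)) == 5
        again = split_segments(meta, "subject", seed=3, repeats=5, k_subjects=2)
        assert combos == [p.test_subjects for p in again]

    def test_subject_strategy_requires_enough_subjects(self):
        meta = _meta_from_counts([6, 6, 6]).assign(subject_id="s0")
        with pytest.raises(ValueError):
            split_segments(meta, "subject", k_subjects=2)

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            split_segments(_meta_from_counts([9, 9, 9]), "temporal")


class TestKFold:
    def test_leave_one_out_on_12_items(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.tile([0, 1, 2], 4)
        dummy = lambda Xtr, ytr, Xte: np.zeros(len(Xte), dtype=int)
        with pytest.warns(UserWarning, match="non-stratified"):
            reports, _ = kfold_cv(dummy, X, y, k=12, seed=0)
        assert len(reports) == 12
        assert all(int(r.cm.sum()) == 1 for r in reports)

    def test_folds_partition_dataset(self, rng):
        X = rng.normal(size=(90, 3))
        y = np.tile([0, 1, 2], 30)
        seen = []
        spec = lambda Xtr, ytr, Xte: np.zeros(len(Xte), dtype=int)
        reports, _ = kfold_cv(spec, X, y, k=10, seed=1)
        total = sum(int(r.cm.sum()) for r in reports)
        assert total == 90

    def test_majority_dummy_on_balanced_classes(self, rng):
        """A majority-class dummy scores ~1/3 on balanced three-class data."""
        X = rng.normal(size=(300, 2))
        y = rng.permutation(np.repeat([0, 1, 2], 100))

        def majority(Xtr, ytr, Xte):
            return np.full(len(Xte), np.bincount(ytr).argmax())

        _, summary = kfold_cv(majority, X, y, k=10, seed=2)
        assert summary["accuracy_mean"] == pytest.approx(1 / 3, abs=0.05)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kfold_cv(lambda *a: None, rng.normal(size=(5, 1)), np.zeros(5, dtype=int), k=10)


def _mcnemar_inputs(b, c, n_extra=20):
    """Construct labels/predictions realizing the discordant counts."""
    n = b + c + n_extra
    labels = np.zeros(n, dtype=int)
    preds_a = np.zeros(n, dtype=int)
    preds_b = np.zeros(n, dtype=int)
    preds_b[:b] = 1          # a correct, b wrong
    preds_a[b : b + c] = 1   # a wrong, b correct
    return preds_a, preds_b, labels


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        res = mcnemar_test(*_mcnemar_inputs(5, 5))
        assert (res.b, res.c, res.p) == (5, 5, 1.0)

    def test_exact_closed_form_b10_c0(self):
        res = mcnemar_test(*_mcnemar_inputs(10, 0))
        assert res.method == "exact-binomial"
        assert res.p == pytest.approx(2 * 0.5**10)  # 0.001953125

    def test_chi_square_closed_form_40_10(self):
        res = mcnemar_test(*_mcnemar_inputs(40, 10))
        assert res.method == "chi2-cc"
        assert res.statistic == pytest.approx((abs(40 - 10) - 1) ** 2 / 50)  # 16.82
        assert res.p == pytest.approx(4.1e-5, rel=0.05)

    def test_exact_branch_equals_brute_force_enumeration(self):
        """For all (b, c) with b + c <= 12 the exact p equals a from-scratch
        enumeration of the symmetric binomial tail."""
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                res = mcnemar_test(*_mcnemar_inputs(b, c))
                m = min(b, c)
                tail = sum(math.comb(n, k) for k in range(m + 1)) * 0.5**n
                assert res.p == pytest.approx(min(1.0, 2 * tail), rel=1e-12), (b, c)

    def test_matches_statsmodels_exact(self):
        """Cross-check the exact branch against the statsmodels oracle."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(10, 0), (7, 3), (1, 8), (12, 11)]:
            res = mcnemar_test(*_mcnemar_inputs(b, c))
            table = [[0, b], [c, 0]]
            sm = sm_mcnemar(table, exact=True)
            assert res.p == pytest.approx(float(sm.pvalue), rel=1e-9), (b, c)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar_test(np.zeros(3), np.zeros(4), np.zeros(4))


@pytest.fixture(scope="module")
def tiny_manifest():
    from fatiguecg.synth import generate_study

    manifest, _ = generate_study(n_subjects=2, n_days=2, seed=21,
                                 session_duration_s=240.0)
    return manifest


class TestDurationSensitivity:
    @staticmethod
    def _mean_hr_model(train_segments, test_segments):
        """Cheap model spec: nearest class centroid on MeanHR."""
        from fatiguecg.hrv import features_table

        tr, _ = features_table(train_segments)
        te, _ = features_table(test_segments)
        centroids = tr.groupby("label")["MeanHR"].mean()
        values = te["MeanHR"].to_numpy()[:, None]
        return centroids.index.to_numpy()[
            np.abs(values - centroids.to_numpy()[None, :]).argmin(axis=1)
        ]

    def test_table_structure_and_fixed_split(self, tiny_manifest):
        table = duration_sensitivity(tiny_manifest, self._mean_hr_model,
                                     durations=(30, 60), seed=5)
        assert table["duration_s"].tolist() == [30, 60]
        assert ((table["accuracy"] >= 0) & (table["accuracy"] <= 1)).all()
        # 240 s sessions: 8 windows at 30 s, 4 at 60 s, same 20% of sessions
        assert table["n_test"].iloc[0] == 2 * table["n_test"].iloc[1]

    def test_duration_longer_than_session_rejected(self, tiny_manifest):
        with pytest.raises(ValueError, match="exceed"):
            duration_sensitivity(tiny_manifest, self._mean_hr_model, durations=(300,))


class TestRunAblation:
    def test_reports_share_test_ids_and_serialize(self, tmp_path):
        import sys

        sys.path.insert(0, "tests")
        from test_cbl import _toy_config, _toy_dataset

        X, y = _toy_dataset(n_per_class=20)
        idx = np.arange(len(y))
        train_idx, test_idx = idx[:45], idx[45:]
        reports = run_ablation(X, y, train_idx, test_idx, config=_toy_config(), epochs=2)
        assert set(reports) == {"cnn_only", "bilstm_only", "full"}
        totals = {int(r.cm.sum()) for r in reports.values()}
        assert totals == {len(test_idx)}
        frame = ablation_frame(reports)
        frame.to_csv(tmp_path / "ablation.csv", index=False)
        assert (tmp_path / "ablation.csv").exists() and len(frame) == 3
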