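"""Split strategies, McNemar paired testing, and duration sensitivity.

Demonstrates the evaluation protocol: how accuracy degrades from
segment-wise to session-wise to subject-wise splitting (a leakage
probe), how two classifiers are compared on paired predictions, and how
window duration trades accuracy against responsiveness.
"""

import numpy as np

from fatiguecg import generate_study
from fatiguecg.classifiers import fit_classical, predict_classical
from fatiguecg.evaluation import mcnemar_test, segment_meta, split_segments
from fatiguecg.experiments import duration_benchmark, split_strategy_benchmark
from fatiguecg.hrv import features_table
from fatiguecg.preprocess import preprocess_study

manifest, _ = generate_study(n_subjects=4, n_days=2, seed=7)
segments, _ = preprocess_study(manifest)
table, _ = features_table(segments)
y = table["label"].to_numpy(int)

print("split-strategy comparison (SVM on the 11 HRV features):")
for strategy, a in split_strategy_benchmark(table, seed=0).items():
    print(f"  {strategy:8s}: {100 * a:5.1f}%")
print("  (segment splits may leak within-session structure; subject splits")
print("   must generalise across resting-HR offsets.  On a study this small")
print("   the differences sit inside draw noise -- the full-scale campaign")
print("   in scripts/acceptance.py measures them at 6 subjects x 4 days)")

plan = split_segments(segment_meta(segments), "segment", seed=0)[0]
tr, te = table.iloc[plan.train_idx], table.iloc[plan.test_idx]
y_tr, y_te = y[plan.train_idx], y[plan.test_idx]
svm = predict_classical(fit_classical("svm_rbf", tr, y_tr), te)
rf = predict_classical(fit_classical("rf", tr, y_tr, seed=0), te)
res = mcnemar_test(svm, rf, y_te)
print(f"\nMcNemar SVM vs RF: b={res.b} c={res.c} p={res.p:.4f} ({res.method})")
print("  (b/c count test segments one model gets right and the other wrong;")
print("   a small p says the accuracy difference is systematic, not luck)")

print("\nsegment-duration sensitivity (fixed session split):")
table = duration_benchmark(seed=0, durations=(10, 30, 60))
print(table[["duration_s", "accuracy", "macro_f1", "n_test"]].round(3).to_string(index=False))
print("  (short windows hold too few beats for stable HRV statistics)")
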