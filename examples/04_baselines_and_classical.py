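"""Fit the interpretable baselines and classical ML models.

Trains the single-feature threshold, the MeanRR/RMSSD rule, the
equal-weight score, and the three classical models on a stratified 8:2
segment split, then prints each model's held-out accuracy.
"""

import numpy as np

from fatiguecg import generate_study
from fatiguecg.classifiers import (
    fit_classical,
    fit_rule_based,
    fit_threshold_classifier,
    fit_weighted_score,
    predict_classical,
)
from fatiguecg.evaluation import segment_meta, split_segments
from fatiguecg.hrv import features_table
from fatiguecg.preprocess import preprocess_study

manifest, _ = generate_study(n_subjects=3, n_days=2, seed=7)
segments, _ = preprocess_study(manifest)
table, _ = features_table(segments)
y = table["label"].to_numpy(int)

plan = split_segments(segment_meta(segments), "segment", seed=0)[0]
tr, te = table.iloc[plan.train_idx], table.iloc[plan.test_idx]
y_tr, y_te = y[plan.train_idx], y[plan.test_idx]
acc = lambda p: 100 * float((p == y_te).mean())

thr = fit_threshold_classifier(tr, y_tr, "RMSSD")
rule = fit_rule_based(tr, y_tr)
weighted = fit_weighted_score(tr, y_tr)
print(f"threshold on RMSSD : {acc(thr.predict(te)):5.1f}%  "
      f"(cutoffs {thr.c1:.1f}/{thr.c2:.1f} ms, direction {thr.direction:+d})")
print(f"MeanRR/RMSSD rule  : {acc(rule.predict(te)):5.1f}%")
print("  " + rule.describe().replace("\n", "\n  "))
print(f"weighted z-score   : {acc(weighted.predict(te)):5.1f}%  "
      f"(features {', '.join(weighted.feature_names)})")

for kind in ("logreg", "svm_rbf", "rf"):
    model = fit_classical(kind, tr, y_tr, seed=0)
    print(f"{kind:19s}: {acc(predict_classical(model, te)):5.1f}%")

print("\nHigher numbers mean better three-class fatigue recognition on unseen")
print("segments.  On small synthetic studies the interpretable rules are")
print("already strong, because the classes are built from these very features.")
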