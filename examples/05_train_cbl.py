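"""Train the CNN-BiLSTM raw-signal classifier end to end.

Uses a small study and a reduced epoch budget so the example finishes in
a few minutes on a laptop CPU; the architecture and every published
hyperparameter (32 conv filters, kernel 150, stride 6, pool 5, two
BiLSTM(50) layers, dropout 0.5, Adam at lr 1e-4, batch 120) are the
package defaults.
"""

from fatiguecg import build_cbl, generate_study, predict_class
from fatiguecg.cbl import CBLConfig, segments_to_matrix, train
from fatiguecg.evaluation import evaluate_predictions, segment_meta, split_segments
from fatiguecg.preprocess import preprocess_study

manifest, _ = generate_study(n_subjects=3, n_days=2, seed=7)
segments, _ = preprocess_study(manifest)
X, y = segments_to_matrix(segments)
plan = split_segments(segment_meta(segments), "segment", seed=0)[0]

model = build_cbl(CBLConfig(seed=0))
print("architecture:")
for name, shape in model.shape_report():
    print(f"  {name:32s} {shape}")

trained = train(model, X[plan.train_idx], y[plan.train_idx], epochs=100)
h = trained.history
print(f"\ntrained 100 epochs; loss {h[0]['loss']:.3f} -> {h[-1]['loss']:.3f}, "
      f"training accuracy {h[-1]['accuracy']:.3f}")

preds = predict_class(model, X[plan.test_idx])
report = evaluate_predictions(y[plan.test_idx], preds, split="segment")
print(f"held-out accuracy {100 * report.accuracy:.1f}%  "
      f"macro F1 {report.metrics.macro_f1:.3f}")
print("confusion matrix (rows true, cols predicted):")
print(report.cm)
print("\nThe network reads raw 30 s ECG windows -- no hand-crafted features --")
print("and separates the three fatigue levels from beat timing it learns itself.")
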