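"""Explain the CNN-BiLSTM's decisions with 1-D Grad-CAM.

Trains a small model briefly, computes per-sample relevance curves for
held-out segments, and summarises each class's activation area -- the
share of the cardiac cycle the model attends to.
"""

import numpy as np

from fatiguecg import build_cbl, generate_study
from fatiguecg.cbl import CBLConfig, segments_to_matrix, train
from fatiguecg.evaluation import segment_meta, split_segments
from fatiguecg.interpret import activation_area, class_mean_activation_area, grad_cam_1d
from fatiguecg.preprocess import preprocess_study

manifest, _ = generate_study(n_subjects=3, n_days=2, seed=7)
segments, _ = preprocess_study(manifest)
X, y = segments_to_matrix(segments)
plan = split_segments(segment_meta(segments), "segment", seed=0)[0]

model = build_cbl(CBLConfig(seed=0))
train(model, X[plan.train_idx], y[plan.train_idx], epochs=30)

seg = segments[plan.test_idx[0]]
cam = grad_cam_1d(model, seg, target_class=int(seg.label))
print(f"segment {seg.provenance} (true class {seg.label.name})")
print(f"CAM length {cam.values.size} samples, peak relevance at "
      f"{np.argmax(cam.values) / seg.fs:.2f} s")
print(f"activation area at 0.5 x max: {activation_area(cam):.1f}%")

test_segments = [segments[i] for i in plan.test_idx[:60]]
areas = class_mean_activation_area(model, test_segments)
areas.index = [("normal", "slight", "fatigued")[k] for k in areas.index]
print("\nmean activation area per true class:")
print(areas.round(2).to_string())
print(f"attention-expansion ordering holds: {areas.attrs['ordering_holds']}")
print("\nLarger areas mean the model consults more of the cardiac cycle;")
print("relevance concentrated near R peaks indicates beat-timing cues.")
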