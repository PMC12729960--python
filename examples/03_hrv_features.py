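"""Detect R peaks with Pan-Tompkins and extract the 11 HRV features.

Shows the detector's intermediate stages on one segment, then builds the
per-segment feature table and prints how the class-conditioned HRV
structure (mean HR up, RMSSD down with fatigue) survives the full
signal-processing chain.
"""

from fatiguecg import generate_study, pan_tompkins
from fatiguecg.hrv import features_table
from fatiguecg.preprocess import preprocess_study

manifest, truth = generate_study(n_subjects=2, n_days=2, seed=7)
segments, _ = preprocess_study(manifest)

seg = segments[0]
peaks = pan_tompkins(seg.samples, seg.fs)
print(f"segment {seg.provenance}: {len(peaks)} beats in {seg.duration_s:.0f} s")
print("detector stages cached:", ", ".join(peaks.stages))

table, unusable = features_table(segments)
print(f"\nfeature table: {len(table)} rows x 11 features "
      f"({len(unusable)} unusable segments)")
summary = table.groupby("label")[["MeanHR", "RMSSD", "SDNN", "LF_HF"]].mean().round(1)
summary.index = ["normal", "slight", "fatigued"]
print(summary.to_string())
print("\nMean HR rises and RMSSD falls monotonically across the three fatigue")
print("levels -- the physiological signature the classifiers rely on.")
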