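"""Generate a small synthetic wearable-ECG fatigue study and inspect it.

Builds a 2-subject x 2-day study (twelve 10-minute sessions at 200 Hz),
prints the session labels drawn by the morning/noon/evening class rule,
and shows how the exported ground truth aligns with the rendered signal.
"""

import numpy as np

from fatiguecg import generate_study

manifest, truth = generate_study(n_subjects=2, n_days=2, seed=7)

print(f"study: {len(manifest)} sessions from subjects {manifest.subjects}")
for row in list(manifest)[:6]:
    st = truth[row.session_key]
    print(f"  {row.subject_id} day {row.day} {row.session:8s} "
          f"Borg {row.borg:2d} -> {row.label.name:8s} "
          f"({len(st.r_times_s)} beats, mean RR {st.rr_ms.mean():.0f} ms)")

# ground truth: the R-bump centre of each beat is the true R time
row = manifest.rows[0]
st = truth[row.session_key]
rec = row.record
first_r = st.r_times_s[0]
idx = int(round(first_r * rec.fs))
window = rec.samples[idx - 10 : idx + 10]
print(f"\nfirst true R time {first_r:.3f} s; "
      f"signal peaks at offset {np.argmax(window) - 10} samples from it")
print("Sessions labelled 'fatigued' have higher heart rates (shorter RR) and")
print("damped beat-to-beat variability, mirroring autonomic fatigue responses.")
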