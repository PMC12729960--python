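# Methods

`fatiguecg` classifies short windows of single-lead wearable ECG into three
ordinal fatigue levels (normal < slight fatigue < fatigued) labelled from
Borg RPE 6–20 self-reports. This note records the models, the assumptions
behind them, the defaults that matter, and the design choices made where the
protocol left the design open.

## Labelling

Borg scores map to classes by two cutoffs: scores ≤ 11 are *normal*, 12–14
*slight fatigue*, ≥ 15 *fatigued*. No published cutoff pair exists for this
protocol; the default follows the customary RPE verbal anchors ("light"
effort ends near 11, "hard" begins near 15) and is exposed in
`map_borg_to_class(score, cutoffs)` so other anchorings can be studied. All
segments cut from one 10-minute session share that session's label — the
self-report rates the session, not individual half-minutes.

## Synthetic study generator

The generator emulates the target study design — `n_subjects × n_days × 3`
sessions (morning/noon/evening) of 600 s at 200 Hz — so every downstream
stage is testable without access to clinical recordings.

**RR series.** Beat-to-beat intervals are synthesized in the spectral
domain: three Gaussian bands — 0.015 Hz (VLF, a fixed 35% share of the
total variance: real short-term HRV is VLF-dominated, and the resulting
within-session heart-rate wander keeps one session's segments from being
near-identical copies), plus 0.095 Hz (LF) and 0.275 Hz (HF) —
mid-band of the standard 0.04–0.15 / 0.15–0.4 Hz ranges — with seeded
random phases, inverse-transformed and sampled at successive beat times.
Band powers are set in the ratio `lf_hf_ratio`, the HF band is additionally
damped by `rmssd_scale²`, and the total variance is then normalised to
`sdnn_target_ms²`. Consequently SDNN is exact by construction and the
realized spectral ratio is `lf_hf_ratio / rmssd_scale²`; with the class
defaults this remains monotone in fatigue level. Intervals are clipped to
the physiologic 300–2000 ms gate (a warning reports unreachable SDNN
targets).

**Class defaults** (per session label):

| class    | mean HR (bpm) | SDNN (ms) | LF/HF | rmssd_scale | T amplitude (mV) |
|----------|---------------|-----------|-------|-------------|------------------|
| normal   | 65            | 60        | 1.0   | 1.0         | 0.30             |
| slight   | 80            | 50        | 2.0   | 0.7         | 0.26             |
| fatigued | 95            | 40        | 3.5   | 0.5         | 0.22             |

The directions (HR and LF/HF up, short-term variability and T-wave
amplitude down with fatigue) follow the physiology of sympathetic
activation; the magnitudes are generator choices. Two of them were chosen
deliberately to make the study informative rather than trivial:

- **Subject offsets.** Each subject carries a fixed resting-HR offset drawn
  uniform in ±11 bpm — comparable to the 15 bpm class gaps. This makes
  subject-wise generalisation genuinely harder than segment-wise (the
  leakage phenomenon the split-strategy comparison exists to show) and
  leaves adjacent classes genuinely overlapping on MeanRR alone, while the
  session-level MeanRR distributions remain separated by a little over two
  pooled standard deviations. With much smaller offsets every classifier
  family saturates near 100% and the classifier hierarchy is unobservable.
- **The T-wave cue.** The class-dependent repolarization amplitude is
  morphology information that RR-interval features cannot represent, so
  raw-signal models have something real to gain over the 11 manual
  features — the phenomenon the end-to-end model exists to demonstrate.
  Feature-based models see it only through what it is: nothing.

**ECG rendering.** Each beat is a sum of Gaussian bumps (P, Q, R, S, T)
with lead-II-like default amplitudes (R 1.0 mV, P 0.15 mV; T per class
above); the R-bump centre is the exported ground-truth R time. These
constants are documented defaults, not physiological claims.

**Noise.** Four wearable noise types: a respiratory-drift sinusoid
(0.02 mV at 0.25 Hz), 50 Hz mains pickup (0.015 mV), white noise
(0.01 mV SD), and motion artifacts as 0.5 s raised-cosine bursts at Poisson
times (1/min, 0.4 mV). The continuous levels describe a good chest-attached
recording at seated rest (the emulated protocol measures after 15 min of
rest); motion bursts are the dominant quality hazard and are what the
rejection screen catches. The burst amplitude is deliberately *below* the
5 mV amplitude bound: a screen that only thresholded amplitude would miss
them. What the generator does **not** emulate: arrhythmia and ectopy,
morphology drift across days, electrode impedance changes, or any
subject-specific waveform shape. Passing tests therefore demonstrate that
the pipeline recovers the structure this model encodes — not clinical
performance on real recordings.

Everything is a pure function of (configuration, seed).

## Preprocessing

The cleaning chain is zero-phase throughout so R-peak timing — the raw
material of HRV — is never shifted:

1. **Baseline wander**: forward-backward Butterworth high-pass (order 3) at
   the 0.5 Hz band edge; a running-median (0.6 s) subtraction is available
   as the alternative. At 0.3 Hz the default attenuates by well over 20 dB
   while leaving ≥ 1 Hz content within 1 dB.
2. **Powerline**: centred N-point moving average, default N = 5. Its gain
   is the Dirichlet kernel `|sin(πfN/fs)/(N sin(πf/fs))|`; note that at
   fs = 200 Hz the 5-point average does *not* null 50 Hz — its nulls fall
   at 40 and 80 Hz and the 50 Hz gain is 0.2 (an 80% reduction). N = 4
   would null 50 Hz exactly and is configurable; N = 5 is kept as the
   default for fidelity to the published chain, and the discrepancy is
   deliberate and documented.
3. **Muscle noise**: 0.5–40 Hz Butterworth band-pass, order 4,
   forward-backward.
4. **Artifact rejection**: a segment is rejected if any raw sample exceeds
   5 mV (checked first) or the residual SNR falls below 15 dB, where
   SNR = 10·log₁₀(P_cleaned / P_(raw−cleaned)) with powers taken as
   variances — the absolute offset of a mV recording is arbitrary, so the
   DC the chain removes is not counted as noise. The SNR reference signal
   excludes the moving-average stage: the MA's in-band Dirichlet
   attenuation is deterministic signal distortion, and counting it as noise
   would reject clean recordings. Kept segments still come from the full
   chain.

Windows are non-overlapping and trailing partials are dropped, so a 600 s
session yields exactly 20 segments of 30 s.

## R-peak detection and HRV features

Pan-Tompkins with the classical constants: 5–15 Hz band-pass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds on running signal/noise estimates, 200 ms refractory period, and
search-back at 1.66× the running RR average when a beat is missed. Each
detection is refined to the argmax of the band-passed signal within ±50 ms.
Intermediate stage arrays are retrievable.

Eleven features per segment: MeanRR, SDNN, RMSSD, pNN50, MeanHR (time
domain); LF, HF, LF/HF, HFnorm (frequency domain); SD1, SD2 (Poincaré).
Numerical conventions, stated so oracles are unambiguous: SDNN uses the
population denominator; pNN50 counts successive differences strictly
greater than 50 ms; SD1 = std(ΔRR)/√2 and SD2 = √(2·SDNN² − SD1²), so
SD1² + SD2² = 2·SDNN² holds identically. Frequency features come from a
Hann-tapered Welch periodogram of the tachogram cubic-resampled to 4 Hz
(segment length min(series, 64 s), 50% overlap), integrated over the
standard bands in ms². Spectral estimates are refused below a 20 s span
and carry the usual ultra-short-term caveat below 60 s: on 30 s windows LF
power is statistically weak, one reason raw-signal models can beat
feature models at short durations. RR intervals outside 300–2000 ms are
gated out before any feature is computed.

## Classifiers

**Simple baselines** (fit by exhaustive training-accuracy maximisation with
deterministic tie-breaks — smallest cutoffs, then direction +1):

- *single-feature threshold*: two cutoffs on one feature's axis, both
  orientations searched over midpoints of sorted unique training values;
- *rule template*: fatigued if MeanRR < a and RMSSD < b; normal if
  MeanRR ≥ c and RMSSD ≥ d; else slight (a ≤ c, b ≤ d on quantile grids).
  The template form is this package's construction — only the feature pair
  is inherited;
- *weighted score*: equal-weight mean of sign-aligned z-scores
  (+MeanHR, −RMSSD, +LF/HF by default; the trio is configurable since no
  published list exists), two cutoffs on the score axis.

**Classical ML**: logistic regression and an RBF-kernel SVM (one-vs-rest),
both behind a training-statistics standardizer, and a 500-tree random
forest with a fixed seed — scikit-learn implementations wrapped so
`predict` is self-contained.

## The CNN-BiLSTM (C-BL)

Raw-signal architecture for a 30 s window at 200 Hz (L = 6000):
1-D convolution (32 filters, kernel 150, stride 6) → ReLU → dropout 0.5 →
max-pool 5 → two BiLSTM layers of 50 units → FC 64 (ReLU) → dropout 0.5 →
softmax over 3 classes. Conv length = ⌊(L−150)/6⌋+1 = 976; pooled length
⌊976/5⌋ = 195. Training: cross-entropy, Adam at lr 1e-4, batch 120.

Design points that were genuinely open:

- **BiLSTM "stride 20"** has no standard recurrent meaning. It is realised
  as *strided framing*: each recurrent step consumes a non-overlapping
  window of 20 pooled frames (195 → 9 steps of 20×32 = 640 values), so the
  scan runs at stride 20 without discarding any frame. Temporal decimation
  (keeping every 20th frame) was evaluated and rejected: it discards 95% of
  the conv output and measurably hurt held-out accuracy. The factor is
  configurable; 1 disables framing.
- **Sequence read-out**: the classifier head consumes the concatenation of
  the last forward and first backward hidden states of the second BiLSTM —
  the conventional bidirectional summary.
- **FC width 64 with ReLU** (unstated in the source design; a free choice).
- **Per-segment z-normalisation** of inputs (input scaling was unspecified).
- **Initialisation**: He-scaled normal for the convolution and dense layers
  (both feed ReLUs), uniform ±1/√H for LSTM matrices with forget-gate bias
  1 — standard choices that shorten the low-gradient plateau at lr 1e-4.
- **Epochs**: config default 200 at desk scale; the published budget of
  2000 epochs belongs to the much harder clinical recordings, and on the
  synthetic study the loss plateaus far earlier. The evaluation campaign
  uses 120 (see below).
- **Checkpoint selection**: whether the original training used early
  stopping is unknown (the published accuracy curve suggests a plain fixed
  budget). `train` defaults to plain fixed-budget training; it optionally
  holds out a stratified slice of the *training* data and restores the
  weights with the best validation accuracy. The evaluation campaign
  enables this (10% validation) for all three variants identically,
  because at ~1k-segment scale the full model visibly overfits within the
  budget — its training loss reaches ~0.01 while held-out accuracy decays —
  and reporting the terminal weights would measure the overfitting stage,
  not the model. The test set is never touched during selection.

Ablation variants share the training loop: `cnn_only` (conv block →
flatten → FC head) and `bilstm_only` (max-|x| envelope over the
pool-equivalent factor of 30 samples, centred per segment, then the
recurrent block's stride-20 framing: 200 → 10 steps of 20 → BiLSTM×2 →
head). Max pooling keeps the narrow R spikes a mean would dilute ten-fold;
centring removes the all-positive offset that parks LSTM gates in
saturation (without it the variant sits at chance for hundreds of epochs
at lr 1e-4); naive decimation of raw ECG would alias the R spikes away
entirely. The framing stays with the recurrent block in both models that
contain it — the ablation removes the convolution, not the block's scan
stride.

The network is implemented directly in NumPy — strided-view convolution,
full backpropagation through time, Adam — with gradients verified against
central finite differences in float64. Training is deterministic given the
config seed (shuffling, dropout and initialisation all derive from it).

## Evaluation protocol

Metrics are computed one-vs-rest per class from the stored confusion
matrix and macro-averaged (unweighted over classes, reported alongside the
per-class values); every report can be recomputed from its matrix. Splits:

- *segment*: per-class stratified, test count = ⌊0.2 × class n⌋ (floor —
  this reproduces the published 719/963/958 → 143/192/191 example);
- *session*: whole sessions assigned, so a session's 20 segments never
  straddle the boundary;
- *subject*: leave-2-subjects-out, 5 distinct seeded draws.

Leakage invariants are asserted on every constructed plan. Stratified
10-fold CV falls back to unstratified folds (with a warning) when a class
has fewer members than folds.

**McNemar**: b and c count test items exactly one model classifies
correctly. For b+c < 25 the exact two-sided binomial p =
min(1, 2·P[X ≤ min(b,c)]), X ~ Bin(b+c, ½); otherwise the continuity-
corrected chi-square (|b−c|−1)²/(b+c) on 1 df. The small-sample switch at
25 is this package's choice; the exact branch is cross-checked against
statsmodels and against direct tail enumeration in the tests.

**Duration sensitivity** re-segments the same sessions at several window
lengths under one fixed session-level assignment, so only the windowing
varies.

## The desk-scale campaign

`fatiguecg.experiments.model_benchmark` runs the whole protocol on a
6-subject × 4-day default study (~1330 kept segments) with 120 epochs for
the C-BL and both ablations on a shared stratified split: baseline and
classical accuracies, C-BL/ablation accuracies, McNemar pairings,
split-strategy accuracies (via the SVM feature classifier — the
segment ≥ session ≥ subject ordering probes the leakage structure of the
splits, which is model-agnostic, and five leave-2-out retrainings of the
network would serve no additional purpose), and per-class Grad-CAM
activation areas. The detector benchmark measures beat-level F1 (greedy
one-to-one matching at 50 ms tolerance) on 50 sessions rendered both
noiseless and with default noise.

## Interpretability

1-D Grad-CAM: channel weights are the temporal mean of ∂(class logit)/∂A
over the post-ReLU conv activation maps A; the rectified weighted channel
sum is linearly interpolated from conv-map length to input length and
min-max normalised (an all-zero map stays zero, and the curve is invariant
to positive rescaling of the logits). The *activation area* is the
percentage of samples at or above `rel_threshold × max` (default 0.5,
configurable — no published threshold exists, so absolute areas are not
comparable across implementations; relative per-class orderings are
reported, not asserted).

## Known limitations

- The synthetic classes are far more separable than real fatigue
  physiology; absolute accuracies here say nothing about clinical accuracy.
- Because the synthetic classes are *defined* by HRV parameters, the manual
  features are close to sufficient statistics: an optimal-cutoff score on
  (MeanHR, RMSSD, LF/HF) is already near-Bayes, and feature-based models
  form a ceiling that raw-signal models — which must learn those statistics
  from 1-D samples — do not reliably exceed at desk-scale sample sizes.
  On real recordings the relation inverts because fatigue classes are not a
  clean parametric function of a few features; the campaign's classifier
  ranking on synthetic data therefore probes the pipeline's mechanics, not
  the real-data superiority of end-to-end learning.
- LF estimates on 30 s windows are statistically weak (inherent to
  ultra-short-term HRV); spectral features are refused below a 20 s span
  and reported as NaN by the composed extractor there.
- The 5-point moving average attenuates in-band QRS energy at 200 Hz
  (gain ≈ 0.65 at 20 Hz); it is retained by default for chain fidelity.
- Determinism holds for fixed BLAS/thread settings; across platforms,
  final accuracies may drift within a fraction of a point.
- WFDB reading is not provided; records use the package's plain-CSV
  dialect (`fs=<Hz>` header, one mV sample per line).
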