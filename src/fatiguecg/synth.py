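"""Synthetic multi-subject wearable-ECG study generator with ground truth.

The generator emulates the study design the pipeline targets: 10-minute
single-lead sessions recorded three times daily, with class-conditioned
heart-rate/HRV structure (fatigue raises mean HR and LF/HF, lowers
beat-to-beat variability) and the four wearable noise types (baseline
wander, 50 Hz powerline, white/muscle noise, transient motion artifacts).

RR-interval series are built by inverse-spectrum synthesis: band-limited
Gaussian spectra in the VLF (< 0.04 Hz, a fixed 35% variance share so
heart rate wanders within a session as it does in real short-term
recordings), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands with seeded
random phases, scaled so the total variance matches the SDNN target and
the LF/HF powers sit in the requested ratio.  ``rmssd_scale`` multiplies
the HF band power before the total-variance normalisation, so a lower
value damps fast beat-to-beat variability (lower RMSSD) while SDNN stays
on target; the realized spectral ratio becomes
``lf_hf_ratio / rmssd_scale**2``, still monotone with fatigue.  All
generation is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from fatiguecg.data_model import (
    ECGRecord,
    FatigueClass,
    ManifestRow,
    SESSIONS,
    StudyManifest,
    write_ecg,
)
from fatiguecg.hrv import RRSeries

logger = logging.getLogger(__name__)

LF_CENTER_HZ = 0.095  # mid-band of the standard 0.04-0.15 Hz LF range
HF_CENTER_HZ = 0.275  # mid-band of the standard 0.15-0.4 Hz HF range
LF_WIDTH_HZ = 0.02
HF_WIDTH_HZ = 0.04
VLF_CENTER_HZ = 0.015  # slow autonomic/thermoregulatory wander (< 0.04 Hz)
VLF_WIDTH_HZ = 0.01
#: Fraction of total RR variance carried by the VLF band.  VLF dominates
#: genuine short-term recordings; it also makes heart rate wander within a
#: session, so segments from one session are not near-identical copies.
VLF_FRACTION = 0.35
RR_FLOOR_MS, RR_CEIL_MS = 300.0, 2000.0
_MOD_FS = 4.0  # Hz, sampling rate of the RR modulation waveform


@dataclass(frozen=True)
class SynthClassParams:
    """Physiological targets for one fatigue class.

    ``t_amp_mv`` sets the T-wave amplitude of the beat template: a
    repolarization-morphology cue that falls with sympathetic activation
    and is invisible to RR-interval features — raw-signal models can use
    it, manual HRV features cannot.
    """

    mean_hr_bpm: float
    sdnn_target_ms: float
    lf_hf_ratio: float
    rmssd_scale: float = 1.0
    t_amp_mv: float = 0.30

    def __post_init__(self) -> None:
        if not (30.0 <= self.mean_hr_bpm <= 220.0):
            raise ValueError(f"mean_hr_bpm {self.mean_hr_bpm} outside [30, 220]")
        if self.sdnn_target_ms < 0:
            raise ValueError("sdnn_target_ms must be >= 0")
        if self.lf_hf_ratio <= 0:
            raise ValueError("lf_hf_ratio must be > 0")
        if self.rmssd_scale < 0:
            raise ValueError("rmssd_scale must be >= 0")
        if self.t_amp_mv < 0:
            raise ValueError("t_amp_mv must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Wearable noise model: respiratory drift, 50 Hz mains, white noise,
    and Poisson-timed 0.5 s raised-cosine motion bursts."""

    baseline_amp_mv: float = 0.02
    baseline_freq_hz: float = 0.25
    powerline_amp_mv: float = 0.015
    white_sd_mv: float = 0.01
    artifact_rate_per_min: float = 1.0
    artifact_amp_mv: float = 0.4
    artifact_width_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("baseline_amp_mv", "powerline_amp_mv", "white_sd_mv", "artifact_amp_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.baseline_freq_hz < 1):
            raise ValueError("baseline_freq_hz must lie in (0, 1)")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseParams":
        return cls(0.0, 0.25, 0.0, 0.0, 0.0, 0.0)


#: Per-beat Gaussian bumps (amplitude mV, centre offset s from the R peak,
#: width s).  Constants approximate lead-II morphology; they are documented
#: defaults, not physiological claims.
DEFAULT_BEAT_TEMPLATE: tuple[tuple[str, float, float, float], ...] = (
    ("P", 0.15, -0.20, 0.040),
    ("Q", -0.10, -0.040, 0.012),
    ("R", 1.00, 0.0, 0.012),
    ("S", -0.15, 0.035, 0.012),
    ("T", 0.30, 0.25, 0.070),
)


@dataclass(frozen=True)
class BeatTemplate:
    waves: tuple[tuple[str, float, float, float], ...] = DEFAULT_BEAT_TEMPLATE

    @property
    def r_amplitude(self) -> float:
        return dict((w[0], w[1]) for w in self.waves)["R"]

    def min_width_s(self) -> float:
        return min(w[3] for w in self.waves)

    def with_wave_amplitude(self, name: str, amp: float) -> "BeatTemplate":
        return BeatTemplate(tuple(
            (n, amp if n == name else a, off, w) for n, a, off, w in self.waves
        ))


@dataclass
class SessionTruth:
    """Ground truth for one synthesized session."""

    r_times_s: np.ndarray
    rr_ms: np.ndarray
    label: FatigueClass
    template: BeatTemplate

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_times_s) <= 0):
            raise ValueError("ground-truth R times must be strictly increasing")


@dataclass
class GroundTruth:
    """Ground truth for a whole study, keyed by (subject_id, day, session)."""

    sessions: dict[tuple[str, int, str], SessionTruth] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, int, str]) -> SessionTruth:
        return self.sessions[key]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "|".join(map(str, key)): {
                "r_times_s": st.r_times_s.tolist(),
                "rr_ms": st.rr_ms.tolist(),
                "label": int(st.label),
            }
            for key, st in self.sessions.items()
        }
        Path(path).write_text(json.dumps(payload))


def default_class_params() -> dict[FatigueClass, SynthClassParams]:
    """Default class-conditioned targets.

    Fatigue raises mean HR and the LF/HF balance, damps beat-to-beat
    variability, and flattens the T wave (repolarization change under
    sympathetic activation).  Combined with the per-subject resting-HR
    offsets, the HR targets leave the session-level MeanRR distributions
    separated by a little over two pooled standard deviations — overlapping
    enough that no single RR statistic is sufficient, which is what makes
    the classifier hierarchy observable.
    """
    return {
        FatigueClass.normal: SynthClassParams(65.0, 60.0, 1.0, 1.0, t_amp_mv=0.30),
        FatigueClass.slight: SynthClassParams(80.0, 50.0, 2.0, 0.7, t_amp_mv=0.26),
        FatigueClass.fatigued: SynthClassParams(95.0, 40.0, 3.5, 0.5, t_amp_mv=0.22),
    }


def _band_waveform(freqs: np.ndarray, center: float, width: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance band-limited noise from a Gaussian spectral envelope."""
    shape = np.exp(-0.5 * ((freqs - center) / width) ** 2)
    shape[0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = np.sqrt(shape) * np.exp(1j * phases)
    wave = np.fft.irfft(spectrum, n=n)
    sd = wave.std()
    if sd < 1e-15:
        return np.zeros(n)
    return wave / sd


def generate_rr_series(
    params: SynthClassParams,
    duration_s: float,
    seed: int,
    rng: np.random.Generator | None = None,
) -> RRSeries:
    """Generate an RR-interval series with the requested HR/HRV structure.

    The RR modulation is synthesized in the spectral domain (VLF, LF and
    HF Gaussian bands with seeded random phases), scaled to the SDNN
    target, and sampled at the successive beat times.  Identical
    (params, duration, seed) give identical output.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    mean_rr_ms = 60000.0 / params.mean_hr_bpm

    n_mod = int(np.ceil(duration_s * _MOD_FS)) + 1
    tgrid = np.arange(n_mod) / _MOD_FS
    freqs = np.fft.rfftfreq(n_mod, d=1.0 / _MOD_FS)
    vlf_unit = _band_waveform(freqs, VLF_CENTER_HZ, VLF_WIDTH_HZ, rng, n_mod)
    lf_unit = _band_waveform(freqs, LF_CENTER_HZ, LF_WIDTH_HZ, rng, n_mod)
    hf_unit = _band_waveform(freqs, HF_CENTER_HZ, HF_WIDTH_HZ, rng, n_mod)

    # Band powers: a fixed VLF share of the total variance, the remainder
    # split LF:HF = lf_hf_ratio before the rmssd_scale damping of HF; total
    # variance is then normalised to the SDNN target.
    p_lf = params.lf_hf_ratio
    p_hf = params.rmssd_scale**2
    norm = p_lf + p_hf
    rest = 1.0 - VLF_FRACTION
    a_vlf = params.sdnn_target_ms * np.sqrt(VLF_FRACTION)
    a_lf = params.sdnn_target_ms * np.sqrt(rest * p_lf / norm)
    a_hf = params.sdnn_target_ms * np.sqrt(rest * p_hf / norm)
    modulation = a_vlf * vlf_unit + a_lf * lf_unit + a_hf * hf_unit

    rr: list[float] = []
    times: list[float] = []
    t = 0.0
    while t < duration_s:
        m = float(np.interp(t, tgrid, modulation))
        interval = mean_rr_ms + m
        clipped = min(max(interval, RR_FLOOR_MS), RR_CEIL_MS)
        rr.append(clipped)
        t += clipped / 1000.0
        times.append(t)
    rr_arr = np.array(rr)
    times_arr = np.array(times)
    if params.sdnn_target_ms > 0:
        realized_sd = rr_arr.std()
        if abs(realized_sd - params.sdnn_target_ms) > 0.5 * params.sdnn_target_ms:
            warnings.warn(
                f"SDNN target {params.sdnn_target_ms:.1f} ms not reachable after "
                f"physiologic clipping; realized {realized_sd:.1f} ms",
                stacklevel=2,
            )
    return RRSeries(values_ms=rr_arr, times_s=times_arr)


def synthesize_ecg(
    rr: RRSeries,
    fs: float,
    template: BeatTemplate | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[ECGRecord, SessionTruth]:
    """Render an ECG waveform from an RR series as per-beat Gaussian bumps.

    The R-bump centre of each beat is the ground-truth R time.  Noise terms
    (baseline drift sinusoid, 50 Hz mains, white noise, raised-cosine motion
    bursts at Poisson times) are added per ``noise``.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz to resolve the QRS complex")
    template = template or BeatTemplate()
    noise = noise or NoiseParams.silent()
    if rng is None:
        rng = np.random.default_rng(seed)
    if template.min_width_s() * fs < 0.75:  # narrowest bump must span >= 3 samples at +-2 sigma
        raise ValueError(
            f"fs={fs} too low: narrowest template bump ({template.min_width_s()} s) "
            f"spans {4 * template.min_width_s() * fs:.1f} < 3 samples"
        )

    # R times: first beat placed after the first interval so every R bump is
    # fully inside the record.
    r_times = rr.times_s
    duration = float(r_times[-1] + 0.4)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    clean = np.zeros(n)
    for _, amp, offset, width in template.waves:
        half = int(np.ceil(4 * width * fs))
        kernel_t = np.arange(-half, half + 1) / fs
        kernel = amp * np.exp(-0.5 * (kernel_t / width) ** 2)
        centers = np.round((r_times + offset) * fs).astype(int)
        for c in centers:
            lo, hi = c - half, c + half + 1
            klo = max(0, -lo)
            khi = kernel.size - max(0, hi - n)
            lo, hi = max(lo, 0), min(hi, n)
            if lo < hi:
                clean[lo:hi] += kernel[klo:khi]

    signal = clean.copy()
    if noise.baseline_amp_mv > 0:
        signal += noise.baseline_amp_mv * np.sin(
            2 * np.pi * noise.baseline_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp_mv > 0:
        signal += noise.powerline_amp_mv * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if noise.white_sd_mv > 0:
        signal += rng.normal(0.0, noise.white_sd_mv, size=n)
    if noise.artifact_rate_per_min > 0 and noise.artifact_amp_mv > 0:
        n_bursts = rng.poisson(noise.artifact_rate_per_min * duration / 60.0)
        width_n = max(int(round(noise.artifact_width_s * fs)), 3)
        burst = np.hanning(width_n)
        for _ in range(n_bursts):
            start = int(rng.uniform(0, max(n - width_n, 1)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            stop = min(start + width_n, n)
            signal[start:stop] += sign * noise.artifact_amp_mv * burst[: stop - start]

    record = ECGRecord(samples=signal, fs=fs)
    truth = SessionTruth(
        r_times_s=r_times.copy(), rr_ms=np.diff(r_times) * 1000.0, label=FatigueClass.normal,
        template=template,
    )
    return record, truth


#: Session-to-class probabilities for the default daily pattern: mornings are
#: normal-biased, evenings fatigued-biased, with stochastic mixing.
DEFAULT_SESSION_CLASS_RULE: dict[str, tuple[float, float, float]] = {
    "morning": (0.70, 0.20, 0.10),
    "noon": (0.20, 0.50, 0.30),
    "evening": (0.10, 0.30, 0.60),
}

_BORG_RANGE_BY_CLASS = {
    FatigueClass.normal: (6, 11),
    FatigueClass.slight: (12, 14),
    FatigueClass.fatigued: (15, 20),
}

#: Uniform half-width (bpm) of the per-subject resting-HR offset.  Chosen
#: comparable to the 15 bpm class gaps so subject-wise generalisation is
#: genuinely harder than segment-wise and adjacent classes genuinely
#: overlap on MeanRR alone, while session-level MeanRR classes stay
#: separated by more than two pooled standard deviations.
SUBJECT_HR_JITTER_BPM = 11.0


def generate_study(
    n_subjects: int = 12,
    n_days: int = 14,
    class_params_by_class: Mapping[FatigueClass, SynthClassParams] | None = None,
    noise: NoiseParams | None = None,
    session_class_rule: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    fs: float = 200.0,
    session_duration_s: float = 600.0,
    template: BeatTemplate | None = None,
) -> tuple[StudyManifest, GroundTruth]:
    """Generate a full synthetic study: ``n_subjects x n_days x 3 sessions``.

    Each session is ``session_duration_s`` seconds at ``fs``; the fatigue
    class of each (day, session) is drawn from ``session_class_rule`` and
    the Borg self-report is drawn uniformly from that class's score range.
    Subjects carry a fixed uniform resting-HR offset so subject-wise splits
    are harder than segment-wise ones.  Deterministic given the seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    class_params = dict(class_params_by_class or default_class_params())
    noise = NoiseParams() if noise is None else noise
    rule = dict(session_class_rule or DEFAULT_SESSION_CLASS_RULE)
    template = template or BeatTemplate()
    rng = np.random.default_rng(seed)

    rows: list[ManifestRow] = []
    truth = GroundTruth()
    for si in range(n_subjects):
        subject_id = f"s{si + 1:02d}"
        hr_offset = rng.uniform(-SUBJECT_HR_JITTER_BPM, SUBJECT_HR_JITTER_BPM)
        for day in range(1, n_days + 1):
            for session in SESSIONS:
                probs = np.asarray(rule[session], dtype=float)
                label = FatigueClass(int(rng.choice(3, p=probs / probs.sum())))
                lo, hi = _BORG_RANGE_BY_CLASS[label]
                borg = int(rng.integers(lo, hi + 1))
                base = class_params[label]
                params = SynthClassParams(
                    mean_hr_bpm=base.mean_hr_bpm + hr_offset,
                    sdnn_target_ms=base.sdnn_target_ms,
                    lf_hf_ratio=base.lf_hf_ratio,
                    rmssd_scale=base.rmssd_scale,
                    t_amp_mv=base.t_amp_mv,
                )
                rr = generate_rr_series(params, session_duration_s, seed=0, rng=rng)
                session_template = template.with_wave_amplitude("T", base.t_amp_mv)
                record, session_truth = synthesize_ecg(
                    rr, fs=fs, template=session_template, noise=noise, rng=rng
                )
                record.subject_id, record.day, record.session = subject_id, day, session
                record.borg_score = borg
                session_truth.label = label
                rows.append(
                    ManifestRow(
                        subject_id=subject_id, day=day, session=session, borg=borg,
                        record=record,
                    )
                )
                truth.sessions[(subject_id, day, session)] = session_truth
    return StudyManifest(rows), truth


def write_study(manifest: StudyManifest, truth: GroundTruth, out_dir: str | Path) -> Path:
    """Write a generated study to disk as CSV records + manifest + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for row in manifest:
        fname = f"{row.subject_id}_d{row.day:02d}_{row.session}.csv"
        write_ecg(out / fname, row.record)
        row.path = fname
    manifest.save(out / "manifest.csv")
    truth.to_json(out / "ground_truth.json")
    return out / "manifest.csv"
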