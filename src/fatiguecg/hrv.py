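"""Pan-Tompkins R-peak detection and the 11 ultra-short-term HRV features.

The QRS detector follows the classical Pan-Tompkins stages: 5-15 Hz
bandpass, five-point derivative, pointwise squaring, 150 ms moving-window
integration, adaptive dual thresholds with a 200 ms refractory period and
a 1.66x-RR search-back for missed beats.  Detected peaks are refined to
the local maximum of the bandpassed signal.  Intermediate stage arrays
are retrievable for inspection and testing.

Features (11): MeanRR, SDNN, RMSSD, pNN50, MeanHR (time domain); LF, HF,
LF/HF, HFnorm (Welch periodogram of the cubic-resampled tachogram over
the standard 0.04-0.15 / 0.15-0.4 Hz bands, in ms^2); SD1, SD2 (Poincare
plot axes).  SDNN uses the population denominator so independent oracle
implementations are unambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from fatiguecg.data_model import FatigueClass, Segment

logger = logging.getLogger(__name__)

RR_FLOOR_MS, RR_CEIL_MS = 300.0, 2000.0
REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150
SEARCHBACK_FACTOR = 1.66
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

FEATURE_NAMES = (
    "MeanRR", "SDNN", "RMSSD", "pNN50", "MeanHR",
    "LF", "HF", "LF_HF", "HFnorm", "SD1", "SD2",
)


class UnusableSegmentError(ValueError):
    """Raised when a segment does not contain enough detectable beats."""


@dataclass
class RPeakSeries:
    """Detected R-peak sample indices and times for one signal."""

    indices: np.ndarray
    fs: float
    stages: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RRSeries:
    """Successive RR intervals (ms) with the time of each interval's end."""

    values_ms: np.ndarray
    times_s: np.ndarray
    n_gated: int = 0

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(self.values_ms <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.values_ms)

    @property
    def span_s(self) -> float:
        if len(self.times_s) < 2:
            return 0.0
        return float(self.times_s[-1] - self.times_s[0])


@dataclass
class HRVFeatures:
    """The 11 scalar HRV features for one segment."""

    MeanRR: float
    SDNN: float
    RMSSD: float
    pNN50: float
    MeanHR: float
    LF: float
    HF: float
    LF_HF: float
    HFnorm: float
    SD1: float
    SD2: float
    provenance: tuple[str, int, str, int] | None = None
    label: FatigueClass | None = None

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _local_maxima(x: np.ndarray, min_distance: int) -> np.ndarray:
    peaks, _ = sps.find_peaks(x, distance=max(min_distance, 1))
    return peaks


def pan_tompkins(samples: np.ndarray, fs: float) -> RPeakSeries:
    """Detect R peaks with the Pan-Tompkins algorithm.

    Returns the peak series with intermediate stage arrays (``bandpassed``,
    ``derivative``, ``squared``, ``integrated``) stored in ``stages``.
    A flat (zero-variance) input yields an empty peak list with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) < 1e-12:
        warnings.warn("flat input signal: no peaks detected", stacklevel=2)
        return RPeakSeries(indices=np.array([], dtype=int), fs=fs)

    sos = sps.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)

    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv**2
    win = max(int(round(INTEGRATION_WINDOW_S * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    candidates = _local_maxima(integrated, refractory)
    if candidates.size == 0:
        return RPeakSeries(indices=np.array([], dtype=int), fs=fs,
                           stages={"bandpassed": bp, "derivative": deriv,
                                   "squared": squared, "integrated": integrated})

    # Adaptive dual thresholds on the running signal/noise peak estimates.
    head = integrated[: int(2 * fs)]
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(head.mean())
    detections: list[int] = []
    rr_history: list[float] = []
    last_det_candidate = -1  # index into `candidates` of the last detection

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < candidates.size:
        idx = candidates[i]
        peak = integrated[idx]
        if peak > threshold1():
            spki = 0.125 * peak + 0.875 * spki
            detections.append(idx)
            if len(detections) >= 2:
                rr_history.append((detections[-1] - detections[-2]) / fs)
                rr_history = rr_history[-8:]
            last_det_candidate = i
        else:
            npki = 0.125 * peak + 0.875 * npki
            # Search-back: if the gap since the last detection exceeds
            # 1.66x the running RR average, re-examine skipped candidates
            # at half threshold.
            if detections and rr_history:
                rr_avg = float(np.mean(rr_history))
                if (idx - detections[-1]) / fs > SEARCHBACK_FACTOR * rr_avg:
                    window = candidates[last_det_candidate + 1 : i + 1]
                    above = window[integrated[window] > 0.5 * threshold1()]
                    if above.size:
                        best = int(above[np.argmax(integrated[above])])
                        spki = 0.25 * integrated[best] + 0.75 * spki
                        detections.append(best)
                        detections.sort()
                        if len(detections) >= 2:
                            rr_history.append((detections[-1] - detections[-2]) / fs)
                            rr_history = rr_history[-8:]
                        last_det_candidate = i
        i += 1

    # Refine each detection to the argmax of the bandpassed signal within
    # +-50 ms, then enforce the refractory period (keep the larger peak).
    half = int(round(0.050 * fs))
    refined: list[int] = []
    for idx in detections:
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = sorted(set(refined))
    kept: list[int] = []
    for idx in refined:
        if kept and (idx - kept[-1]) < refractory:
            if bp[idx] > bp[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)

    return RPeakSeries(
        indices=np.array(kept, dtype=int), fs=fs,
        stages={"bandpassed": bp, "derivative": deriv, "squared": squared,
                "integrated": integrated},
    )


def rr_from_peaks(peaks: RPeakSeries) -> RRSeries:
    """Successive RR intervals (ms) from detected peaks.

    Intervals outside the physiologic [300, 2000] ms gate are removed and
    counted in ``n_gated``.
    """
    if len(peaks) < 2:
        raise ValueError("insufficient beats: need >= 2 peaks to form RR intervals")
    times = peaks.times_s
    rr = np.diff(times) * 1000.0
    keep = (rr >= RR_FLOOR_MS) & (rr <= RR_CEIL_MS)
    n_gated = int((~keep).sum())
    if n_gated:
        logger.debug("gated %d RR intervals outside [%g, %g] ms", n_gated, RR_FLOOR_MS, RR_CEIL_MS)
    return RRSeries(values_ms=rr[keep], times_s=times[1:][keep], n_gated=n_gated)


class TimeDomain(NamedTuple):
    MeanRR: float
    SDNN: float
    RMSSD: float
    pNN50: float
    MeanHR: float


def time_domain_features(rr: RRSeries) -> TimeDomain:
    """MeanRR, SDNN (population), RMSSD, pNN50 (>50 ms), MeanHR."""
    v = rr.values_ms
    if v.size < 2:
        raise ValueError("need at least 2 RR intervals")
    d = np.diff(v)
    mean_rr = float(v.mean())
    return TimeDomain(
        MeanRR=mean_rr,
        SDNN=float(v.std()),
        RMSSD=float(np.sqrt(np.mean(d**2))),
        pNN50=float(100.0 * np.mean(np.abs(d) > 50.0)),
        MeanHR=60000.0 / mean_rr,
    )


class FrequencyDomain(NamedTuple):
    LF: float
    HF: float
    LF_HF: float
    HFnorm: float


def frequency_domain_features(
    rr: RRSeries,
    resample_hz: float = 4.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> FrequencyDomain:
    """Welch band powers (ms^2) of the uniformly resampled RR tachogram.

    The tachogram is cubic-interpolated to ``resample_hz``, mean-removed,
    and analysed with a Hann-tapered Welch periodogram (segment length
    ``min(series, 64 s)``, 50% overlap).  Series spanning less than 60 s
    carry the usual ultra-short-term caveat (logged); below 20 s the
    estimate is refused.
    """
    if rr.span_s < 20.0:
        raise ValueError(f"series spans {rr.span_s:.1f} s; need >= 20 s for spectral analysis")
    if rr.span_s < 60.0:
        logger.debug("ultra-short-term spectral estimate on %.1f s of data", rr.span_s)
    t = rr.times_s
    v = rr.values_ms
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = CubicSpline(t, v)(grid)
    tach = tach - tach.mean()
    nperseg = min(tach.size, int(64 * resample_hz))
    freqs, psd = sps.welch(tach, fs=resample_hz, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant")
    lf_mask = (freqs >= lf_band[0]) & (freqs < lf_band[1])
    hf_mask = (freqs >= hf_band[0]) & (freqs < hf_band[1])
    lf = float(np.trapezoid(psd[lf_mask], freqs[lf_mask]))
    hf = float(np.trapezoid(psd[hf_mask], freqs[hf_mask]))
    if hf <= 0:
        if lf > 0:
            warnings.warn("HF power is zero; LF/HF reported as +inf", stacklevel=2)
            ratio = float("inf")
        else:
            ratio = 0.0
        hfnorm = 0.0 if (lf + hf) <= 0 else 100.0 * hf / (lf + hf)
    else:
        ratio = lf / hf
        hfnorm = 100.0 * hf / (lf + hf)
    return FrequencyDomain(LF=lf, HF=hf, LF_HF=ratio, HFnorm=hfnorm)


class Poincare(NamedTuple):
    SD1: float
    SD2: float


def poincare_features(rr: RRSeries) -> Poincare:
    """Poincare short/long-axis dispersions: SD1 = std(diff)/sqrt(2),
    SD2 = sqrt(max(0, 2*SDNN^2 - SD1^2))."""
    v = rr.values_ms
    if v.size < 3:
        raise ValueError("need at least 3 RR intervals for Poincare features")
    d = np.diff(v)
    sd1 = float(d.std() / np.sqrt(2.0))
    sdnn = float(v.std())
    sd2 = float(np.sqrt(max(0.0, 2.0 * sdnn**2 - sd1**2)))
    return Poincare(SD1=sd1, SD2=sd2)


def extract_features(segment: Segment) -> HRVFeatures:
    """Compute the 11-feature HRV vector for one segment.

    Raises :class:`UnusableSegmentError` when fewer than 4 beats are
    detected; segments are never silently zero-filled.
    """
    peaks = pan_tompkins(segment.samples, segment.fs)
    if len(peaks) < 4:
        raise UnusableSegmentError(
            f"segment {segment.provenance}: only {len(peaks)} beats detected (need >= 4)"
        )
    rr = rr_from_peaks(peaks)
    if len(rr) < 3:
        raise UnusableSegmentError(
            f"segment {segment.provenance}: only {len(rr)} usable RR intervals after gating"
        )
    td = time_domain_features(rr)
    if rr.span_s >= 20.0:
        fd = frequency_domain_features(rr)
    else:
        # Windows below the 20 s spectral minimum keep the time-domain and
        # Poincare features; band powers are reported as NaN, not zero.
        logger.debug("segment %s spans %.1f s; spectral features unavailable",
                     segment.provenance, rr.span_s)
        fd = FrequencyDomain(LF=float("nan"), HF=float("nan"),
                             LF_HF=float("nan"), HFnorm=float("nan"))
    pc = poincare_features(rr)
    return HRVFeatures(
        MeanRR=td.MeanRR, SDNN=td.SDNN, RMSSD=td.RMSSD, pNN50=td.pNN50, MeanHR=td.MeanHR,
        LF=fd.LF, HF=fd.HF, LF_HF=fd.LF_HF, HFnorm=fd.HFnorm,
        SD1=pc.SD1, SD2=pc.SD2,
        provenance=segment.provenance, label=segment.label,
    )


def features_table(segments) -> tuple["pd.DataFrame", list[tuple]]:
    """Feature rows for a list of segments; unusable segments are skipped
    and their provenances returned separately."""
    import pandas as pd

    rows, unusable = [], []
    for seg in segments:
        try:
            f = extract_features(seg)
        except UnusableSegmentError:
            unusable.append(seg.provenance)
            continue
        rec = {name: getattr(f, name) for name in FEATURE_NAMES}
        rec["subject_id"], rec["day"], rec["session"], rec["segment_index"] = seg.provenance
        rec["label"] = int(seg.label)
        rows.append(rec)
    return pd.DataFrame(rows), unusable
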