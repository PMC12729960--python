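"""1-D Grad-CAM for the CNN-BiLSTM model and the activation-area statistic.

Gradient-weighted class activation mapping localises the input regions
driving a class score: channel weights are the temporal mean of the
gradient of the target-class logit w.r.t. the convolutional activation
maps; the rectified weighted channel sum is linearly interpolated back
to input length and min-max normalised to [0, 1].  The *activation area*
of a CAM is the percentage of samples at or above a relative threshold
(default 0.5 x max) -- a compact measure of how much of the cardiac
cycle the model attends to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fatiguecg.cbl import CBLModel, TrainedModel, standardize_segments
from fatiguecg.data_model import Segment
from fatiguecg.nn import F32


@dataclass
class CAMCurve:
    """Per-sample relevance in [0, 1] for one segment and target class."""

    values: np.ndarray
    target_class: int
    provenance: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < 0:
            raise ValueError("CAM values must be >= 0")
        if self.values.size and self.values.max() > 1 + 1e-9:
            raise ValueError("CAM values must be <= 1")


def _unwrap(model) -> CBLModel:
    return model.model if isinstance(model, TrainedModel) else model


def grad_cam_1d(model, segment: Segment | np.ndarray, target_class: int) -> CAMCurve:
    """Grad-CAM relevance curve for one segment.

    Requires a model with a convolutional block (the ``bilstm_only``
    variant is rejected).  An all-zero CAM (e.g. zero gradients) stays
    all-zero rather than being normalised.
    """
    net = _unwrap(model)
    if net.conv is None:
        raise ValueError("unsupported architecture: Grad-CAM needs a convolutional block")
    if isinstance(segment, Segment):
        x = segment.samples[None, :]
        provenance = segment.provenance
    else:
        x = np.asarray(segment, dtype=float)[None, :]
        provenance = None
    n_in = x.shape[1]
    x = standardize_segments(x)
    logits = net.forward(x, train=False)
    if not (0 <= target_class < logits.shape[1]):
        raise ValueError(f"target_class {target_class} out of range")
    onehot = np.zeros_like(logits)
    onehot[0, target_class] = 1.0
    for p in net.params():
        p.grad[...] = 0.0
    d_act = net.backward(onehot.astype(F32), to_conv_activation=True)  # (1, T, F)
    activation = net._conv_activation[0]  # (T, F)
    weights = d_act[0].mean(axis=0)  # temporal mean per channel
    cam = np.maximum(activation @ weights, 0.0)
    # upsample from conv-map length to input length
    t_conv = np.linspace(0.0, 1.0, cam.size)
    t_in = np.linspace(0.0, 1.0, n_in)
    cam_full = np.interp(t_in, t_conv, cam)
    peak = cam_full.max()
    if peak > 0:
        cam_full = cam_full / peak
    return CAMCurve(values=cam_full, target_class=int(target_class), provenance=provenance)


def activation_area(cam: CAMCurve, rel_threshold: float = 0.5) -> float:
    """Percentage of samples with relevance >= rel_threshold x max.

    Monotone non-increasing in the threshold; an all-zero CAM has area 0.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    v = cam.values
    peak = v.max() if v.size else 0.0
    if peak <= 0:
        return 0.0
    return float(100.0 * np.mean(v >= rel_threshold * peak))


def class_mean_activation_area(model, segments: list[Segment],
                               rel_threshold: float = 0.5) -> pd.DataFrame:
    """Mean activation area per true class, with the attention-expansion
    ordering (normal <= slight <= fatigued) reported, not asserted."""
    net = _unwrap(model)
    per_class: dict[int, list[float]] = {0: [], 1: [], 2: []}
    for seg in segments:
        cam = grad_cam_1d(net, seg, target_class=int(seg.label))
        per_class[int(seg.label)].append(activation_area(cam, rel_threshold))
    rows = []
    for k in sorted(per_class):
        areas = per_class[k]
        if not areas:
            warnings.warn(f"class {k} has no segments; excluded", stacklevel=2)
            continue
        rows.append({"class": k, "mean_area_pct": float(np.mean(areas)), "n": len(areas)})
    df = pd.DataFrame(rows).set_index("class")
    means = df["mean_area_pct"]
    df.attrs["ordering_holds"] = bool(np.all(np.diff(means.to_numpy()) >= 0))
    return df
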