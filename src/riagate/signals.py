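"""Per-frame signal derivations: normalization, asymmetry, velocity, posture.

Fluorescence traces are min-max normalized over the full recording,
(F_t - F_min) / (F_max - F_min).  The nerve-ring asymmetry dnr is the
difference of the normalized compartment traces, nrV - nrD.  Head
orientation is normalized per animal by its maximal absolute deflection,
so the bent/unbent cut at 0.5 means "more than half the maximal degree of
head deflection".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BENT_THRESHOLD = 0.5


@dataclass
class NormalizedTrace:
    """A min-max normalized fluorescence trace with its scaling constants."""

    values: np.ndarray
    label: str = ""
    f_min: float = 0.0
    f_max: float = 1.0

    def __len__(self) -> int:
        return len(self.values)


def _values(trace) -> np.ndarray:
    if isinstance(trace, NormalizedTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def normalize_trace(raw, label: str = "") -> NormalizedTrace:
    """Min-max normalize a raw trace: (F_t - F_min) / (F_max - F_min).

    F_min and F_max are taken over the whole recording, so the output
    attains both 0 and 1.  Constant traces have zero dynamic range and are
    rejected.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(raw)):
        raise ValueError("trace contains non-finite values")
    f_min, f_max = float(raw.min()), float(raw.max())
    if f_max <= f_min:
        raise ValueError("constant trace has zero dynamic range")
    return NormalizedTrace((raw - f_min) / (f_max - f_min), label, f_min, f_max)


def compute_dnr(nrV, nrD) -> np.ndarray:
    """Nerve-ring asymmetry dnr = nrV - nrD (normalized traces), in [-1, 1]."""
    v, d = _values(nrV), _values(nrD)
    if v.shape != d.shape:
        raise ValueError("nrV and nrD must have equal length")
    return v - d


def head_velocity(theta, fps: float, smooth_frames: int = 0) -> np.ndarray:
    """Per-frame orientation velocity d(theta)/dt in 1/s.

    Central differences with one-sided endpoints; optional boxcar
    smoothing of the result (odd ``smooth_frames`` width, off by default
    since the measurement protocol specifies none).
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    v = np.gradient(theta, 1.0 / fps)
    if smooth_frames > 1:
        if smooth_frames % 2 == 0:
            raise ValueError("smooth_frames must be odd")
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = smooth_frames // 2
        v = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="valid")
    return v


def rectify(theta, velocity) -> tuple[np.ndarray, np.ndarray]:
    """Fold the dorsoventral axis: deflection in either direction is positive.

    Returns ``(|theta|, velocity * sign(theta))`` so that positive
    rectified velocity is bending away from the body axis and negative is
    head withdrawal, regardless of side.  At theta exactly 0 the side is
    taken from the direction of motion, so departing the midline counts as
    bending.
    """
    theta = np.asarray(theta, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if theta.shape != velocity.shape:
        raise ValueError("theta and velocity must be aligned")
    side = np.sign(theta)
    at_zero = side == 0
    side[at_zero] = np.sign(velocity[at_zero])
    return np.abs(theta), velocity * side


def classify_posture(theta_at_event):
    """Classify orientation at an event as "bent" or "unbent".

    Bent means more than half the maximal head deflection in either
    direction (|theta| > 0.5 on the per-animal normalized scale); exactly
    half counts as unbent.  Accepts scalars or arrays.
    """
    arr = np.asarray(theta_at_event, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("orientation exceeds 1; normalize theta per animal first")
    out = np.where(np.abs(arr) > BENT_THRESHOLD, "bent", "unbent")
    return out.item() if np.isscalar(theta_at_event) else out


def normalize_orientation(theta) -> np.ndarray:
    """Scale orientation by the recording's maximal absolute deflection."""
    theta = np.asarray(theta, dtype=float)
    peak = np.abs(theta).max()
    if peak == 0:
        raise ValueError("orientation is identically zero")
    return theta / peak


@dataclass
class PostureSeries:
    """Derived per-frame posture quantities for one recording."""

    theta: np.ndarray  # normalized to [-1, 1]
    velocity: np.ndarray  # 1/s
    rectified: np.ndarray  # |theta|
    rectified_velocity: np.ndarray  # positive = bending, negative = withdrawal
    posture_class: np.ndarray  # "bent" / "unbent" per frame


def posture_series(
    theta, fps: float, normalize: bool = True, smooth_frames: int = 0
) -> PostureSeries:
    """Compute the full set of posture derivations for a theta series."""
    theta = np.asarray(theta, dtype=float)
    if normalize:
        theta = normalize_orientation(theta)
    v = head_velocity(theta, fps, smooth_frames=smooth_frames)
    rect, rect_v = rectify(theta, v)
    return PostureSeries(theta, v, rect, rect_v, classify_posture(theta))
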