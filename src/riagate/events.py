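"""Event-triggered analysis: peristimulus windows, gating magnitudes,
displacement, position-velocity paths, and timing relationships.

Windowing conventions (documented once, used everywhere): the switch frame
(t = 0, the first frame of the new stimulus state) belongs to the *post*
window; quantitation windows are half-open, [t, t + w) in frames.  A
positive cross-correlation lag means the first series lags (trails) the
second.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from riagate.recording import Recording
from riagate.signals import classify_posture, normalize_orientation

logger = logging.getLogger(__name__)


@dataclass
class StimulusEvent:
    """One odor switch (or a matched no-switch time point)."""

    frame: int
    kind: str  # "off" | "on" | "no_switch"
    theta_at_event: float
    posture: str  # "bent" | "unbent"


@dataclass
class PeristimulusTable:
    """Per-event signal windows aligned to the switch frame.

    ``data`` is (n_events, n_frames); column ``align_index`` is t = 0, the
    switch frame itself, with ``pre_s`` seconds before it and ``post_s``
    seconds after.
    """

    events: list
    data: np.ndarray
    pre_s: float
    post_s: float
    fps: float
    label: str = ""
    n_dropped: int = 0

    @property
    def align_index(self) -> int:
        return int(round(self.pre_s * self.fps))

    @property
    def times(self) -> np.ndarray:
        """Window time axis in seconds relative to the event (t=0 at switch)."""
        return (np.arange(self.data.shape[1]) - self.align_index) / self.fps

    def theta_at_event(self) -> np.ndarray:
        return np.array([e.theta_at_event for e in self.events])

    def posture(self) -> np.ndarray:
        return np.array([e.posture for e in self.events])


def detect_events(
    recording: Recording, normalize_theta: bool = True
) -> list[StimulusEvent]:
    """Find odor on/off switches in a recording's stimulus series.

    The event frame is the first frame of the new stimulus state; the
    orientation at the event is theta on that frame, normalized per animal
    unless ``normalize_theta`` is false.
    """
    theta = recording.theta
    if normalize_theta:
        theta = normalize_orientation(theta)
    d = np.diff(recording.stimulus.astype(int))
    events = []
    for i in np.flatnonzero(d != 0):
        frame = i + 1
        kind = "off" if d[i] < 0 else "on"
        th = float(theta[frame])
        events.append(StimulusEvent(frame, kind, th, classify_posture(th)))
    return events


def sample_no_switch_events(
    recording: Recording,
    n: int,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    seed: int = 0,
    min_separation_s: float | None = None,
    normalize_theta: bool = True,
) -> list[StimulusEvent]:
    """Draw control events at times with no stimulus change.

    Candidate frames keep full pre/post coverage and stay at least
    ``min_separation_s`` (default: the pre window) away from any real
    switch; sampled uniformly without replacement, seeded.
    """
    fps = recording.fps
    if min_separation_s is None:
        min_separation_s = pre_s
    theta = recording.theta
    if normalize_theta:
        theta = normalize_orientation(theta)
    n_frames = recording.n_frames
    lo = int(np.ceil(pre_s * fps))
    hi = n_frames - int(np.ceil(post_s * fps)) - 1
    ok = np.zeros(n_frames, dtype=bool)
    ok[lo : hi + 1] = True
    sep = int(np.ceil(min_separation_s * fps))
    switch_frames = np.flatnonzero(np.diff(recording.stimulus.astype(int)) != 0) + 1
    for sw in switch_frames:
        ok[max(0, sw - sep) : sw + sep + 1] = False
    candidates = np.flatnonzero(ok)
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} candidate no-switch frames for n={n}")
    rng = np.random.default_rng(seed)
    frames = np.sort(rng.choice(candidates, size=n, replace=False))
    return [
        StimulusEvent(int(f), "no_switch", float(theta[f]), classify_posture(float(theta[f])))
        for f in frames
    ]


def extract_peristimulus(
    recording: Recording,
    events: list,
    signal_label: str,
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> PeristimulusTable:
    """Slice a named signal into per-event windows aligned to the switch.

    Row length is ``pre_s*fps + post_s*fps + 1`` frames (t = 0 inclusive).
    Events without full coverage at the record edges are dropped; the
    count of dropped events is logged and kept on the table.
    """
    if not events:
        raise ValueError("empty event list")
    fps = recording.fps
    signal = np.asarray(recording.trace(signal_label), dtype=float)
    n_pre = int(round(pre_s * fps))
    n_post = int(round(post_s * fps))
    rows, kept, dropped = [], [], 0
    for ev in events:
        lo, hi = ev.frame - n_pre, ev.frame + n_post
        if lo < 0 or hi >= len(signal):
            dropped += 1
            continue
        rows.append(signal[lo : hi + 1])
        kept.append(ev)
    if dropped:
        logger.info("extract_peristimulus: dropped %d events at record edges", dropped)
    data = np.asarray(rows) if rows else np.empty((0, n_pre + n_post + 1))
    return PeristimulusTable(kept, data, pre_s, post_s, fps, signal_label, dropped)


def bin_by_orientation(table: PeristimulusTable, n_bins: int = 8) -> dict:
    """Group event windows by orientation at the switch into equal-width bins.

    Default 8 bins over [-1, 1].  Returns bin edges with per-bin mean and
    SEM traces and counts; an empty bin is reported with count 0 and NaN
    traces rather than raising.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    th = table.theta_at_event()
    idx = np.clip(np.digitize(th, edges) - 1, 0, n_bins - 1)
    n_t = table.data.shape[1]
    mean = np.full((n_bins, n_t), np.nan)
    sem = np.full((n_bins, n_t), np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        rows = table.data[idx == b]
        count[b] = len(rows)
        if len(rows):
            mean[b] = rows.mean(axis=0)
            if len(rows) > 1:
                sem[b] = rows.std(axis=0, ddof=1) / np.sqrt(len(rows))
    return {"edges": edges, "mean": mean, "sem": sem, "count": count}


def response_magnitude(
    table: PeristimulusTable,
    window_s: float = 1.0,
    peak_on_mean: bool = True,
) -> dict:
    """Paired pre/post response magnitudes per event.

    ``pre`` is the mean over the 1-s window ending just before the switch
    (frames [t0 - w, t0)); ``post`` is the mean over the 1-s window
    centered on the peak of the across-events mean trace in (0, post_s]
    (or on each event's own peak when ``peak_on_mean`` is false).  A peak
    whose centered window overruns the table is clipped with a warning.
    """
    if table.data.shape[0] == 0:
        raise ValueError("empty peristimulus table")
    fps, a = table.fps, table.align_index
    w = int(round(window_s * fps))
    if w < 1:
        raise ValueError("window shorter than one frame")
    n_t = table.data.shape[1]
    if a - w < 0:
        raise ValueError("pre window does not fit in the table")
    pre = table.data[:, a - w : a].mean(axis=1)

    post_region = table.data[:, a + 1 :]
    if post_region.shape[1] == 0:
        raise ValueError("post window does not fit in the table")
    half = w // 2
    if peak_on_mean:
        peak = a + 1 + int(np.argmax(post_region.mean(axis=0)))
        peaks = np.full(len(table.events), peak)
    else:
        peaks = a + 1 + np.argmax(post_region, axis=1)
    post = np.empty(len(table.events))
    for i, p in enumerate(peaks):
        lo, hi = p - half, p - half + w
        if lo < a + 1 or hi > n_t:
            warnings.warn("peak window clipped at the table edge", stacklevel=2)
            lo, hi = max(lo, a + 1), min(hi, n_t)
        post[i] = table.data[i, lo:hi].mean()
    return {"pre": pre, "post": post, "peak_index": peaks, "times": table.times}


def head_displacement(
    recording: Recording,
    events: list,
    horizon_s: float = 2.0,
    normalize_theta: bool = True,
) -> dict:
    """Signed head displacement theta(t + horizon) - theta(t) per event.

    Events lacking ``horizon_s`` of coverage are dropped.  Returns the
    kept events, their orientation at the switch, and the displacement —
    the inputs to the displacement-vs-orientation regression.
    """
    theta = recording.theta
    if normalize_theta:
        theta = normalize_orientation(theta)
    h = int(round(horizon_s * recording.fps))
    kept, th0, disp = [], [], []
    for ev in events:
        if ev.frame + h >= len(theta):
            continue
        kept.append(ev)
        th0.append(theta[ev.frame])
        disp.append(theta[ev.frame + h] - theta[ev.frame])
    return {
        "events": kept,
        "theta_at_event": np.asarray(th0),
        "displacement": np.asarray(disp),
    }


def position_velocity_path(
    recording: Recording,
    events: list,
    span_s: float = 2.0,
    color_label: str | None = None,
    normalize_theta: bool = True,
) -> list[dict]:
    """Per-event (theta, velocity) trajectory from the switch to ``span_s`` after.

    Optionally attaches a coloring variable (e.g. ``F_loop`` or a dnr
    series stored on the recording) sampled over the same span.
    """
    from riagate.signals import head_velocity

    theta = recording.theta
    if normalize_theta:
        theta = normalize_orientation(theta)
    v = head_velocity(theta, recording.fps)
    span = int(round(span_s * recording.fps))
    paths = []
    for ev in events:
        if ev.frame + span >= len(theta):
            continue
        sl = slice(ev.frame, ev.frame + span + 1)
        path = {"event": ev, "theta": theta[sl], "velocity": v[sl]}
        if color_label is not None:
            path["color"] = np.asarray(recording.trace(color_label))[sl]
        paths.append(path)
    return paths


def cross_correlation(
    x, y, max_lag_s: float, fps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (Pearson) cross-correlation at integer-frame lags.

    Returns ``(lags_s, r)`` for lags in [-max_lag_s, +max_lag_s].  At lag
    L > 0, r(L) is the Pearson correlation of x[L:] with y[:-L]; a peak at
    positive lag therefore means x lags (trails) y.  Each lag is
    normalized over its own overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    max_lag = int(round(max_lag_s * fps))
    if len(x) - max_lag < 3:
        raise ValueError("series too short for the requested maximum lag")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag > 0:
            a, b = x[lag:], y[:-lag]
        elif lag < 0:
            a, b = x[:lag], y[-lag:]
        else:
            a, b = x, y
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            r[i] = np.nan
            continue
        r[i] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return lags / fps, r


def peak_time_difference(
    table_a: PeristimulusTable,
    table_b: PeristimulusTable,
    post_only: bool = True,
) -> np.ndarray:
    """Per-event difference of peak times (seconds), first table minus second.

    Peaks are located within each event's window, restricted to the
    post-switch portion by default (peak times after odor removal).
    """
    if table_a.data.shape != table_b.data.shape:
        raise ValueError("tables must hold matching event windows")
    start = table_a.align_index + 1 if post_only else 0
    pa = start + np.argmax(table_a.data[:, start:], axis=1)
    pb = start + np.argmax(table_b.data[:, start:], axis=1)
    return (pa - pb) / table_a.fps


def peak_lag(
    table_x: PeristimulusTable,
    table_y: PeristimulusTable,
    max_lag_s: float = 2.0,
    per_event: bool = True,
) -> dict:
    """Lag of the peak event-windowed cross-correlation between two signals.

    With ``per_event`` true (default), cross-correlograms are computed per
    event window and averaged before locating the maximum; otherwise the
    windows are concatenated first.  Windows with zero variance in either
    signal are skipped.  Also reports the per-event peak-time difference
    between the two signals (see :func:`peak_time_difference`).
    """
    if table_x.data.shape != table_y.data.shape:
        raise ValueError("tables must hold matching event windows")
    fps = table_x.fps
    if per_event:
        curves = []
        for xr, yr in zip(table_x.data, table_y.data):
            if np.std(xr) == 0 or np.std(yr) == 0:
                continue
            lags, r = cross_correlation(xr, yr, max_lag_s, fps)
            curves.append(r)
        if not curves:
            raise ValueError("all event windows are flat")
        mean_r = np.nanmean(np.asarray(curves), axis=0)
    else:
        x = table_x.data.ravel()
        y = table_y.data.ravel()
        lags, mean_r = cross_correlation(x, y, max_lag_s, fps)
    peak = int(np.nanargmax(mean_r))
    return {
        "lag_s": float(lags[peak]),
        "lags_s": lags,
        "correlogram": mean_r,
        "peak_time_difference_s": peak_time_difference(table_x, table_y),
    }
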