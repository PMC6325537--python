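"""The Recording container: aligned orientation, stimulus, and fluorescence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_COLUMNS = ("F_loop", "F_nrV", "F_nrD")


@dataclass
class Recording:
    """Aligned time series from one imaging session.

    ``time_s`` is a uniform grid at 1/fps; ``theta`` is head orientation
    normalized to [-1, 1] (ventral positive); ``stimulus`` is the binary
    odor state per frame; the three fluorescence traces correspond to the
    loop, nrV, and nrD axonal ROIs.
    """

    time_s: np.ndarray
    theta: np.ndarray
    stimulus: np.ndarray
    F_loop: np.ndarray
    F_nrV: np.ndarray
    F_nrD: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("theta", "stimulus", *TRACE_COLUMNS):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time grid ({n})")

    @property
    def fps(self) -> float:
        if "fps" in self.meta:
            return float(self.meta["fps"])
        return float(1.0 / np.median(np.diff(self.time_s)))

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def trace(self, label: str) -> np.ndarray:
        """Return a named series (``F_loop``/``F_nrV``/``F_nrD``/``theta``/``stimulus``)."""
        if label in ("theta", "stimulus", *TRACE_COLUMNS):
            return getattr(self, label)
        raise KeyError(f"unknown trace {label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "theta": self.theta,
                "stimulus": self.stimulus.astype(int),
                "F_loop": self.F_loop,
                "F_nrV": self.F_nrV,
                "F_nrD": self.F_nrD,
            }
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the CSV schema plus a JSON sidecar holding the metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.9g")
        if sidecar and self.meta:
            path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            time_s=df["time_s"].to_numpy(float),
            theta=df["theta"].to_numpy(float),
            stimulus=df["stimulus"].to_numpy(int),
            F_loop=df["F_loop"].to_numpy(float),
            F_nrV=df["F_nrV"].to_numpy(float),
            F_nrD=df["F_nrD"].to_numpy(float),
            meta=meta,
        )
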