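"""Scoring of the two-stream head-orientation preference assay.

An animal restrained mid-body faces two parallel fluid streams, buffer on
one side and odorant on the other, with the sides exchanged at the 1-min
mark of a 2-min recording.  Preference is the percentage of assay time the
head spends bent into the odor stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ASSAY_DURATION_S = 120.0
ASSAY_SWITCH_S = 60.0


@dataclass
class AssayRecord:
    """One animal's assay: head orientation and the odor-carrying side per frame.

    ``odor_side`` is +1 when the odor stream is on the ventral (positive
    theta) side and -1 when dorsal; it changes exactly once, at the switch.
    """

    theta: np.ndarray
    odor_side: np.ndarray
    fps: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.odor_side = np.asarray(self.odor_side, dtype=int)
        if self.theta.shape != self.odor_side.shape:
            raise ValueError("theta and odor_side must be aligned")
        if len(self.theta) != int(round(ASSAY_DURATION_S * self.fps)):
            raise ValueError(
                f"assay must cover {ASSAY_DURATION_S:.0f} s at {self.fps} fps"
            )
        changes = np.flatnonzero(np.diff(self.odor_side) != 0)
        if len(changes) != 1 or changes[0] + 1 != int(round(ASSAY_SWITCH_S * self.fps)):
            raise ValueError("odor side must change exactly once, at the 60-s mark")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": np.arange(len(self.theta)) / self.fps,
                "theta": self.theta,
                "odor_side": self.odor_side,
            }
        ).to_csv(Path(path), index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, fps: float | None = None) -> "AssayRecord":
        df = pd.read_csv(path)
        if fps is None:
            fps = float(1.0 / np.median(np.diff(df["time_s"].to_numpy())))
        return cls(
            theta=df["theta"].to_numpy(float),
            odor_side=df["odor_side"].to_numpy(int),
            fps=fps,
        )


def stream_preference(record: AssayRecord, threshold: float = 0.0) -> float:
    """Percent of assay time with the head within the odor stream.

    A frame counts as in-odor when the head is deflected past ``threshold``
    toward the odor-carrying side.  Exactly-midline frames belong to
    neither stream: they are excluded from the numerator but remain in the
    denominator, so a head held at the midline scores 0.
    """
    in_odor = (record.theta * record.odor_side) > threshold
    return 100.0 * float(np.count_nonzero(in_odor)) / len(record.theta)
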