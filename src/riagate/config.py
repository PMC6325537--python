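"""Simulation configuration for the gate-and-switch circuit model.

All generator randomness flows from a single integer seed; independent
substreams for head movement and per-trace noise are derived
deterministically from it (see :mod:`riagate.synthetic`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable

import numpy as np

GENOTYPES = ("wildtype", "gar3", "ria_tetx", "scopolamine")

#: genotypes in which muscarinic (GAR-3) signalling is absent, abolishing
#: motor-evoked compartmental calcium and stimulus-evoked head withdrawal
NO_MOTOR_GENOTYPES = ("gar3", "scopolamine")

#: genotypes with no directional head response (withdrawal / stream preference)
NO_WITHDRAWAL_GENOTYPES = ("gar3", "scopolamine", "ria_tetx")

#: genotypes with no odor-stream preference in the two-stream assay
NO_PREFERENCE_GENOTYPES = ("ria_tetx", "scopolamine")


def gate_function(kind: str, threshold: float = 0.5) -> Callable[[np.ndarray], np.ndarray]:
    """Return the posture gate: |theta at switch| -> multiplicative gain in [0, 1].

    ``"step"``  — all-or-none gate, gain 1 when the rectified orientation
    exceeds ``threshold`` (half the maximal head deflection by default),
    else 0.  ``"graded"`` — gain rises linearly with rectified orientation.
    ``"none"`` — always 1 (ungated).
    """
    if kind == "step":
        return lambda a: (np.abs(a) > threshold).astype(float)
    if kind == "graded":
        return lambda a: np.clip(np.abs(a), 0.0, 1.0)
    if kind == "none":
        return lambda a: np.ones_like(np.asarray(a, dtype=float))
    raise ValueError(f"unknown gate kind {kind!r}; expected step, graded, or none")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the forward model.

    Head orientation theta is dimensionless, normalized to [-1, 1]
    (ventral positive).  Fluorescence is in arbitrary units on the scale of
    ``sensory_amplitude``.

    Parameters
    ----------
    duration_s, fps
        Recording length and frame rate (5 Hz imaging by default).
    osc_period_s, osc_amplitude, osc_noise_sd
        Spontaneous head-bend oscillation: period of the sinusoid, its peak
        rectified orientation, and the stationary SD of the additive AR(1)
        jitter (lag-one coefficient 0.9).
    motor_gain, motor_lag_s, motor_tau_s
        Motor-evoked compartmental calcium (mCa2+): fluorescence per unit
        rectified bend, the latency by which it trails head movement, and
        the decay constant of the short causal smoothing kernel.
    sensory_amplitude, sensory_rise_s, sensory_tau_s
        Sensory-evoked whole-axon calcium (sCa2+) on odor removal: ungated
        peak amplitude and the rise/decay constants of the transient.
    suppression_depth
        Depth of the whole-axon suppression transient on odor presentation,
        same waveform as the off-transient with negative sign.
    gate, gate_threshold
        Posture gate applied to the sCa2+ amplitude (see
        :func:`gate_function`).  Default: step at half-maximal deflection.
    withdrawal_gain
        Rate (1/s) at which a gated odor-off event pulls the head toward
        the midline during the 2-s withdrawal window.
    baseline, noise_sd
        Fluorescence baseline and per-frame Gaussian imaging noise SD.
    compartment_sign_convention
        ``"ventral"``: nrV carries mCa2+ for ventral (theta > 0) bends and
        nrD for dorsal; ``"dorsal"``: the mapping is exchanged.
    genotype
        ``gar3`` and ``scopolamine`` abolish mCa2+ and head withdrawal;
        ``ria_tetx`` (blocked synaptic output) abolishes withdrawal and
        assay preference while leaving both calcium signals intact.
    switch_schedule
        Sequence of ``(time_s, "on"|"off")`` odor-valve switches; the entry
        names the stimulus state *after* the switch.
    """

    duration_s: float = 600.0
    fps: float = 5.0
    osc_period_s: float = 2.0
    osc_amplitude: float = 0.8
    osc_noise_sd: float = 0.05
    motor_gain: float = 0.6
    motor_lag_s: float = 0.6
    motor_tau_s: float = 0.1
    sensory_amplitude: float = 1.0
    sensory_rise_s: float = 0.5
    sensory_tau_s: float = 1.5
    suppression_depth: float = 0.5
    gate: str = "step"
    gate_threshold: float = 0.5
    withdrawal_gain: float = 2.0
    baseline: float = 1.0
    noise_sd: float = 0.02
    compartment_sign_convention: str = "ventral"
    genotype: str = "wildtype"
    switch_schedule: tuple = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 < self.osc_amplitude <= 1.0):
            raise ValueError("osc_amplitude must lie in (0, 1]")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.compartment_sign_convention not in ("ventral", "dorsal"):
            raise ValueError("compartment_sign_convention must be 'ventral' or 'dorsal'")
        gate_function(self.gate, self.gate_threshold)  # validates gate kind
        for entry in self.switch_schedule:
            t, kind = entry
            if kind not in ("on", "off"):
                raise ValueError(f"switch kind must be 'on' or 'off', got {kind!r}")
            if not (0.0 <= float(t) < self.duration_s):
                raise ValueError(f"switch time {t} outside the recording")

    # -- genotype-resolved effective parameters ------------------------------

    @property
    def effective_motor_gain(self) -> float:
        return 0.0 if self.genotype in NO_MOTOR_GENOTYPES else self.motor_gain

    @property
    def effective_withdrawal_gain(self) -> float:
        return 0.0 if self.genotype in NO_WITHDRAWAL_GENOTYPES else self.withdrawal_gain

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def gate_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return gate_function(self.gate, self.gate_threshold)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["switch_schedule"] = [[float(t), k] for t, k in self.switch_schedule]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["switch_schedule"] = tuple((float(t), k) for t, k in d.get("switch_schedule", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def alternating_schedule(
    first_switch_s: float, interval_s: float, n_switches: int, first_kind: str = "off"
) -> tuple:
    """Build a regular on/off switch schedule starting with ``first_kind``."""
    kinds = [first_kind, "on" if first_kind == "off" else "off"]
    return tuple(
        (first_switch_s + i * interval_s, kinds[i % 2]) for i in range(n_switches)
    )


def jittered_schedule(
    first_switch_s: float,
    interval_s: float,
    n_switches: int,
    jitter_s: float,
    seed: int,
    first_kind: str = "off",
) -> tuple:
    """Alternating schedule with uniform jitter added to each switch time.

    With ``jitter_s`` equal to the head-bend period, switches sample all
    phases of a strictly periodic oscillation instead of locking to one —
    the situation for freely behaving animals whose bend phase is
    uncorrelated with the valve clock.
    """
    rng = np.random.default_rng([int(seed), 7701])
    kinds = [first_kind, "on" if first_kind == "off" else "off"]
    times = (
        first_switch_s
        + interval_s * np.arange(n_switches)
        + rng.uniform(0.0, jitter_s, size=n_switches)
    )
    return tuple((float(t), kinds[i % 2]) for i, t in enumerate(times))
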