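"""Forward simulator of the gate-and-switch model of RIA function.

The generator produces the statistical structure the analysis pipeline
assumes: a noisy oscillatory head bend; motor-evoked compartmental calcium
(mCa2+) that tracks rectified bending with a short latency; whole-axon
sensory calcium transients (sCa2+) on odor removal whose amplitude is gated
by head orientation at the switch; additive superposition of the two
sources within each nerve-ring compartment (the loop carries sCa2+ only);
stimulus-evoked head withdrawal toward the midline; and genotype ablations
(gar-3 / scopolamine: no mCa2+ and no withdrawal; RIA::TeTx: calcium intact
but no withdrawal and no assay preference).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from riagate.assay import AssayRecord
from riagate.config import NO_PREFERENCE_GENOTYPES, SimulationConfig
from riagate.recording import Recording

# substream keys: all randomness flows from (seed, key) pairs
_STREAM_PHASE = 0
_STREAM_THETA = 1
_STREAM_LOOP = 2
_STREAM_VENTRAL = 3  # noise of the compartment associated with ventral bends
_STREAM_DORSAL = 4
_STREAM_ASSAY = 5

#: lag-one coefficient of the AR(1) orientation jitter
AR1_COEF = 0.9

#: duration of the active withdrawal pull after a gated odor-off switch
WITHDRAWAL_WINDOW_S = 2.0

#: time constant of the passive release back to the ongoing oscillation
WITHDRAWAL_RELEASE_TAU_S = 0.5


def _rng(config: SimulationConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), key])


def _ar1_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) jitter with stationary standard deviation ``sd``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - AR1_COEF**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    return lfilter([1.0], [1.0, -AR1_COEF], e)


def stimulus_series(config: SimulationConfig) -> np.ndarray:
    """Binary odor state per frame implied by the switch schedule.

    Each schedule entry names the state *after* its switch; the initial
    state is the complement of the first switch (odor on if the first
    switch is "off"), or constant odor-on for an empty schedule.
    """
    n = config.n_frames
    if not config.switch_schedule:
        return np.ones(n, dtype=int)
    first_kind = config.switch_schedule[0][1]
    state = 1 if first_kind == "off" else 0
    stim = np.full(n, state, dtype=int)
    for t, kind in config.switch_schedule:
        i = int(round(t * config.fps))
        stim[i:] = 0 if kind == "off" else 1
    return stim


def simulate_head_trajectory(config: SimulationConfig) -> np.ndarray:
    """Head orientation theta(t), normalized to [-1, 1], ventral positive.

    A sinusoid of the configured period and amplitude with AR(1) jitter and
    a random starting phase.  After any odor-off switch that occurs while
    the head is bent past the gate threshold (and the genotype permits a
    directional response), a withdrawal transient pulls the head toward the
    midline at rate ``withdrawal_gain`` for 2 s, then releases.
    """
    n = config.n_frames
    if n == 0:
        raise ValueError("duration too short for the frame rate")
    dt = 1.0 / config.fps
    t = np.arange(n) * dt
    phi0 = _rng(config, _STREAM_PHASE).uniform(0.0, 2.0 * np.pi)
    base = config.osc_amplitude * np.sin(2.0 * np.pi * t / config.osc_period_s + phi0)
    base = base + _ar1_noise(n, config.osc_noise_sd, _rng(config, _STREAM_THETA))

    theta = base.copy()
    gain = config.effective_withdrawal_gain
    if gain > 0.0:
        n_active = int(round(WITHDRAWAL_WINDOW_S * config.fps))
        release = np.exp(-dt / WITHDRAWAL_RELEASE_TAU_S)
        for time_s, kind in config.switch_schedule:
            if kind != "off":
                continue
            i0 = int(round(time_s * config.fps))
            if i0 >= n or abs(base[i0]) <= config.gate_threshold:
                continue
            p = 0.0
            for k in range(i0 + 1, n):
                if k - i0 <= n_active:
                    # pull total orientation (base + p) toward the midline
                    p -= gain * dt * (base[k] + p)
                else:
                    p *= release
                    if abs(p) < 1e-6:
                        break
                theta[k] += p
    return np.clip(theta, -1.0, 1.0)


def sensory_waveform(t: np.ndarray, rise_s: float, tau_s: float) -> np.ndarray:
    """Unit-peak sCa2+ transient: (1 - exp(-t/rise)) * exp(-t/tau), t >= 0."""
    t = np.asarray(t, dtype=float)
    if rise_s <= 0:
        w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_s), 0.0)
        return w
    w = np.where(
        t >= 0,
        (1.0 - np.exp(-np.maximum(t, 0) / rise_s)) * np.exp(-np.maximum(t, 0) / tau_s),
        0.0,
    )
    t_peak = rise_s * np.log1p(tau_s / rise_s)
    w_max = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / tau_s)
    return w / w_max


def motor_kernel(config: SimulationConfig) -> np.ndarray:
    """Causal mCa2+ kernel: exponential decay shifted by ``motor_lag_s``.

    Normalized to unit sum, so ``motor_gain`` is fluorescence per unit of
    sustained rectified bend.  The decay constant is kept short relative to
    the bend cycle so the kernel delays the motor signal by very nearly the
    configured latency.
    """
    dt = 1.0 / config.fps
    lag, tau = config.motor_lag_s, config.motor_tau_s
    if tau <= 0:
        k = np.zeros(int(round(lag / dt)) + 1)
        k[-1] = 1.0
        return k
    t = np.arange(0.0, lag + 8.0 * tau + dt, dt)
    k = np.where(t >= lag - 1e-12, np.exp(-np.maximum(t - lag, 0.0) / tau), 0.0)
    return k / k.sum()


def _sensory_trace(
    theta: np.ndarray, stimulus: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Whole-axon sCa2+ trace: gated positive transients at odor removal,
    fixed-depth suppression transients at odor presentation."""
    n = len(theta)
    t = np.arange(n) / config.fps
    gate = config.gate_fn
    sca = np.zeros(n)
    d = np.diff(stimulus.astype(int))
    for i in np.flatnonzero(d != 0):
        i_sw = i + 1  # first frame of the new stimulus state
        w = sensory_waveform(t[i_sw:] - t[i_sw], config.sensory_rise_s, config.sensory_tau_s)
        if d[i] < 0:  # odor removed: gated whole-axon increase
            amp = config.sensory_amplitude * float(gate(abs(theta[i_sw])))
            sca[i_sw:] += amp * w
        else:  # odor presented: whole-axon suppression
            sca[i_sw:] -= config.suppression_depth * w
    return sca


def simulate_calcium(
    theta: np.ndarray, stimulus: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fluorescence traces (F_loop, F_nrV, F_nrD) for a given head trajectory.

    Each nerve-ring compartment is baseline + mCa2+ + sCa2+ + noise, where
    mCa2+ is the rectified bend toward that compartment's associated
    direction passed through the causal motor kernel, and sCa2+ is added
    identically to all three traces (whole-axon).  The loop carries sCa2+
    only.  gar-3 / scopolamine genotypes zero the motor gain.
    """
    theta = np.asarray(theta, dtype=float)
    stimulus = np.asarray(stimulus)
    if theta.shape != stimulus.shape:
        raise ValueError("theta and stimulus must share one time grid")
    n = len(theta)

    sca = _sensory_trace(theta, stimulus, config)
    gain = config.effective_motor_gain
    if gain > 0.0:
        k = motor_kernel(config)
        mca_ventral = gain * np.convolve(np.maximum(theta, 0.0), k)[:n]
        mca_dorsal = gain * np.convolve(np.maximum(-theta, 0.0), k)[:n]
    else:
        mca_ventral = np.zeros(n)
        mca_dorsal = np.zeros(n)

    def noise(key: int) -> np.ndarray:
        if config.noise_sd <= 0:
            return np.zeros(n)
        return _rng(config, key).normal(0.0, config.noise_sd, size=n)

    f_loop = config.baseline + sca + noise(_STREAM_LOOP)
    ventral_trace = config.baseline + mca_ventral + sca + noise(_STREAM_VENTRAL)
    dorsal_trace = config.baseline + mca_dorsal + sca + noise(_STREAM_DORSAL)
    if config.compartment_sign_convention == "ventral":
        return f_loop, ventral_trace, dorsal_trace
    return f_loop, dorsal_trace, ventral_trace


def simulate_recording(config: SimulationConfig) -> Recording:
    """Compose the head trajectory, stimulus, and calcium into a Recording.

    Deterministic for a fixed config (including the seed).
    """
    theta = simulate_head_trajectory(config)
    stim = stimulus_series(config)
    f_loop, f_nrv, f_nrd = simulate_calcium(theta, stim, config)
    t = np.arange(config.n_frames) / config.fps
    return Recording(
        time_s=t,
        theta=theta,
        stimulus=stim,
        F_loop=f_loop,
        F_nrV=f_nrv,
        F_nrD=f_nrd,
        meta=config.to_dict(),
    )


def render_head_mask(
    angle_deg: float,
    image_shape: tuple[int, int] = (128, 128),
    aspect_ratio: float = 3.5,
    length: float | None = None,
    anchor: tuple[float, float] | None = None,
) -> np.ndarray:
    """Binary mask of an elongated head at a given bend angle.

    The head is drawn as a filled ellipse whose base sits at ``anchor``
    (the most anterior restrained midline point, bottom-center of the frame
    by default) and whose major axis makes ``angle_deg`` with the neutral
    vertical body axis.  Positive angles tilt the anterior tip toward
    increasing column index (the ventral side under this package's
    convention; image origin top-left, row-major).
    """
    if aspect_ratio <= 1.0:
        raise ValueError("aspect_ratio must exceed 1 (elongated head)")
    if not (-90.0 < angle_deg < 90.0):
        raise ValueError("angle must lie in (-90, 90) degrees")
    h, w = image_shape
    if length is None:
        length = 0.43 * min(h, w)
    if anchor is None:
        anchor = (0.92 * h, (w - 1) / 2.0)  # pixel-centered for mirror symmetry
    a = np.deg2rad(angle_deg)
    drow, dcol = -np.cos(a), np.sin(a)  # unit vector toward the anterior tip
    cy = anchor[0] + 0.5 * length * drow
    cx = anchor[1] + 0.5 * length * dcol
    semi_major = length / 2.0
    semi_minor = semi_major / aspect_ratio
    rr, cc = np.mgrid[0:h, 0:w]
    y, x = rr - cy, cc - cx
    u = y * drow + x * dcol  # along the major axis
    v = -y * dcol + x * drow
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def simulate_assay(config: SimulationConfig, bias: float) -> AssayRecord:
    """Two-stream head-orientation preference assay (120 s, side switch at 60 s).

    ``bias`` in [0, 1] shifts the head oscillation toward whichever side
    carries the odor; 0 gives no preference, 1 parks the head in the odor
    stream.  Genotypes lacking RIA output or mCa2+ (RIA::TeTx, scopolamine)
    are forced to zero bias regardless of the argument.
    """
    if not (0.0 <= bias <= 1.0):
        raise ValueError("bias must lie in [0, 1]")
    if config.genotype in NO_PREFERENCE_GENOTYPES:
        bias = 0.0
    duration_s, switch_s = 120.0, 60.0
    n = int(round(duration_s * config.fps))
    t = np.arange(n) / config.fps
    odor_side = np.where(t < switch_s, 1, -1)  # ventral first, then dorsal
    phi0 = _rng(config, _STREAM_PHASE).uniform(0.0, 2.0 * np.pi)
    osc = config.osc_amplitude * np.sin(2.0 * np.pi * t / config.osc_period_s + phi0)
    jitter = _ar1_noise(n, config.osc_noise_sd, _rng(config, _STREAM_ASSAY))
    theta = (1.0 - bias) * osc + bias * config.osc_amplitude * odor_side + jitter
    theta = np.clip(theta, -1.0, 1.0)
    return AssayRecord(
        theta=theta,
        odor_side=odor_side,
        fps=config.fps,
        meta={"genotype": config.genotype, "bias": bias, "seed": config.seed},
    )
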