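# Methods

This note documents the forward model behind the synthetic-data
generator, the measurement conventions of the analysis pipeline, the
numerical choices that were genuinely open, and what the passing tests do
and do not establish about real recordings.

## The forward model

The generator produces what a 5-Hz imaging session of a head-restrained
worm yields: aligned series of head orientation θ(t), binary odor state,
and fluorescence from the loop, nrV, and nrD axonal ROIs.

**Head orientation.** θ(t) is a sinusoid of period `osc_period_s` and
amplitude `osc_amplitude`, plus AR(1) jitter (lag-one coefficient 0.9,
stationary SD `osc_noise_sd`), clipped to [−1, 1]. The AR(1) coefficient
gives smooth, realistic frame-to-frame jitter without destroying the
oscillation. The default period is 2 s (0.5-Hz head sweeps, the tempo of
restrained head casts) and the default amplitude 0.8.

**Stimulus schedules and phase sampling.** The oscillator keeps a fixed
phase for a whole recording, as a metronomic idealization of rhythmic head
casting. A strictly regular valve schedule would therefore hit the same
bend phase at every switch. The scenario drivers instead jitter each
switch time uniformly over one bend period (`jittered_schedule`), which
reproduces the experimental situation — the animal's bend phase is
uncorrelated with the valve clock — and makes orientation-at-switch sample
all phases.

**Motor-evoked calcium.** Each compartment's mCa²⁺ is
`motor_gain × (bend rectified toward its associated direction)` passed
through a causal kernel: an exponential decay of time constant
`motor_tau_s` delayed by `motor_lag_s` (default 0.6 s), normalized to unit
sum. The decay constant defaults to 0.1 s, deliberately short: a causal
exponential adds a phase delay of ≈ atan(ωτ)/ω at the bend frequency, so a
long-tailed kernel would make the measured cross-correlation lag
substantially exceed the configured latency. With τ = 0.1 s the measured
peak lag equals `motor_lag_s` to within half a frame at the default bend
period, so the configured latency is also the recoverable one. By default
nrV carries the ventral-bend signal; the mapping is a config flag
(`compartment_sign_convention`) because the ipsi/contra wording in the
source material is not self-consistent, and flipping it exactly exchanges
the two traces.

**Sensory-evoked calcium.** Each odor removal adds, identically to all
three ROIs, a transient `A · g(|θ(t_switch)|) · w(t)` where `w` is a
unit-peak rise/decay waveform `(1 − e^{−t/0.5 s}) · e^{−t/1.5 s}` and `g`
is the posture gate. The gate defaults to a step at 0.5 (all-or-none at
half-maximal deflection, matching the bent/unbent dichotomy); a graded
(linear) gate is available, since a regression of response magnitude on
deflection cannot distinguish the two at modest event counts. Odor
presentation adds the same waveform with negative sign and depth
`suppression_depth` (whole-axon suppression, ungated — posture dependence
of suppression is not modeled). The loop trace carries sCa²⁺ only; each
nerve-ring compartment is baseline + mCa²⁺ + sCa²⁺; every trace gets
independent Gaussian noise of SD `noise_sd` (default 0.02, i.e. 2% of the
ungated transient amplitude).

**Withdrawal.** After an odor removal that occurs while |θ| exceeds the
gate threshold — and only in genotypes with intact RIA output *and*
mCa²⁺ — the head is pulled toward the midline at rate `withdrawal_gain`
(default 2 s⁻¹) for 2 s, then released with a 0.5-s time constant.

**Genotypes.** `gar3` and `scopolamine` zero the motor gain (no mCa²⁺)
and, because the directional response requires muscarinic signalling, also
the withdrawal; `ria_tetx` (blocked synaptic output) leaves both calcium
signals intact but abolishes withdrawal and assay preference;
`scopolamine` likewise shows no assay preference.

**Preference assay.** 120 s at 5 Hz, odor side exchanged at 60 s. The
commanded `bias` b ∈ [0, 1] mixes the oscillation with a constant offset
toward the odor side: θ = (1−b)·osc + b·A·side + jitter, so b = 0 is
side-symmetric and b = 1 parks the head in the stream.

**Randomness.** All of it flows from one integer seed; the phase, the
orientation jitter, and each fluorescence noise trace use deterministic
substreams keyed on (seed, stream id). Noise substreams are keyed by
*associated bend direction*, not compartment name, which is what makes the
sign-convention swap an exact exchange.

## Measurement conventions

- Fluorescence normalization uses F_min/F_max over the full recording
  (one normalization per measured trace), not per window.
- Orientation is normalized per animal by its maximum |θ|, so the 0.5
  bent cut means "half the maximal degree of head deflection". Exactly
  0.5 classifies as unbent (strict inequality).
- The switch frame (t = 0) belongs to the post window; quantitation
  windows are half-open [t, t+w) in frames. Peristimulus rows are
  `pre·fps + post·fps + 1` frames long.
- The pre/post quantitation windows are 1 s; the post window is centered
  on the peak of the *across-events mean* trace (a per-event-peak option
  exists). Where the transient's true peak falls midway between frames,
  the discrete argmax is a numerical coin toss between two frames whose
  1-s windowed means differ by a few percent; the closed-form expected
  response therefore accepts the measurement's peak frame so the two
  share one window convention.
- Orientation binning uses 8 equal-width bins over [−1, 1]; empty bins
  are reported with count 0 and NaN traces, not an error.
- Cross-correlation is per-lag Pearson over the overlap; positive lag
  means the first series trails the second. Event-windowed correlograms
  are computed per event and averaged (concatenation is an option);
  peak-time differences are located in the post-switch portion of the
  2-s-pre / 4-s-post window.
- No-switch control events are drawn uniformly at random, seeded, from
  frames with full window coverage and at least one pre-window away from
  any real switch.
- The Bayesian bootstrap weights each observation by gamma((n−1)/n, 1)
  normalized to sum one per replicate — implemented exactly as specified
  by the estimation-statistics recipe this package follows, even though
  the canonical Bayesian bootstrap uses unit-exponential (flat Dirichlet)
  weights; the `canonical` flag provides the standard variant. At n = 50
  the two are nearly indistinguishable and the 95% percentile interval
  covers a Normal mean in ~94% of replicates. CIs are percentile-based;
  callers choose whether the supplied values are raw observations or
  per-animal means.
- Pre/post designs are analyzed as paired estimation differences (plus
  ordinary one-way ANOVA and regression F where a single F statistic is
  wanted); repeated-measures ANOVA machinery is deliberately out of
  scope.
- Head angle from masks: second central moments (scikit-image
  regionprops), defined only for major/minor axis ratio ≥ 1.2; the
  nose-tip alternative measures the vector from the most posterior mask
  row's centroid to the farthest mask pixel. On rendered heads the two
  agree within ~4°.
- Assay scoring counts a frame as in-odor when sign(θ) matches the odor
  side (threshold configurable); exact-midline frames count in the
  denominator only.

## What the generator does and does not emulate

It reproduces the *statistical structure* the analysis assumes:
oscillatory posture with jitter, lagged motor calcium, gated additive
sensory transients, withdrawal kinematics, genotype ablations, and
realistic event counts. It does not emulate photobleaching, motion
artifacts, z-drift, irregular bout/quiescence structure, graded
per-animal variability in gains, or segmentation noise in real video.
Passing tests therefore establish that the pipeline's estimators recover
the model's parameters under its own assumptions — not that those
assumptions hold for any particular real recording.

Two quantitative consequences of the conventions are worth knowing:

- Per-animal orientation normalization places the analysis' bent cut at
  0.5·max|θ| while the generator gates at |θ| = 0.5 on the raw scale, so
  a few percent of events near the boundary are classified bent but
  ungated; the bent-group mean underestimates the fully gated response by
  up to ~7% at default noise. This is a property of the normalization
  convention, not an estimator bug.
- The 2-s displacement horizon equals one default bend period, so for a
  non-withdrawing animal the oscillation returns the head to its starting
  posture and the displacement-vs-orientation slope is ~0. The residual
  AR(1) jitter still mean-reverts slightly, leaving knockout slopes of
  order −0.01 (vs ~−0.5 for wildtype); at some seeds this residue reaches
  nominal significance at n = 500. Any stationary bounded process
  mean-reverts, so "slope ≈ 0" should be read relative to the wildtype
  effect, which is ~40-fold larger.

## Problem sizes

The scenario drivers use 200 odor-off events for gating, 100 for timing,
500 per genotype for withdrawal, 200 animals per assay condition, 1000
datasets (n = 50, 2500 bootstrap replicates each) for interval
calibration, and a 25-point angle grid — sizes at which the Monte-Carlo
error of each recovered quantity is several-fold smaller than the
tolerance it is compared against, while a full scenario sweep completes
in seconds.
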