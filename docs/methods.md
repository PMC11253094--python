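# Methods

This note documents the models, conventions and numerical choices behind
`kpsignal`, and what the synthetic benchmarks do and do not demonstrate
about real recordings.

## Izhikevich stimulus generation

The two-variable model `dv/dt = 0.04v² + 5v + 140 − u + I`,
`du/dt = a(bv − u)` with reset `v ← c, u ← u + d` at the 30 mV threshold is
integrated with fixed-step forward Euler. No integrator is canonical for
this model; it is conventionally run with Euler steps ≤ 1 ms, and the
default `dt = 0.25 ms` keeps all 20 registry regimes finite and stable
while halving `dt` moves the tonic-spiking inter-spike interval by ~1.2%.
Choices that matter:

- **Apex clipping.** The Euler step that crosses threshold overshoots by an
  amount that depends on `dt`; the trace records exactly 30 mV at that
  step, so "max(v) == 30 mV" is a well-defined, testable property rather
  than a step-size artifact.
- **Initial conditions** default to `v₀ = −65 mV`, `u₀ = b·v₀` (the common
  convention). With `I = 0` and tonic-spiking `(a, b)`, `v = −70 mV` is the
  stable root of `0.04v² + (5−b)v + 140 = 0` and the simulation holds it
  exactly — a useful null check.
- **Onset transient.** From rest the first *two* inter-spike intervals are
  shorter than the limit-cycle period (the recovery variable needs two
  cycles to settle); afterwards intervals are constant to the `dt`
  resolution. Periodicity metrics (ISI coefficient of variation) are
  therefore evaluated over multi-second runs (5 s of model time, ~180
  intervals), where CV ≈ 0.026.
- **Ramp and arbitrary drives** go through `input_override`, a per-step
  current series (the accommodation regime's published table row has
  `I = 0`; its characteristic behavior needs a ramp whose slope the user
  chooses).

Pulse protocols (trains of 1 ms pulses, 100 ms bursts, stepped-frequency
trains, hyperpolarizing pre-pulses, oscillatory packets) are constructed
piecewise-constant at an explicit resolution; audio stimuli are polyphase
resampled at the exact rational rate ratio and linearly rescaled so the
absolute peak equals the requested amplitude (zero-mean in, zero-mean out).
Model-time (ms) and recording-time (s) waveforms both carry an explicit
`sample_interval`; any rate conversion is an explicit resampling step,
never implicit.

## Synthetic recordings

The generator emulates 1 sample/s electrode recordings statistically — it
is not a biophysical membrane model. Each channel is
`baseline + N(0, σ²) noise + injected spikes`, where a spike is a
single-sample peak with a short exponential tail (default 2 samples at
decay 0.3/sample): 1 Hz sampling cannot resolve spike shape, so shape is a
convention, kept configurable.

**Spike laws.** Amplitudes are log-normal — positive, right-skewed, with
rare large outliers (reported maxima of 48/81 mV against 12/15 mV means) —
*left-truncated at the smallest reported amplitude* (1.54 mV kombucha,
8.82 mV proteinoid), which we read as the detector's floor; the right tail
stays open because reported maxima are sample maxima, not distribution
bounds. (A log-normal truncated on *both* sides cannot reach the proteinoid
sd of 11.15 mV at mean 15.11 mV on [8.82, 80.74]; the one-sided family
can.) Periods are normal, truncated to the reported [min, max]. In both
families the underlying (μ, σ) are solved numerically (moment equations of
the truncated law, `scipy.optimize.root`) so that the **truncated**
distribution's mean and sd equal the reported targets exactly — matching
moments before truncating biases the realized mean by several standard
errors at n ≈ 10⁴. Spike trains are built by cumulative period sampling;
events whose rounded peak index falls on the record edge are dropped from
both trace and ground truth, since an edge sample can never be an interior
local maximum for any detector.

**Noise.** Generic channels default to σ = 5 mV, on the scale of reported
output-channel variability. The kombucha/proteinoid presets default to
σ = 0.1 mV: the smallest reported detected amplitude (1.54 mV) implies
recording noise well below it, and the presets exist to benchmark
ground-truth recovery, which requires the noise floor the real detector
evidently had.

**Coupling** mixes the source channel's baseline-removed fluctuation into
the target: `y = ρx + (1−ρ)n`, giving correlation `ρ/√(ρ² + (1−ρ)²)`
(≈ 0.999 at ρ = 0.95) and MI orders of magnitude above independent pairs —
the synchronized-pair contrast the coordination analysis looks for.
**Quantization** rounds half-away-from-zero to multiples of a step (e.g.
10 mV reproduces observed 0/10/20/30 mV levels). One seeded
`numpy.random.Generator` drives everything; identical configs give
byte-identical recordings.

**What passing these benchmarks shows.** That the detector and estimators
recover what was injected under the stated statistical structure. Real KP
recordings add drift, non-stationary baselines, electrode artifacts and
correlated noise that the generator deliberately omits; results on
synthetic data bound achievable, not field, performance.

## Spike detection and statistics

Events are local maxima exceeding `median + k·1.4826·MAD`, at least
`min_separation` apart (higher peak wins). The robust scale tolerates the
large outlier spikes without threshold inflation; the defaults are `k = 4`
and `min_separation = 30 s` (safely below the smallest reported period,
51 s). Ground-truth recovery experiments use `k = 6`: across the ~2×10⁶
samples of a 100-recording benchmark a 5σ threshold still yields ≈ 1
expected false alarm, while 6σ drops that to ~10⁻³ with the threshold
(≈ 0.6 mV) still far below the smallest admissible amplitude. A zero-MAD
trace (constant or noise-free) logs a warning and falls back to the bare
above-baseline local-maximum rule. Amplitude is peak minus median baseline,
so it is invariant to constant offsets; periods are successive peak-time
differences. Quantiles use Hazen plotting positions `(i−0.5)/n` with linear
interpolation — the convention under which quarter-step quartile values
(e.g. 176.75 s) are exactly representable — and dispersions use the n−1
sample standard deviation.

## Mutual information

Plug-in estimation on equal-width B×B histograms spanning each channel's
observed [min, max], base-2 logs, `0·log 0 := 0`. Defaults: B = 10, no
bias correction — values are then directly comparable with plain
histogram-based MI estimates; the estimator's upward bias is
≈ (B−1)²/(2N ln 2) (0.016 bits at B = 10, N = 3600), and Miller–Madow
correction is available behind a flag. The matrix diagonal carries the
marginal entropy H(X) = I(X;X) ≤ log₂B at the same binning. A rank mode
bins rank-transformed series, buying invariance under strictly monotone
rescaling. A constant series occupies a single bin (entropy 0) with a
warning rather than an error. Cross-correlation reports the maximum
Pearson coefficient over integer lags in [−L, L] on the lag-aligned
overlap, ties to the smallest |lag|; a positive lag means the second
series trails the first.

## Association learning

Hebbian updates `Δw_ij = ε·α_i·α_j` accumulate as a pure sum of scaled
outer products (order-invariant, additive; no decay term). The learning
rate defaults to ε = 0.1; since published weight magnitudes are not
recoverable without the rate and the raw activities, weight-level
comparisons are structural (sign patterns), not numeric. Digitized
patterns use {0, 1} bits matching the 6-bit optical / 7-bit
acoustic-electrical bitstream framing, with thresholds as explicit
parameters (scalar stimuli get a thermometer code); a {−1, +1} coding is
provided for Hopfield analysis. The energy `E = −0.5 αᵀWα` sees only the
symmetric part of W (bilinear-form identity, tested); the landscape sweeps
two unit activities over a grid (default 41×41 on [−1, 1]²) with the rest
clamped. Retrieval dynamics (asynchronous updates) are out of scope: only
the energy surface is analyzed.

## I/O and reproducibility

Recordings travel as `time_s, ch<N>_mV` CSV (strict dialect; a `loose`
parser accepts arbitrary column names), with fs inferred from the median
time step and >1% interval jitter rejected unless resampling is requested.
WAV input (PCM 8/16/32-bit or float) is scaled to [−1, 1] and stereo is
averaged. Every writer/reader pair round-trips within 1e−6 mV (9
significant digits on disk). CLI outputs carry `.meta.json` sidecars with
the resolved configuration; config files use a strict schema that rejects
unknown keys.

## Benchmark problem sizes

The shipped benchmarks use: 500 random ≤6×6 joint tables for
estimator-vs-oracle agreement; 100 seeds × 3600 samples for the
independent-noise MI ceiling; one 6-channel, 3600 s recording for coupling
detectability; 100 recordings × 22 000 s (~100 spikes each, the reported
recording scale) for detector recovery; 5 s of model time for periodicity.
All together they run in a few seconds on one CPU.

## Known limitations

- Published MI tables and spike counts derive from the deposited raw
  recordings with unstated detection and binning parameters; they are not
  reproducible from summary statistics alone, and the package makes no
  attempt to match them numerically.
- The plug-in MI estimator is biased upward at small N; compare values only
  at equal (B, N).
- The generator's spike shape and noise model are conventions; parameter
  recovery results transfer to real data only insofar as the real noise
  floor resembles the configured one.
- Euler integration quantizes spike times to `dt`; ISI-based statistics
  inherit that granularity.
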