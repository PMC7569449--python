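# Methods

## Problem and pipeline

The package estimates how many repetitions of a repetitive exercise occur
in a short accelerometer recording, without training data and without
knowing which exercise was performed. The pipeline is:

1. **Ingest** (`signal_io`): delimited text `t,x,y,z`, comma or tab,
   optional header. Units of g are converted to m/s² (× 9.80665) on load;
   millisecond timestamps are supported via a config switch. Rows with
   non-finite values are dropped; duplicate timestamps keep the first
   occurrence (deterministic and order-preserving). Signals are linearly
   interpolated onto a uniform grid, default 50 Hz — phone accelerometers
   commonly record near this rate, and it oversamples any plausible
   repetition cadence by an order of magnitude, so interpolation order is
   immaterial for crossing counts and spectral peaks. Session boundaries
   can be trimmed to a closed time interval.
2. **Signed magnitude** (`preprocess`): the 3-axis signal is collapsed to
   one scalar per sample. A plain Euclidean norm would half-wave-rectify
   the motion (both directions of travel come out positive), which doubles
   crossing counts and distorts the spectrum. Instead the gravity baseline
   g_i is estimated by a centered moving average of each axis (default
   window 2.0 s, truncated at the edges so there is no phase lag and no
   padding), and the signal is
   `X_i = sgn(d_i·ĝ_i)·‖d_i‖` with `d = a − g` and `sgn(0) = +1`.
   The default signs the *dynamic* component; a `raw` mode signs the full
   vector norm instead, which stays almost always positive (gravity
   dominates) and is kept only for fidelity to the simplest description of
   sign multiplication. A 2 s window exceeds every plausible half-cycle of
   a repetition (cadences of interest are 0.2–5 Hz) while still tracking
   slow orientation drift.
3. **Counting** (`counters`): three methods, all operating on X alone.

## The counters

**Threshold crossing.** τ = min X + c·(max X − min X), default c = 2/3.
Count indices with X_{i−1} < τ ≤ X_i. After a counted crossing, crossings
within a refractory period ρ (default 0.1 s) are suppressed; suppressed
crossings do not restart the period (the period exists to prevent
double-counting within one repetition, not to chain). A signal whose range
is below 1e−9 m/s² is degenerate: no threshold is placed, count 0. The
strict-below / at-or-above convention counts a sample sitting exactly on τ
once, deterministically. Because τ is range-relative and the spectrum
argmax is scale-free, all three counters are invariant to positive
rescaling of the signal.

**Threshold crossing with low-pass filtering.** The same counter applied
to `A_{i+1} = (1−α)·A_i + α·X_i`, default α = 0.1, with τ recomputed on
the filtered signal. The recursion is implemented exactly as written — the
input sample drives the *next* output sample — with A_0 = X_0 to avoid a
startup transient; its unit-impulse response from a zero initial state is
α(1−α)^(n−1). This is a first-order exponentially-weighted IIR filter with
a −3 dB point near αf_s/2π ≈ 0.8 Hz at the defaults: repetition
fundamentals pass (attenuated but τ is range-relative, so attenuation is
harmless) while sample-scale noise is strongly suppressed.

**Fourier dominant frequency.** Remove the series mean, take the magnitude
of the real FFT, and pick the largest bin with 0.2 Hz ≤ f ≤ 5 Hz (the
plausible band of human repetition cadences; the lower edge excludes DC
leakage and posture drift, the upper edge tremor-band noise). Ties break
toward the lower frequency to avoid harmonic capture. The count is
round(f*·T) with T = (n−1)/f_s, rounded half-up (counts are integers; a
`floor` mode is available). A flat signal or an empty band yields count 0.

## Evaluation protocol

RMSE of counts: sqrt(mean((estimate − truth)²)) over sessions, grouped per
exercise and per method. The per-method "average" row is the *pooled* RMSE
over all sessions (sqrt of the pooled mean squared error), not the mean of
per-exercise RMSEs; the two differ whenever error variance differs between
exercises, so the report carries both. Sessions whose participant and
observer counts disagree in the manifest are excluded before scoring —
their ground truth is unreliable. The threshold fraction can be tuned by
grid sampling (default grid 0.05…0.95 in steps of 0.05), minimising pooled
RMSE, ties toward the smaller fraction.

## Synthetic benchmark

Real recordings of this kind are generally not shareable, so benchmarks
are simulated with known ground truth. A session is

    a(t) = 9.80665·o(t) + s(t)·o(t) + ε(t),

with o(t) a unit orientation that may drift slowly (rotation at a fixed
rate about a perpendicular axis), ε white Gaussian noise per axis, and
s(t) a per-repetition waveform `a_r·[sin(2πu) + Σ_k w_k sin(2πku)]` of the
within-rep phase u ∈ [0,1).

Key modelling choices:

- **Tempo.** Per-rep log-periods follow a mean-reverting AR(1) process
  (coefficient 0.85) with stationary coefficient of variation
  `freq_jitter_cv`, so cadence drifts smoothly (pacing, fatigue) rather
  than white-jittering around a fixed tempo. This non-stationarity is what
  degrades spectral counting on irregular movers while leaving crossing
  counters untouched. Lognormal keeps periods positive; with zero jitter
  the periods are exact.
- **Ground truth.** Repetitions are laid end to end; the true count is the
  number of *complete* repetitions that fit in the session (observers count
  whole reps), and the signal rests at pure gravity afterwards. With zero
  jitter, true_count = floor(rep_freq·duration) exactly.
- **Amplitude.** Per-rep amplitudes have Gaussian jitter truncated at
  ±3 SD and floored at 5% of nominal, so they stay positive.
- **Holds** (`rest_frac`). Exercises such as bridges hold at end-range and
  trunk rotations pause between half-turns. The motion is compressed into
  the first 1 − rest_frac of each period and the remainder is stationary.
  Crossing counters still see exactly one upward crossing per repetition,
  but the duty-cycled waveform concentrates spectral energy near the burst
  frequency — at rest_frac = 0.5, on the second harmonic of the repetition
  rate — which is precisely the documented failure mode of
  dominant-frequency counting on irregular motions.

The ten archetypes are graded from large/periodic (arm_circle: 6 m/s²
amplitude, 2% tempo CV, 0.15 m/s² noise) to small/irregular
(upper_trunk_rotation: 1.6 m/s², 12% tempo CV, 0.6 m/s² noise, half-period
holds). All archetype numbers are this package's own calibration —
plausible magnitudes for the named movements — not measured values; no
quantitative description of the original recordings is available. The
benchmark draws n_subjects × 10 sessions, scaling each archetype's rate,
amplitude, jitters and noise by per-subject uniform ±20% factors. Child
seeds derive from the master seed via `numpy` SeedSequence spawn keys, so
every session stream is independent and the whole benchmark is
reproducible bit for bit.

**What the simulator does not model:** sensor bias, clipping, temperature
drift, non-exercise segments, rest breaks between sets, multi-activity
streams, or biomechanically realistic limb trajectories. Passing benchmark
tests therefore demonstrates the counters' behaviour under controlled
periodic-plus-noise structure, not field accuracy on human data; the
qualitative contrasts (filtering helps; irregular, small motions are
harder; spectral counting fails on duty-cycled movements) are the claims
being exercised, never absolute error levels.

## Numerical choices and degenerate inputs

- Grid-point selection for resampling and trimming uses a 1e−9 relative
  tolerance so closed intervals include boundary samples despite float
  division.
- sgn(0) = +1 everywhere; gravity-norm-zero samples fall back to sign +1.
- Spectral ties (exactly equal magnitudes) resolve to the lowest frequency
  via first-argmax.
- Flat signals (range < 1e−9 m/s²) count 0 under every method.
- Filter state: A_0 = X_0 in normal use; an explicit `initial` argument
  exposes the zero-state impulse response for verification.
- The threshold counter is implemented vectorised (crossing detection) with
  a sequential refractory pass; the test suite pins it to a literal
  per-sample reference scanner on 1000 random signals.

## Known limitations

- The counters assume one continuous bout of a single repetitive activity;
  mixed or interrupted streams will be mis-counted.
- The 2/3-of-range threshold is sensitive to single extreme samples
  (min/max are not robust statistics); the low-pass variant mitigates but
  does not remove this.
- Fourier counting quantises to spectral bins (resolution 1/T Hz), so very
  short sessions have coarse count granularity.
- The per-method ordering measured on the synthetic benchmark is a property
  of the simulated conditions; on real data the best method varies by
  movement type.
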