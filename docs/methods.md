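# Methods

## The model

`gammachain` treats the visual sensory chain as a *synchronous
pipeline*. A contrasted, flashed stimulus elicits a volley of activity
that crosses a succession of cortical stages — sets of areas whose
columns fire within the same gamma cycle. Each stage is paced by its
thalamic partner: after a volley, inhibition from the reticular
thalamic nucleus (RTN) acts as a spacer, and the next volley can start
only at the next *gate release*. A stage that consumes `c` cycles at
synchronization frequency `F` therefore contributes a delay of exactly
`c·θ` with `θ = 1000/F` ms, and the noiseless stimulus-to-response
time is

```
RT0 = afferent_delay + Σ_i c_i·θ_i + entrainment_delay + motor_offset
```

The first stage (LGN + V1, frequency f1) carries the inducer
entrainment delay; the higher-order sensory stages share a common f2
(so each contributes `T2 = 1/f2`); PFC (f3) and the motor output (f4)
close the chain. All default frequencies are 40 Hz (`θ = 25 ms`), the
typical human gamma rhythm for an attended stimulus.

### Why the delay is near-deterministic

Individual neuronal latencies are highly variable, yet each stage
re-quantizes its volley onto the gate lattice: early arrivals wait for
the release; late arrivals (within the excitation window, or caught by
the lateral suppress-then-facilitate mechanism) are re-phased onto the
same cycle. `event_driven_rt` implements this literally — the gate
lattice of each stage is phase-locked to the nominal arrival of the
volley and a jittered arrival snaps to the *nearest* release — so any
per-stage latency perturbation smaller than `θ/2` leaves the output
time bit-for-bit unchanged, and the closed form above coincides
exactly with the event-driven traversal. Perturbations beyond `θ/2`
slip whole cycles (quantized failures, not graded noise). This is the
mechanism by which per-cell variability does not accumulate across
stages, and it is exercised directly by the test suite (jitter sweeps
0–12 ms at `θ/2 = 12.5 ms`).

### Lateral convergence

Within a stage, the fastest columns inhibit the laggards through the
fast (myelinated) lateral inhibitory projections, and the slower
excitatory projections then facilitate them, so laggards re-fire at
the next gate release at the leader's phase. `lateral_converge` models
this as: per cycle, every column whose phase exceeds the leader's by
more than `tol` (default 1 ms) is re-emitted at the leader phase. With
precise re-phasing (the default; a residual-jitter knob exists) any
ensemble with spread below `θ/2` converges in at most one cycle, and
spread is non-increasing.

### The intra-column sequence

`column_sequence` produces the event times of one cycle: thalamic
relay → layer 4 (stellate clusters) → layer 3 → layer 5 → layer 6 →
pulvinar (layer-5 collaterals) and RTN (layer-6 collaterals, the
spacer of the next cycle). The ordering L4 < L3 < L5 < L6 is the
constrained part; the per-step lags are free parameters defaulting to
1 ms (sub-window values that preserve the ordering), with the
thalamocortical hops fixed at the length-compensated ~2 ms.

### Entrainment by a periodic inducer

A small target flashing every `P` ms at an alpha-band rate acts as an
attentional distractor: alpha-locked inhibition at the first cortical
stage delays processing of the attended target by about `P/3`.
`entrainment_delay` returns `fraction·P` (fraction fixed at 1/3, an
empirical value — no mechanistic derivation is attempted) for `P`
inside the lock range, default (55, 105) ms. The 120 ms condition lies
beyond the range — the measured monotone progression breaks down there
— so the delay saturates at the range edge and a `DegradedLockWarning`
is emitted; the saturated value is a placeholder, not a prediction,
and the behavior between full lock and full breakdown is unknown.
Periods below the range saturate symmetrically (equally a placeholder).

By default the entrainment delay is purely *additive* on top of the
usual uniform wait for the first gate release. This reproduces the
observed condition differences: mean shift = `P/3` exactly, equal
variances. An alternative reading — the in-range inducer phase-locks
the V1 gate to the stimulus, replacing the uniform `[0, θ1)` wait by
the deterministic delay — is implemented behind
`ChainConfig.remove_phase_wait` (default off); it predicts a shift of
`P/3 − θ1/2` and a reduced variance, which does not match the measured
shifts, so it is kept only as a switchable variant.

## Stochastic trial composition

```
rt = RT0 + U[0, frame)          # display refresh jitter (no sync)
         + U[0, θ1)             # wait for the first gate release
         + N(0, motor_sd)       # motor/decision noise
         + bias_slope·(gap − 1800)   # anticipation bias, default 0
```

clipped at zero. A configurable fraction of trials (default 6%) is
replaced by *erratic strikes*, uniform on [0, 200) ms — the erroneous
key presses that the 200 ms screen later removes (matching the
observed 1090 → 1018 screening ratio).

## Calibration

The model cannot predict the absolute response time: the stage count
is an open empirical question and the non-cortical offsets (retina,
neuromuscular, device) are unmeasured. `calibrate` therefore anchors
the two free parameters to a measured baseline session:

- `motor_offset` so the analytic mean `RT0 + frame/2 + θ1/2` equals
  the target mean (281 ms in the reference session);
- `motor_sd` from the variance decomposition
  `target_sd² = frame²/12 + θ1²/12 + motor_sd² (+ bias term)`,
  giving 36.86 ms for a 38 ms target at the defaults.

The structural floor `sqrt(frame²/12 + θ1²/12) = 9.24 ms` bounds the
feasible SD; smaller targets raise an error. Because the calibration
absorbs residual time into `motor_offset`, the anchored statistics are
independent of the stage roster; the default roster (LGN+V1, five
higher-order sensory stages, PFC, motor — 8 stages × 25 ms — plus a
50 ms afferent delay) is one plausible choice, fully configurable,
loosely bounded by the three EEG time-clusters reported between V1 and
the frontal areas. Everything downstream (cyclic-condition means,
lags) is then a genuine prediction: only baseline data enter the
calibration.

## The protocol generator

`build_schedule` emulates the recording conditions: 50 Hz video
(20 ms frames), gaps equiprobable and i.i.d. over the multiples of the
step in [1200, 2400] ms inclusive (both endpoints are step multiples;
21/16/13/11 values for steps 60/80/100/120), cyclic lattice anchored
at session start (the anchor is arbitrary; any choice preserves the
in-phase invariant), random targets replacing the cyclic flash at
their slot, 5-minute default sessions. Immediate gap repeats are not
excluded (plain i.i.d. draws). What it does *not* emulate: photometry
(luminance/color are irrelevant to timing), eye movements, attention
lapses within a session, inter-subject variability, or any drift of
gamma frequency over time — so passing tests demonstrate internal
consistency of the model and pipeline, not properties of new human
data.

## The analysis pipeline

Exactly the treatment applied to the recorded sessions: drop responses
≤ 200 ms (erratic strikes; no other filter), report mean/sample SD,
5 ms-aligned histograms, empirical CDFs with pointwise 95%
percentile-bootstrap bands (1000 resamples, seeded; isotonic clean-up
keeps the band monotone and bracketing the estimate), and the
cross-condition lag as the *median of per-quantile shifts*
`Q_b(p) − Q_a(p)` over 33 evenly spaced probabilities in [0.10, 0.90].
Quantiles use linear interpolation of order statistics (type 7), the
numpy/R default, stated for cross-language reproducibility. The
quantile-median estimator is one defensible formalization of reading a
horizontal shift off a CDF plot; it is translation-exact and
antisymmetric. Note that the 200 ms screen truncates the baseline's
lower tail (~1.7% of mass) more than the cyclic conditions' (~0.1%),
which inflates baseline quantiles slightly and compresses measured
lags by about 1 ms relative to the closed form — visible in both
simulated and recorded data.

Diagnostics: `gap_bias` (least-squares RT-on-gap slope and the
shortest-vs-longest-gap contrast; a slope of −0.083 ms/ms reproduces
the ~100 ms extreme-gap contrast seen in the recordings) and
`session_stability` (trend of session means; flag threshold 5 ms per
session, several times the standing error of a 5-minute session mean).

## Numerical choices and problem sizes

- Single `SeedSequence` per session, spawned into separate sub-streams
  for trial noise, pre-gate jitter and contamination, so enabling one
  noise source never perturbs the others; all outputs are
  byte-reproducible from (config, seed).
- Exact float equality is asserted between the closed-form and
  event-driven delays (same accumulation order by construction).
- Trial CSVs store floats in shortest round-trip representation; reads
  parse with Python `float` for lossless round trips.
- Simulated sessions in tests and in the acceptance script use
  1090–1200 raw trials per condition (the recorded sizes) and 12 000
  for the lag estimates, keeping the Monte-Carlo standard error of a
  lag near 0.5 ms.

## Known limitations

- The pipeline law and the 1/3 entrainment fraction are empirical
  summaries; the model carries no biophysics (no membrane dynamics,
  conductances or spike waveforms — events are timestamps).
- The stage count, afferent delay and motor offset are not separately
  identifiable from behavioral data; only their calibrated sum is.
- Behavior outside the entrainment lock range is a placeholder; the
  extrageniculate shortcut, attention shifts and feedback re-entry
  beyond the entrainment delay are out of scope.
- The erratic-strike model (uniform below 200 ms) is a screening
  stand-in, not a model of anticipatory responding.
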