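# Methods

This note records the models, parameter choices and numerical decisions
behind `ianeedle`, and what the synthetic benchmark does and does not show
about real recordings.

## Signal model and detection procedure

The measured quantity is the impedance magnitude at a single excitation
frequency (100 kHz, where tissue layers separate most clearly), streamed at
33 S/s while a monopolar injection needle advances toward the joint cavity.
The detection pipeline is:

1. **Low-pass filter.** First-order digital Butterworth, Nyquist-normalized
   cutoff `wn = 0.04` (0.66 Hz at 33 S/s), designed by the prewarped
   bilinear transform (`scipy.signal.butter`). First order keeps latency
   and computation minimal for a real-time loop; the −3 dB point is exactly
   at `wn`. The filter runs causally, single pass — no forward–backward
   smoothing, which would be non-causal.
2. **Control chart.** From an in-space calibration sample, `μ` (arithmetic
   mean) and `σ` (sample SD, N−1 denominator) define `CL = μ`,
   `UCL/LCL = μ ± kσ` with `k = 3` (99.73% normal coverage). A sample is
   out-of-control iff it is strictly above UCL or strictly below LCL;
   values exactly on a limit count as in-control.
3. **State machine.** `searching → in_space` after `debounce = 10`
   consecutive in-control samples (~0.3 s at 33 S/s), preventing indicator
   chatter on noise; `in_space → searching` on the first out-of-control
   sample, which is also what retracts the indicator when the contrast-dye
   rise crosses the UCL. `debounce = 1` reproduces a per-sample indicator.

Limits are computed on **filtered** magnitudes by default — the chart then
monitors the same signal it classifies — with a raw-mode switch
(`filter_enabled=False`) for comparison. Prospective limits come either
from the shipped per-joint reference table or from a user-marked
calibration window on the incoming stream.

### Filter state initialization

The recursion starts at steady state for the first input sample
(`lfilter_zi` scaled by x[0]). A stream that begins at a constant level
therefore produces that level immediately, and the detector cannot emit
spurious out-of-limit flags during startup. Streaming (sample-at-a-time)
and batch application perform the same floating-point operations in the
same order and are bitwise identical; the test suite asserts this.

## Reference joint statistics

Intra-articular impedance at 100 kHz, porcine model, n = 242 per joint:

| joint       | mean (Ω) | SD (Ω) |
|-------------|----------|--------|
| right knee  | 1537.3   | 88.5   |
| left knee   | 1367.2   | 8.0    |
| right elbow | 2012.5   | 7.4    |
| left elbow  | 2001.8   | 12.6   |

The right-knee SD is dominated by breathing/movement artifact (about 5% of
the mean). The elbows read higher and separate less from surrounding fat,
which is why knee joints are the easier target.

## Synthetic scenario

The generator emulates the recorded insertion timeline:

| phase            | time (s)      | mean path                                   | noise SD |
|------------------|---------------|---------------------------------------------|----------|
| subcutaneous     | 0 – 10.77     | constant 2500 Ω (configurable)              | 100 Ω    |
| transition       | 10.77 – 22.89 | linear ramp down to the joint mean          | 50 Ω     |
| intra-articular  | 22.89 – 22.98 | constant at the joint mean                  | joint SD |
| dye injection    | 22.98 – 32    | accelerating exponential, plateau 3000 Ω    | joint SD |

plus a +800 Ω single-sample spike at 15 s (clinician hand movement). Noise
is Gaussian per sample — means and SDs are the only statistics the
reference data report, and the 99.73% coverage argument presupposes
normality. Everything is deterministic given a seed.

Choices the source data leave open, fixed here once:

* **Subcutaneous level 2500 Ω.** Reported only qualitatively ("very high"
  relative to the cavity); 2500 Ω puts it ~8σ above the right-knee UCL,
  consistent with fat being the most resistive layer. Configurable.
* **The 8.85 → 10.77 s gap** is assigned to the subcutaneous phase; no
  intervening tissue is described.
* **Breathing artifact (right knee only):** 0.3 Hz sinusoid, phase 0 at
  window start, amplitude `√2 · 0.05 · μ` so its SD contribution is 5% of
  the mean; the segment's Gaussian SD is reduced to `sqrt(σ² − (0.05μ)²)`
  so the total sample SD still matches the reference 88.5 Ω. The window
  runs from cavity entry (22.89 s) to the sharp dye rise (27.98 s); during
  the sharp rise the dye front dominates the signal.
* **Dye rise:** `μ + A(e^{(t−22.98)/τ} − 1)` with τ = 0.5 s and A chosen so
  the mean path crosses the UCL exactly at 27.98 s, matching the recorded
  "slight increase, then sharp rise" shape; it plateaus at a configurable
  3000 Ω (contrast dye conducts worse than synovial fluid).

### Needle-in-saline electrode model

`Z(f) = R_s + Q·(j2πf)^(−α)`: solution resistance in series with a
constant-phase element for the electrode–electrolyte interface. Because the
shaft is insulated and only the tip is exposed, none of the parameters
depend on immersion depth, so spectra at 2/4/6 cm are identical to machine
precision — the model-level statement of the electrode's depth invariance.

## Detector evaluation

`evaluate_detector` scores the per-sample in-control flag of the filtered
stream against a noiseless ground truth: whether the scenario's mean
trajectory lies within the control limits, i.e. what an ideal noise-free
chart would report. Samples within a guard band (default ±0.5 s) of a
ground-truth transition — the moments the mean path crosses a limit — are
excluded, because no causal filter can be graded fairly inside its own
settling window (the first-order filter's ramp lag is ~8 samples ≈ 0.24 s).
Segment-identity labels are deliberately not used as the truth signal: the
mean path dwells inside the band late in the descent and early in the dye
phase, so an ideal detector *must* flag those samples, and counting them as
errors would measure the scenario's geometry, not the classifier.

At the default operating point (100 right-knee traces, ±0.5 s guard band,
~99 000 scored samples) the residual errors are a handful of
filter-lag/noise misses just outside the guard band around the descent
crossing; accuracy is ≥ 99.9% with specificity ~1. The benchmark is
deterministic given the seed; 100 traces of 1056 samples run in about one
second.

**What this does and does not show.** Passing it shows the filter + chart +
state machine correctly classify a stream whose segment statistics match
the reference recordings, including spike and breathing artifacts. It does
not validate against real tissue inhomogeneity, electrode drift,
non-Gaussian movement artifact, needle retraction mid-procedure, or
joint-to-joint variability beyond the four reference (μ, σ) pairs.

## Circuit fitting

Objective: summed squared relative error of the complex impedance (real and
imaginary residuals divided by the measured magnitude), so all decades of a
log sweep weigh equally. Solver: `scipy.optimize.least_squares` (TRF,
non-negative bounds), deterministic, seeded by a heuristic initial guess —
R1 from the high-frequency plateau, R2 from the low-frequency plateau
minus R1, C1 from the mid-drop frequency via `1/(2πf_mid R2)`. A flat
spectrum (no capacitive drop) seeds C1 = 0 and recovers R1 + R2; the R1/R2
split is not identifiable in that degenerate case. Noiseless round trips
recover parameters to ~1e−6 relative; 1% multiplicative noise to a few
percent. Non-convergence raises a `FitError` carrying the best-so-far
circuit.

## Numerical conventions

* Phases in degrees, negative for capacitive behaviour; times in seconds
  from stream start; magnitudes in ohms.
* Sampling rate is treated as ground truth (33 S/s); a stated 30 ms
  interval is its rounded reciprocal. `detect_trace` rejects traces whose
  inter-sample intervals deviate from the configured rate by more than 1%.
* Trace/spectrum files use shortest round-trip float formatting, making
  write → read an identity and repeated writes byte-identical.
* Simulated traces use `numpy.random.Generator` seeded per trace via
  `SeedSequence.spawn`, so evaluations are reproducible and traces
  independent.

## Known limitations

* The RRC model is a single-dispersion approximation; real tissue spectra
  show broader (CPE-like) dispersion the three-element circuit cannot fit
  exactly.
* The detector has no notion of "dye phase" — the dye rise simply returns
  the state to `searching`; modelling a third state was deliberately left
  out of scope.
* Reference statistics come from a single animal; the per-joint table is a
  default, not a population model.
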