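# Methods

## The circuit model

The electrode–tissue system is modelled as a one-port network: a constant
phase element (CPE) for the electrode–electrolyte interface in series with
a parallel R₁‖C block for the bulk of the encapsulating tissue and a
series resistor R₂ for the culture medium / body path to ground,

    Z(s) = 1/(Y·sᵖ) + R₁/(1 + s·R₁·C) + R₂ .

The CPE impedance is 1/(Y·(jω)ᵖ) with magnitude Y (CPE-T, S·sᵖ) and
exponent p (CPE-P, dimensionless, (0, 1]); its phase is exactly −p·90° at
every frequency, and p = 1 recovers an ideal capacitor. We adopt the
(jω)ᵖ convention throughout; CPE-T magnitudes are only comparable between
tools that share it. Phases are stored in degrees (negative =
capacitive, as instruments export them); internal arithmetic is in
radians. All five elements are strictly positive.

A simpler legacy circuit — access resistance in series with a
polarization R‖C — is kept as an alternate model. On CPE-generated
spectra its best modulus-weighted fit is always worse than the full
circuit's (a nested-model property the tests check), which is the
quantitative reason to prefer the CPE circuit for frequency-resolved
data.

## EIS screening and fitting

Spectra are measured on a 10 Hz–100 kHz grid, 10 points per decade,
log-spaced and inclusive of both endpoints (41 points) — endpoint
inclusion is our convention. Recordings carry nominally three repeats;
analysis uses the arithmetic mean of magnitude and of phase per
frequency. Three exclusion rules screen out broken electrodes and air
bubbles:

- **R1**: upper quartile (75th percentile) of the per-frequency phase
  standard deviation across repeats exceeds 4°;
- **R2**: mean |Z| at 10 Hz exceeds 50 kΩ;
- **R3**: mean phase lies inside the open interval (−20°, 0°) at any
  frequency between 10 Hz and 1 kHz.

All fired rules are reported; a recording with a single repeat is an
error (its standard deviation is undefined), not a silent pass. The
quantile reading of R1 and the open interval of R3 are implementation
choices (the thresholds are pluggable); QC operates on the mean-of-repeats
spectrum.

Fitting minimizes the modulus-weighted mean squared complex residual on
the percentage scale,

    ssq% = 100/N · Σᵢ [(ReZᵢ−ReẐᵢ)² + (ImZᵢ−ImẐᵢ)²] / |Zᵢ|² ,

with the data modulus in the denominator (a model-modulus option exists;
the two differ only at poor fits). The optimizer is scipy's bounded
trust-region least squares on log-transformed elements — the elements
span ~6 orders of magnitude, and the log transform makes the trust region
meaningful — with wide bounds (10⁻¹² to 10⁶ in SI units, effectively
unconstrained; the exponent p is bounded by (10⁻³, 1]), a cost tolerance
of 10⁻¹⁰ and an evaluation budget equivalent to 100 outer iterations.
Start values come from the decade endpoints: p starts at 0.8, Y solves
the CPE model at 10 Hz, both resistors start at |Z(100 kHz)|, and C
solves the ideal-capacitor model at 10 Hz. These are heuristics that
assume the interface dominates at 10 Hz and the resistors at 100 kHz;
they are never constraints. If an exact 10 Hz or 100 kHz point is
missing, the nearest frequency within a factor of two substitutes with a
logged warning; beyond that the spectrum is rejected with the missing
frequency named.

Over a time course, the first QC-kept timepoint is fitted with all
elements free; R₂ (not expected to change) is then fixed bit-for-bit at
that fitted value, and each later fit warm-starts from the previous
result. QC-excluded timepoints produce explicit gaps, never
interpolations.

## Pulse transients

A charge-balanced biphasic rectangular pulse (amplitude i_amp, phase
duration T₀, optional interphase gap; cathodic-leading by default) has
four current edges. Each edge contributes a shifted copy of the
circuit's unit step response

    r(t) = tᵖ/(Y·Γ(p+1)) + R₁(1 − e^(−t/(R₁C))) + R₂ ,

so for zero gap V(t) = −i_amp·[r(t)u(t) − 2r(t−T₀)u(t−T₀) +
r(t−2T₀)u(t−2T₀)]; the four-term generalization covers the gapped
clinical pulse (25 µs phases, 9 µs gap). Values at switching instants
are right-limits (the value just after the step) in both backends.
Anodic-leading pulses negate the trace; the response is exactly linear in
i_amp.

The independent oracle inverts Z(s)/s numerically with the fixed Talbot
contour (M = 48 nodes, vectorized over time points) and superposes the
same four shifted copies; it never touches the closed-form time
expression. Agreement is ~10⁻⁸ relative away from switching instants
(at the instants the band-limited inversion cannot represent the jump, so
±2 samples are excluded from comparisons).

## Waveform preprocessing and onset detection

Raw repeated traces are processed per repeat in the measurement order:
first-order digital Butterworth low-pass at 80 kHz (causal), decimation
by plain sample-picking (the Butterworth is the anti-alias step; factor
20 from a 125 MHz record gives the ~6 MHz working rate), then subtraction
of the mean over the first 500 output samples (80 µs at 6.25 MHz), which
must lie wholly before stimulus onset. Mean and standard deviation
across repeats are taken last. The filter is initialized at steady state
for the record's first value, so a constant environmental offset passes
through unchanged and is removed exactly by the baseline step; with
zero-state initialization a start-up transient would leak into the
baseline window. The filter's group delay (~2 µs at low frequency) and
its ~15 µs settling after each current edge are inherent to the
specified preprocessing; comparisons against the ideal waveform account
for them.

Stimulus onset is found as the single change point in RMS level: the
two-segment split minimizing the Gaussian variance cost
k·log(rms₁²) + (n−k)·log(rms₂²). The search is confined to samples
before the absolute voltage peak — the onset precedes the peak by
construction, and without the restriction a quiet–pulse–quiet record
with a long tail can split at the pulse end. If no post-onset sample
exceeds three times the pre-onset standard deviation the waveform is
declared flat ("no onset detected").

## Markers

**Contact "impedance"** is the clinical telemetry quantity, not a true
impedance: the first-phase voltage peak divided by the input current.
Within a phase the model voltage magnitude grows monotonically, so the
peak equals the end-of-phase value; using the in-window maximum of |V| is
robust to noise and makes the marker invariant to pulse polarity and
current scaling.

**SPPR** (second phase peak ratio) is the second-phase peak — the
extremum of the opposite-polarity excursion within the second-phase
window — as a percentage of the first-phase peak, magnitudes throughout.
Its mechanism: the bulk capacitance discharges between the phases, and as
fibrosis raises R₁ and lowers C the capacitive contribution to the second
peak shrinks, so SPPR rises. In closed form (zero gap) the ratio is

    SPPR = 100·[(2−2ᵖ)·B + R₁(1−e^(−τ))² + R₂] / [B + R₁(1−e^(−τ)) + R₂]

with B = T₀ᵖ/(Y·Γ(p+1)) and τ = T₀/(R₁C). Two regime facts matter and
are encoded in the tests:

- monotonicity (non-decreasing in R₁, non-increasing in C) holds where
  the bulk charges appreciably within a phase, τ ≳ 0.5. In the
  overdamped corner (R₁C ≫ T₀) the closed form itself reverses slightly
  (the first-phase peak gains R₁τ while the second gains only R₁τ²), so
  that corner is outside the marker's operating range;
- as C → 0 the ratio saturates at ((2−2ᵖ)B + R₁ + R₂)/(B + R₁ + R₂),
  which approaches 100% only once R₁ dominates the CPE term B.

**SPPR slope** is an ordinary least-squares fit of SPPR against day over
construct-on timepoints, computed only when at least three timepoints are
available and at least one lies beyond day 7 (the R₁ inflection);
otherwise an explicit refusal object is returned — never a numeric zero.
The final included day is reported for pairing with the EIS fit.

**Patient telemetry** works from voltages sampled at fixed offsets inside
each phase: contact impedance from |V| at 25 µs over the input current,
the altered SPPR from 6 µs into each phase. Signed voltages are
accepted and magnitudes taken. Implant current levels convert as
µA = 17.5·100^(CL/255).

Pearson correlations are reported with Fisher-z 95% confidence intervals
(scipy's implementation; the tests cross-check the closed-form z
interval and its coverage under independence).

## Reverse waveform fitting

With Y, p and R₂ pinned to the day-2 EIS fit, R₁ and C are recovered
from the preprocessed mean waveform by bounded least squares over the
window from onset to the end of the pulse plus an equal-length decay
tail. Local searches launch from every pair of 30 linearly spaced
start values per element within R₁ ∈ 50–5000 Ω and C ∈ 10⁻¹³–10⁻⁷ F
(900 searches; the start grid is linear on the raw scale even though C
spans six decades — a log-spaced option exists but is off by default),
and the lowest sum of squared voltage residuals wins. Internally each
search optimizes (R₁, log C) so the trust region is well-scaled; the CPE
and R₂ contributions over the window are precomputed, leaving only three
exponentials per candidate. A solution within 0.1% of a bound is
flagged capped. The procedure is fully deterministic. Non-finite model
output at a start discards that start with a log entry.

Capping is informative, not a failure: when the true bulk capacitance
exceeds the 10⁻⁷ F upper bound (typical early, before fibrosis has
compacted the tissue) the fit caps there, and the cap fraction falls over
the time course as C drops into range. Correlations between VW-fitted
and EIS-fitted elements are therefore reported with capped fits excluded,
plus a variant additionally excluding R₁ > 2 kΩ outliers.

## The synthetic cohort generator

The generator is the statistical stand-in for the study's measurements;
its defaults are the study conditions of every end-to-end test.

Per electrode, baseline elements are drawn once — R₁₀ ∈ [100, 250] Ω and
R₂ ∈ [50, 150] Ω uniform; C₀ ∈ [0.15, 0.6] µF and Y ∈ [0.9, 1.3] µS·sᵖ
log-uniform; p ∈ [0.78, 0.82] uniform — and the trajectory over the
measurement days {2, 4, 7, 9, 11, 14} is: R₁ a linear-scale logistic rise
(fold ×2–4, inflection day uniform in [7, 9], width 1.5 days), C a
geometric logistic fall (fold ÷2–10, inflection in [4, 7]), Y, p, R₂
constant. The fold magnitudes share a per-electrode "severity" factor
(weight 0.7): encapsulation drives the R₁ rise and C fall jointly, and
without that coupling the SPPR slope (mechanistically dominated by the C
fall) would carry no information about an electrode's final R₁. If a
construct contracts off an electrode, parameters revert to baseline from
the next measurement day (instantaneous reversion; no kinetics are
available to calibrate anything slower) and construct-on flags turn
false.

The parameter regime was chosen by working the QC rules and the marker
mechanism backwards, since no absolute element values are published for
this system: |Z(10 Hz)| must stay in the tens of kΩ (below the 50 kΩ
exclusion) while the 1 kHz phase stays below −20° even at the most
fibrotic excursion — jointly these bound R₁+R₂ ≲ 1.5 kΩ against the CPE
magnitude — and R₁C must sit near T₀ = 50 µs so the capacitive-discharge
mechanism is active and C is identifiable inside the 10 Hz–100 kHz band
(knee at 1/(2πR₁C) ≈ 1–10 kHz). The sub-µF baseline C also reproduces
the observed early capping of waveform-fitted C at its 10⁻⁷ F bound.

Measurement noise: per EIS repeat, multiplicative log-normal magnitude
noise (σ = 2% in log units) and additive Gaussian phase noise (σ = 1°);
per waveform repeat, additive Gaussian noise (σ = 2 mV against ~30–80 mV
peaks) plus a constant per-repeat offset (σ = 5 mV) emulating
environmental drift. Raw waveforms embed the dense simulated response
after a ≥80 µs quiet segment; the cohort generator samples at 12.5 MHz
with factor-2 decimation (same 6.25 MHz working grid and 80 µs/500-sample
baseline window as the 125 MHz/factor-20 lab chain) to keep a
30-electrode, 6-day cohort tractable on one CPU. Degenerate recordings
are constructed to trip exactly one rule each: a CPE-like 200 kΩ
spectrum (R2), a flat near-resistive −5° spectrum (R3), and a sound
spectrum whose three repeats carry −10°/0°/+10° phase offsets so every
per-frequency phase std is exactly 10° while the mean is untouched (R1).

All randomness flows from the config seed through a single generator;
equal configs give bit-identical cohorts, and every generated measurement
retains its generating parameters for recovery scoring.

## What the synthetic data does and does not show

The generator reproduces the measurement geometry (grids, repeats,
sampling), the noise scale, the trajectory shapes and the degenerate
failure modes, so green tests demonstrate that the pipeline recovers
known ground truth under those conditions. It does not emulate
electrode-to-electrode covariance beyond the severity coupling,
non-stationary drift within a sweep, Faradaic nonlinearity at the
interface, amplifier saturation, or biological variance between
experiments — so passing tests bound algorithmic, not instrumental,
error. Correlation signs and orderings from the cohort are properties
of the configured trajectories; their magnitudes are not calibrated to
any particular dataset.

## Problem sizes and numerical choices

Default test/driver sizes: 41-point spectra, 3 EIS repeats; waveform fits
on ~625 samples per window at 6.25 MHz; the study driver uses 10 starts
per dimension for the reverse fit (spot-checked equivalent to the full
30×30 grid on noise-free and noisy examples), 30 electrodes × 6 days for
the end-to-end cohort. Tolerances: cost tolerance 10⁻¹⁰ (EIS) and
10⁻¹² (VW); cap detection at 0.1% of a bound; onset noise floor at 3×
the pre-stimulus std. Ties in the multistart (identical ssq from
different starts) resolve to the first start in grid order.

## Known limitations

- The interphase-gap pulse generalization is used for patient telemetry
  arithmetic only; the in-vitro pipeline is zero-gap.
- No Kramers–Kronig validity testing, Warburg or inductive elements, or
  uncertainty quantification beyond cap flags.
- The SPPR monotonicity map is a regime property (τ ≳ 0.5), not global.
- ANOVA/Tukey-style significance machinery is deliberately out of scope;
  the study driver emits tidy tables for external statistics tools.
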