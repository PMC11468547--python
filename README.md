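# eispulse

Equivalent-circuit analysis of electrode impedance spectra and
biphasic-pulse voltage waveforms, for monitoring fibrotic encapsulation of
stimulation electrodes such as cochlear-implant arrays.

When dense fibrotic tissue forms around an implanted electrode, the bulk
resistance of the surrounding tissue rises and its bulk capacitance falls,
while the electrode–electrolyte interface stays largely unchanged. `eispulse`
turns that observation into a reusable pipeline for bioelectronics groups and
CI researchers who want to track encapsulation from electrical measurements
alone:

- **Circuit model.** A constant phase element (CPE) for the interface in
  series with a parallel R₁‖C block (bulk tissue) and a series resistor R₂
  (medium and ground path):

  Z(s) = 1/(Y·sᵖ) + R₁/(1 + s·R₁·C) + R₂,  s = jω

  A legacy two-element circuit (access resistance + polarization R‖C) is
  included for comparison.
- **EIS fitting.** Quality screening of repeated spectra (phase-spread,
  open-circuit and near-resistive exclusion rules), then complex nonlinear
  least squares with modulus weighting, endpoint start-value heuristics
  (CPE-P starts at 0.8, both resistors at |Z(100 kHz)|, Y and C solved at
  10 Hz), R₂ fixed from the first timepoint and warm starts along the time
  course.
- **Pulse transients.** The closed-form voltage response to a
  charge-balanced biphasic current pulse, via the inverse Laplace transform
  of I(s)·Z(s): each current edge contributes a shifted copy of the step
  response r(t) = tᵖ/(Y·Γ(p+1)) + R₁(1 − e^(−t/(R₁C))) + R₂. An independent
  numerical inverse-Laplace backend (fixed Talbot contour) validates it.
- **Clinical markers.** Contact "impedance" (first-phase peak over input
  current), the second phase peak ratio (SPPR = second-phase peak as % of
  first-phase peak), their day-2-normalized variants, the SPPR slope with
  its inclusion rules, and patient-telemetry arithmetic (25 µs contact
  impedance, altered SPPR 6 µs into each phase, CL → µA conversion).
- **Reverse waveform fitting.** R₁ and C recovered from a measured waveform
  with the interface elements and R₂ pinned to day-2 EIS values: bounded
  least squares from a 30×30 grid of starts (R₁ ∈ 50–5000 Ω,
  C ∈ 10⁻¹³–10⁻⁷ F), with explicit capped-at-bound flags.
- **Synthetic cohorts.** A seeded generator of fibrosis-like parameter
  trajectories (logistic R₁ rise with day 7–9 inflection, logistic C fall
  with day 4–7 inflection, constant CPE and R₂), noisy EIS repeats, raw
  waveform repeats and degenerate recordings (open circuit, air bubble,
  noisy phase), so the whole pipeline is testable without instrument data.

The two fitting procedures are scikit-learn-style estimators
(`EquivalentCircuitFitter`, `WaveformCircuitFitter`) with `fit`/`predict`
and trailing-underscore fitted attributes; module-level functions
(`fit_spectrum`, `vw_fit`, …) wrap them.

## Worked example

Fit a noisy synthetic spectrum, then read the fibrosis markers off the
simulated pulse response:

```python
import numpy as np
from eispulse import (CircuitParams, PulseSpec, fit_spectrum, synth_eis,
                      simulate_waveform, contact_impedance, sppr)

truth = CircuitParams(cpe_t=1.1e-6, cpe_p=0.8, r1=180.0, c=3.0e-7, r2=90.0)
rec = synth_eis(truth, mag_noise=0.02, phase_noise_deg=1.0, rng=0)
fit = fit_spectrum(rec.mean_spectrum())
print(fit.params.to_dict(), fit.weighted_ssq)

pulse = PulseSpec(i_amp=50e-6, t0=50e-6)           # 50 uA, 50 us per phase
t = np.arange(0.0, 2 * pulse.duration, 1 / 6.25e6)
wf = simulate_waveform(fit.params, pulse, t)
print(contact_impedance(wf, pulse), sppr(wf, pulse))
```

This prints (fitted elements rounded):

```
{'cpe_t': 1.099e-06, 'cpe_p': 0.8003, 'r1': 181.3, 'c': 3.004e-07, 'r2': 90.07}  0.0220
551.5  44.5
```

The circuit elements are recovered to well under 1% despite 2% magnitude /
1° phase measurement noise, with an average weighted sum-of-squares of
0.022% — the modulus-weighted residual on the percentage-error scale. The
simulated pulse response of that electrode has a contact impedance of
~552 Ω and an SPPR of ~44%. Raising R₁ to 540 Ω and dropping C to 60 nF
(a fibrosed state) moves them to ~868 Ω and ~59%: both markers rise with
encapsulation, which is what makes them clinically useful.

A full in-silico study — QC, per-electrode time-course fits, waveform
preprocessing, markers, reverse fits and the marker/element correlation
table — runs with:

```bash
eispulse run-study --synthetic-seed 1 --n-electrodes 12 --out report/
```

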