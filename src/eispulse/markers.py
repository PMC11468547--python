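"""Clinically measurable fibrosis markers from pulse voltage waveforms.

Contact "impedance" is the telemetry quantity used in the clinic: the
first-phase voltage peak (or the voltage at a fixed offset near the end
of the first phase, for patient telemetry) divided by the input current.
It is not a true frequency-resolved impedance, hence the quotes.

The second phase peak ratio (SPPR) is the second-phase voltage peak as a
percentage of the first-phase peak.  As encapsulating tissue stiffens
(bulk R1 up, bulk C down) the capacitive discharge contributing to the
second phase shrinks, so the SPPR rises -- the mechanism that makes it a
fibrosis-progression marker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .waveform import CATHODIC, PulseSpec, VoltageWaveform


@dataclass
class MarkerSeries:
    """Day-indexed marker trajectories for one electrode."""

    electrode_id: str
    days: np.ndarray
    contact_impedance: np.ndarray  # ohm
    sppr: np.ndarray  # percent
    construct_on: np.ndarray  # bool
    baseline_day: int | None = None  # set once normalized

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.contact_impedance = np.asarray(self.contact_impedance, dtype=float)
        self.sppr = np.asarray(self.sppr, dtype=float)
        self.construct_on = np.asarray(self.construct_on, dtype=bool)
        n = self.days.size
        if not (self.contact_impedance.size == self.sppr.size == self.construct_on.size == n):
            raise ValueError("marker arrays must align on days")
        if np.any(self.sppr[np.isfinite(self.sppr)] < 0):
            raise ValueError("sppr must be non-negative")


@dataclass
class PatientTelemetry:
    """Voltages sampled at fixed offsets inside each phase of a clinical pulse.

    ``phase1_samples`` / ``phase2_samples`` map offset (microseconds into
    the phase) to measured voltage (V, signed values accepted; magnitudes
    are used downstream).
    """

    patient_id: str
    electrode_number: int
    visit: str
    phase1_samples: dict[float, float]
    phase2_samples: dict[float, float]
    input_current: float  # A
    mcl_cl: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.electrode_number <= 22:
            raise ValueError("electrode_number must lie in 1..22")
        if self.input_current <= 0:
            raise ValueError("input_current must be strictly positive")
        for d in (self.phase1_samples, self.phase2_samples):
            if any(k <= 0 for k in d):
                raise ValueError("sample offsets must be positive")


def _phase_windows(waveform: VoltageWaveform, pulse: PulseSpec):
    if waveform.onset_time is None:
        raise ValueError("waveform is not aligned: onset_time unset (run detect_onset)")
    t = waveform.times - waveform.onset_time
    first = (t >= 0) & (t < pulse.t0)
    second = (t >= pulse.t0 + pulse.gap) & (t < pulse.duration)
    if not first.any() or t[-1] < pulse.t0:
        raise ValueError("first-phase window lies outside the recorded waveform")
    return first, second


def contact_impedance(waveform: VoltageWaveform, pulse: PulseSpec) -> float:
    """First-phase voltage peak divided by the input current, ohm.

    For this circuit the first-phase voltage magnitude grows monotonically
    through the phase, so the peak coincides with the end-of-phase value.
    Invariant to pulse polarity and to current scaling.
    """
    first, _ = _phase_windows(waveform, pulse)
    return float(np.max(np.abs(waveform.mean_v[first])) / pulse.i_amp)


def sppr(waveform: VoltageWaveform, pulse: PulseSpec) -> float:
    """Second phase peak ratio: second-phase peak as % of first-phase peak.

    The second-phase peak is the extremum of the opposite-polarity
    excursion within the second-phase window; magnitudes throughout, so
    the ratio is polarity-free.
    """
    first, second = _phase_windows(waveform, pulse)
    if not second.any() or waveform.times[-1] - waveform.onset_time < pulse.duration:
        raise ValueError("second-phase window lies outside the recorded waveform")
    v = waveform.mean_v
    i_peak = int(np.argmax(np.abs(v[first])))
    first_peak = float(np.abs(v[first])[i_peak])
    if first_peak == 0:
        raise ValueError("zero first-phase peak: SPPR undefined")
    s1 = np.sign(v[first][i_peak])
    opposite = np.clip(-s1 * v[second], 0.0, None)
    return float(100.0 * opposite.max() / first_peak)


def _sample_at(samples: dict[float, float], offset_us: float) -> float:
    for k, v in samples.items():
        if abs(k - offset_us) < 1e-9:
            return v
    raise ValueError(f"no sample at {offset_us:g} us into the phase")


def altered_sppr(telemetry: PatientTelemetry, offset_us: float = 6.0) -> float:
    """Clinical SPPR variant from voltages 6 us into each phase, percent."""
    v1 = abs(_sample_at(telemetry.phase1_samples, offset_us))
    v2 = abs(_sample_at(telemetry.phase2_samples, offset_us))
    if v1 == 0:
        raise ValueError("zero phase-1 voltage: altered SPPR undefined")
    return float(100.0 * v2 / v1)


def patient_contact_impedance(telemetry: PatientTelemetry, offset_us: float = 25.0) -> float:
    """Clinical contact impedance: |V| at the end of the first phase / current."""
    v1 = abs(_sample_at(telemetry.phase1_samples, offset_us))
    return float(v1 / telemetry.input_current)


def normalize_series(series: MarkerSeries, baseline_day: int = 2) -> MarkerSeries:
    """Express both markers relative to their baseline-day value (baseline = 1).

    Idempotent: renormalizing an already-normalized series is a no-op.
    """
    match = np.flatnonzero(series.days == baseline_day)
    if match.size == 0:
        raise ValueError(f"baseline day {baseline_day} not present in series")
    i = int(match[0])
    ci0, sp0 = series.contact_impedance[i], series.sppr[i]
    if not np.isfinite(ci0) or ci0 == 0 or not np.isfinite(sp0) or sp0 == 0:
        raise ValueError(f"baseline day {baseline_day} marker is zero or missing")
    return replace(
        series,
        contact_impedance=series.contact_impedance / ci0,
        sppr=series.sppr / sp0,
        baseline_day=baseline_day,
    )


@dataclass(frozen=True)
class SpprSlope:
    """OLS slope of SPPR vs day over the included timepoints."""

    slope: float  # %/day
    intercept: float
    n_points: int
    final_day: int  # last included day, for pairing with EIS fits


@dataclass(frozen=True)
class SlopeRefusal:
    """Explicit non-numeric refusal (too few points / no point beyond day 7)."""

    reason: str


def sppr_slope(
    series: MarkerSeries, min_points: int = 3, beyond_day: int = 7
) -> SpprSlope | SlopeRefusal:
    """Linear SPPR trend over construct-on timepoints, or an explicit refusal.

    Included: construct-on days with finite SPPR.  Refuses when fewer
    than ``min_points`` remain or no included day lies beyond
    ``beyond_day`` (the R1 inflection); refusals are distinct from zero.
    """
    mask = series.construct_on & np.isfinite(series.sppr)
    days = series.days[mask]
    vals = series.sppr[mask]
    if days.size < min_points:
        return SlopeRefusal(f"only {days.size} construct-on timepoints (need {min_points})")
    if not np.any(days > beyond_day):
        return SlopeRefusal(f"no timepoint beyond day {beyond_day}")
    slope, intercept = np.polyfit(days, vals, 1)
    return SpprSlope(
        slope=float(slope),
        intercept=float(intercept),
        n_points=int(days.size),
        final_day=int(days.max()),
    )


def cl_to_microamps(cl) -> np.ndarray | float:
    """Convert implant current-level units to microamps: 17.5 * 100**(CL/255)."""
    cl_arr = np.asarray(cl, dtype=float)
    if np.any(cl_arr < 0):
        raise ValueError("current level must be non-negative")
    out = 17.5 * 100.0 ** (cl_arr / 255.0)
    return out if np.ndim(cl) else float(out)


def pearson_ci(x, y, confidence: float = 0.95) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval (default 95%)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size != x.size:
        raise ValueError("pearson_ci needs aligned samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(ci.low), float(ci.high)
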