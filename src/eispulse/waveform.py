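"""Voltage transients of biphasic current pulses through the electrode circuit.

The closed-form response follows from the inverse Laplace transform of
I(s) * Z(s): each rectangular current step contributes a shifted copy of
the circuit's unit step response

    r(t) = t**p / (Y * Gamma(p+1)) + R1 * (1 - exp(-t/(R1*C))) + R2

so a charge-balanced biphasic pulse (cathodic-leading, no interphase gap)
gives

    V(t) = -i_amp * [ r(t)u(t) - 2 r(t-T0)u(t-T0) + r(t-2T0)u(t-2T0) ].

With an interphase gap the four current edges contribute four shifted
copies.  A numerical inverse-Laplace backend (fixed Talbot contour)
serves as an independent oracle.

Raw measured waveforms are preprocessed as in the lab pipeline: first
order digital Butterworth low-pass (80 kHz), decimation (factor 20),
baseline subtraction over the pre-stimulus window, then mean/std across
repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import gamma as _gamma

from .circuit import CircuitParams

logger = logging.getLogger(__name__)

CATHODIC = "cathodic-leading"
ANODIC = "anodic-leading"


class OnsetNotFoundError(ValueError):
    """Raised when no stimulus onset rises above the noise floor."""


@dataclass(frozen=True)
class PulseSpec:
    """Charge-balanced biphasic rectangular current pulse.

    i_amp : phase current amplitude, A (positive number).
    t0    : phase duration, s.
    gap   : interphase gap, s (0 for the in-vitro pulse, 9 us clinically).
    polarity : "cathodic-leading" (first phase negative) or "anodic-leading".
    """

    i_amp: float
    t0: float
    gap: float = 0.0
    polarity: str = CATHODIC

    def __post_init__(self) -> None:
        if self.i_amp <= 0:
            raise ValueError("i_amp must be strictly positive")
        if self.t0 <= 0:
            raise ValueError("t0 must be strictly positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.polarity not in (CATHODIC, ANODIC):
            raise ValueError(f"polarity must be {CATHODIC!r} or {ANODIC!r}")

    @property
    def duration(self) -> float:
        """Total pulse support, 2*t0 + gap."""
        return 2 * self.t0 + self.gap

    @property
    def sign(self) -> float:
        """Sign of the leading phase (-1 cathodic, +1 anodic)."""
        return -1.0 if self.polarity == CATHODIC else 1.0


@dataclass
class RawWaveformSet:
    """Repeated raw oscilloscope traces of one pulse on one electrode."""

    sampling_rate: float
    repeats: np.ndarray  # (n_repeats, n_samples), volt
    pre_stimulus_samples: int

    def __post_init__(self) -> None:
        self.repeats = np.atleast_2d(np.asarray(self.repeats, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be strictly positive")
        if self.pre_stimulus_samples < 0:
            raise ValueError("pre_stimulus_samples must be non-negative")


@dataclass
class VoltageWaveform:
    """Mean voltage trace on a uniform time grid, with repeat spread."""

    times: np.ndarray
    mean_v: np.ndarray
    std_v: np.ndarray
    sampling_rate: float
    onset_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_v = np.asarray(self.mean_v, dtype=float)
        self.std_v = np.asarray(self.std_v, dtype=float)
        if not np.all(np.isfinite(self.mean_v)):
            raise ValueError("mean_v must be finite everywhere")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            raise ValueError("times must be a uniform grid")


def _check_uniform(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
        raise ValueError("time grid must be uniform with at least two samples")
    return times


def biphasic_current(pulse: PulseSpec, times) -> np.ndarray:
    """Time-domain biphasic current trace on a uniform grid, ampere.

    Half-open phase windows: leading phase on [0, t0), trailing phase on
    [t0+gap, 2*t0+gap); zero elsewhere, so integrated charge is zero.
    """
    times = _check_uniform(times)
    i = np.zeros_like(times)
    lead = (times >= 0) & (times < pulse.t0)
    trail = (times >= pulse.t0 + pulse.gap) & (times < pulse.duration)
    i[lead] = pulse.sign * pulse.i_amp
    i[trail] = -pulse.sign * pulse.i_amp
    return i


def step_response(params: CircuitParams, t) -> np.ndarray:
    """Unit current-step voltage response r(t); zero for t < 0.

    Switching instants use the right-limit convention: r(0) = R2.
    """
    t = np.asarray(t, dtype=float)
    on = t >= 0
    tp = np.where(on, t, 0.0)
    out = np.zeros_like(tp)
    out[on] = (
        tp[on] ** params.cpe_p / (params.cpe_t * _gamma(params.cpe_p + 1))
        + params.r1 * (1.0 - np.exp(-tp[on] / (params.r1 * params.c)))
        + params.r2
    )
    return out


def _edge_times_and_signs(pulse: PulseSpec) -> list[tuple[float, float]]:
    """Current edges as (time, step amplitude in units of sign*i_amp)."""
    return [
        (0.0, 1.0),
        (pulse.t0, -1.0),
        (pulse.t0 + pulse.gap, -1.0),
        (pulse.duration, 1.0),
    ]


def simulate_waveform(params: CircuitParams, pulse: PulseSpec, times) -> VoltageWaveform:
    """Closed-form voltage response of the circuit to a biphasic pulse.

    For gap = 0 the middle two edges coincide and the expression reduces
    to the three-term form r(t) - 2 r(t-T0) + r(t-2T0).
    """
    times = _check_uniform(times)
    v = np.zeros_like(times)
    for t_edge, amp in _edge_times_and_signs(pulse):
        v += amp * step_response(params, times - t_edge)
    v *= pulse.sign * pulse.i_amp
    dt = times[1] - times[0]
    return VoltageWaveform(
        times=times, mean_v=v, std_v=np.zeros_like(v), sampling_rate=1.0 / dt, onset_time=0.0
    )


# ---------------------------------------------------------------------------
# Independent numerical-inversion backend (fixed Talbot contour)
# ---------------------------------------------------------------------------


def _talbot_step_response(params: CircuitParams, t: np.ndarray, m: int = 48) -> np.ndarray:
    """L^{-1}[Z(s)/s] by the fixed Talbot method, per time point.

    Never calls the closed form; Z(s) is evaluated from the Laplace-domain
    circuit expression directly.
    """

    def laplace_f(s: np.ndarray) -> np.ndarray:
        z = (
            1.0 / (params.cpe_t * s**params.cpe_p)
            + params.r1 / (1.0 + s * params.r1 * params.c)
            + params.r2
        )
        return z / s

    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tpos = t[pos]
    if tpos.size:
        r = 2.0 * m / (5.0 * tpos)  # (n_t,)
        theta = (np.arange(1, m) * np.pi / m)[:, None]  # (m-1, 1)
        cot = 1.0 / np.tan(theta)
        s = r * theta * (cot + 1j)  # (m-1, n_t)
        sigma = theta + (theta * cot - 1.0) * cot
        terms = np.real(np.exp(tpos * s) * laplace_f(s) * (1.0 + 1j * sigma))
        total = 0.5 * laplace_f(r + 0j).real * np.exp(r * tpos) + terms.sum(axis=0)
        out[pos] = total * r / m
    out[t == 0] = 0.0
    return out


def simulate_waveform_numeric(
    params: CircuitParams, pulse: PulseSpec, times, m: int = 48
) -> VoltageWaveform:
    """Numerical inverse-Laplace oracle for :func:`simulate_waveform`.

    Intended for testing, not production (orders of magnitude slower).
    """
    if not 0 < params.cpe_p <= 1:
        raise ValueError("cpe_p must lie in (0, 1]")
    times = _check_uniform(times)
    v = np.zeros_like(times)
    for t_edge, amp in _edge_times_and_signs(pulse):
        v += amp * _talbot_step_response(params, times - t_edge, m=m)
    v *= pulse.sign * pulse.i_amp
    dt = times[1] - times[0]
    return VoltageWaveform(
        times=times, mean_v=v, std_v=np.zeros_like(v), sampling_rate=1.0 / dt, onset_time=0.0
    )


# ---------------------------------------------------------------------------
# Measured-waveform preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    raw: RawWaveformSet,
    cutoff_hz: float = 80e3,
    downsample_factor: int = 20,
    baseline_samples: int = 500,
) -> VoltageWaveform:
    """Filter, decimate and baseline-correct repeated raw traces.

    Per repeat: first-order digital Butterworth low-pass (causal, as with
    MATLAB ``filter``), plain sample-picking decimation, subtraction of
    the mean over the first ``baseline_samples`` output samples (which
    must all precede stimulus onset).  Mean and std are taken across
    repeats afterwards.
    """
    if downsample_factor < 1 or int(downsample_factor) != downsample_factor:
        raise ValueError("downsample_factor must be a positive integer")
    downsample_factor = int(downsample_factor)
    n_raw = raw.repeats.shape[1]
    if n_raw % downsample_factor:
        logger.warning(
            "preprocess: trace length %d not divisible by %d; truncating",
            n_raw,
            downsample_factor,
        )
    n_out = n_raw // downsample_factor
    pre_out = raw.pre_stimulus_samples // downsample_factor
    if baseline_samples > pre_out:
        raise ValueError(
            f"baseline window ({baseline_samples} samples) overlaps the stimulus: "
            f"only {pre_out} pre-stimulus samples remain after decimation"
        )
    b, a = sps.butter(1, cutoff_hz / (raw.sampling_rate / 2.0))
    # steady-state initial conditions: a constant (pre-stimulus) level passes
    # through unchanged instead of producing a start-up transient, so the
    # per-repeat environmental offset is removed exactly by baselining
    zi = sps.lfilter_zi(b, a)
    processed = np.empty((raw.repeats.shape[0], n_out))
    for k, trace in enumerate(raw.repeats):
        filtered, _ = sps.lfilter(b, a, trace, zi=zi * trace[0])
        down = filtered[::downsample_factor][:n_out]
        processed[k] = down - down[:baseline_samples].mean()
    fs_out = raw.sampling_rate / downsample_factor
    times = (np.arange(n_out) - pre_out) / fs_out
    return VoltageWaveform(
        times=times,
        mean_v=processed.mean(axis=0),
        std_v=processed.std(axis=0, ddof=1) if processed.shape[0] > 1 else np.zeros(n_out),
        sampling_rate=fs_out,
        onset_time=None,
    )


def detect_onset(waveform: VoltageWaveform, noise_floor_factor: float = 3.0) -> float:
    """Locate the stimulus onset as the single RMS-level change point.

    The split index minimizes the two-segment Gaussian variance cost
    n1*log(rms1^2) + n2*log(rms2^2) (zero-mean segments), i.e. maximizes
    the between-segment difference in RMS level.  Raises
    :class:`OnsetNotFoundError` when no post-onset sample exceeds
    ``noise_floor_factor`` times the pre-onset standard deviation.
    """
    x = waveform.mean_v
    # The onset precedes the absolute voltage peak by construction, so the
    # change-point search is confined to [0, argmax|V|]; without this the
    # quiet-loud-quiet record can split at the pulse END instead.
    i_peak = int(np.argmax(np.abs(x)))
    n = i_peak + 1
    if n < 4:
        raise OnsetNotFoundError("waveform too short for change-point detection")
    seg = x[:n]
    css = np.concatenate([[0.0], np.cumsum(seg**2)])
    k = np.arange(2, n - 1)
    eps = 1e-300
    m1 = css[k] / k
    m2 = (css[-1] - css[k]) / (n - k)
    cost = k * np.log(m1 + eps) + (n - k) * np.log(m2 + eps)
    k_best = int(k[np.argmin(cost)])
    pre_std = float(np.std(x[:k_best]))
    post_peak = float(np.max(np.abs(x[k_best:] - x[:k_best].mean())))
    if post_peak <= noise_floor_factor * pre_std or post_peak == 0.0:
        raise OnsetNotFoundError("no onset detected: signal does not exceed the noise floor")
    return float(waveform.times[k_best])
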