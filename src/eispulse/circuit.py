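"""Equivalent-circuit models of a fibrosing stimulation electrode.

The main circuit is a constant phase element (CPE, the non-ideal
electrode-electrolyte interface) in series with a parallel R1||C block
(the bulk of the encapsulating tissue) and a series resistor R2 (media
and path to ground):

    Z(s) = 1 / (Y * s**p) + R1 / (1 + s*R1*C) + R2,    s = j*omega

An alternate, simpler legacy circuit (access resistance in series with a
polarization R||C) is provided for comparison.

Phases are stored in degrees (negative = capacitive, matching instrument
exports); all internal arithmetic is in radians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Circuit element names, in canonical order.
ELEMENT_NAMES = ("cpe_t", "cpe_p", "r1", "c", "r2")
SIMPLE_ELEMENT_NAMES = ("r_access", "r_pol", "c_pol")


def default_frequency_grid() -> np.ndarray:
    """10 Hz - 100 kHz, 10 points per decade, both endpoints included (41 points)."""
    return np.logspace(1.0, 5.0, 41)


@dataclass(frozen=True)
class CircuitParams:
    """The five elements of the CPE + R1||C + R2 circuit.

    Parameters
    ----------
    cpe_t : float
        CPE magnitude Y in S*s^p.
    cpe_p : float
        CPE exponent p, in (0, 1]; p = 1 is an ideal capacitor.
    r1 : float
        Bulk (tissue) resistance, ohm.
    c : float
        Bulk capacitance, F.
    r2 : float
        Series (media + ground) resistance, ohm.
    """

    cpe_t: float
    cpe_p: float
    r1: float
    c: float
    r2: float

    def __post_init__(self) -> None:
        for name in ELEMENT_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")
        if self.cpe_p > 1:
            raise ValueError(f"cpe_p must lie in (0, 1], got {self.cpe_p!r}")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in ELEMENT_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParams":
        return cls(**{name: d[name] for name in ELEMENT_NAMES})

    def replace(self, **kw: float) -> "CircuitParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimpleCircuitParams:
    """Legacy two-element waveform circuit: R_access + (R_pol || C_pol)."""

    r_access: float
    r_pol: float
    c_pol: float

    def __post_init__(self) -> None:
        for name in SIMPLE_ELEMENT_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in SIMPLE_ELEMENT_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SimpleCircuitParams":
        return cls(**{name: d[name] for name in SIMPLE_ELEMENT_NAMES})


@dataclass
class ImpedanceSpectrum:
    """Frequency-resolved complex impedance, stored as magnitude + phase.

    ``repeat_std`` carries per-frequency standard deviations (magnitude,
    phase) across measurement repeats when the spectrum is a mean of
    repeats; it is ``None`` for model-generated spectra.
    """

    frequencies: np.ndarray
    z_mag: np.ndarray
    phase_deg: np.ndarray
    mag_std: np.ndarray | None = None
    phase_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z_mag = np.asarray(self.z_mag, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.frequencies.ndim != 1:
            raise ValueError("frequencies must be one-dimensional")
        if not (self.z_mag.shape == self.phase_deg.shape == self.frequencies.shape):
            raise ValueError("frequencies, z_mag and phase_deg must share a shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.z_mag <= 0):
            raise ValueError("impedance magnitude must be strictly positive")
        if np.any((self.phase_deg <= -90) | (self.phase_deg > 90)):
            raise ValueError("phase must lie in (-90, 90] degrees")
        for attr in ("mag_std", "phase_std"):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, np.asarray(value, dtype=float))

    @property
    def z(self) -> np.ndarray:
        """Complex impedance, ohm."""
        return self.z_mag * np.exp(1j * np.deg2rad(self.phase_deg))

    @classmethod
    def from_complex(cls, frequencies: np.ndarray, z: np.ndarray) -> "ImpedanceSpectrum":
        z = np.asarray(z, dtype=complex)
        return cls(
            frequencies=np.asarray(frequencies, dtype=float),
            z_mag=np.abs(z),
            phase_deg=np.rad2deg(np.angle(z)),
        )

    def nearest_index(self, frequency: float) -> int:
        return int(np.argmin(np.abs(np.log(self.frequencies) - np.log(frequency))))


def _validate_frequency(frequency) -> np.ndarray:
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequency must be finite and strictly positive")
    return f


def cpe_impedance(cpe_t: float, cpe_p: float, frequency) -> np.ndarray | complex:
    """Impedance of a constant phase element, 1 / (Y * (j*omega)^p).

    The returned phase is exactly -p * 90 degrees at every frequency.
    """
    if cpe_t <= 0:
        raise ValueError("cpe_t must be strictly positive")
    if not 0 < cpe_p <= 1:
        raise ValueError("cpe_p must lie in (0, 1]")
    f = _validate_frequency(frequency)
    s = 1j * 2 * np.pi * f
    z = 1.0 / (cpe_t * s**cpe_p)
    return z if np.ndim(frequency) else complex(z)


def circuit_impedance(params: CircuitParams, frequency) -> np.ndarray | complex:
    """Total impedance of the CPE + R1||C + R2 circuit at ``frequency`` (Hz)."""
    f = _validate_frequency(frequency)
    s = 1j * 2 * np.pi * f
    z = 1.0 / (params.cpe_t * s**params.cpe_p)
    z = z + params.r1 / (1.0 + s * params.r1 * params.c) + params.r2
    return z if np.ndim(frequency) else complex(z)


def simple_circuit_impedance(params: SimpleCircuitParams, frequency) -> np.ndarray | complex:
    """Impedance of the legacy access-resistance / polarization circuit."""
    f = _validate_frequency(frequency)
    s = 1j * 2 * np.pi * f
    z = params.r_access + params.r_pol / (1.0 + s * params.r_pol * params.c_pol)
    return z if np.ndim(frequency) else complex(z)


def _endpoint_magnitude(spectrum: ImpedanceSpectrum, target_hz: float) -> float:
    """|Z| at the grid point nearest ``target_hz``; warn if inexact, error if far.

    "Far" means more than a factor of two off the requested frequency --
    at that distance the decade-endpoint heuristics no longer apply.
    """
    idx = spectrum.nearest_index(target_hz)
    actual = spectrum.frequencies[idx]
    ratio = max(actual / target_hz, target_hz / actual)
    if ratio > 2.0:
        raise ValueError(
            f"spectrum lacks a point near {target_hz:g} Hz "
            f"(closest available: {actual:g} Hz)"
        )
    if not np.isclose(actual, target_hz, rtol=1e-6):
        logger.warning(
            "start_values: substituting nearest frequency %g Hz for %g Hz", actual, target_hz
        )
    return float(spectrum.z_mag[idx])


def start_values(spectrum: ImpedanceSpectrum, cpe_p_init: float = 0.8) -> CircuitParams:
    """Heuristic start values for the circuit fit, from the decade endpoints.

    CPE-P is fixed at ``cpe_p_init``; CPE-T solves the CPE model for Y at
    10 Hz assuming the CPE dominates there; both resistors start at
    |Z(100 kHz)| (resistor-dominated end); C solves the ideal-capacitor
    model at 10 Hz.  These are heuristics only, never fit constraints.
    """
    if not 0 < cpe_p_init <= 1:
        raise ValueError("cpe_p_init must lie in (0, 1]")
    z_lo = _endpoint_magnitude(spectrum, 10.0)
    z_hi = _endpoint_magnitude(spectrum, 1e5)
    omega_lo = 2 * np.pi * 10.0
    return CircuitParams(
        cpe_t=1.0 / (z_lo * omega_lo**cpe_p_init),
        cpe_p=cpe_p_init,
        r1=z_hi,
        c=1.0 / (omega_lo * z_lo),
        r2=z_hi,
    )


def simple_start_values(spectrum: ImpedanceSpectrum) -> SimpleCircuitParams:
    """Start values for the legacy circuit, by the same endpoint heuristics."""
    z_lo = _endpoint_magnitude(spectrum, 10.0)
    z_hi = _endpoint_magnitude(spectrum, 1e5)
    return SimpleCircuitParams(
        r_access=z_hi,
        r_pol=max(z_lo - z_hi, 0.1 * z_lo),
        c_pol=1.0 / (2 * np.pi * 10.0 * z_lo),
    )
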