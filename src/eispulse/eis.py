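"""Quality control and complex nonlinear least-squares fitting of EIS spectra.

Recordings (nominally three repeats per electrode per timepoint) are
screened by three exclusion rules before fitting:

R1  upper quartile of the per-frequency phase standard deviation > 4 deg
R2  mean |Z| at 10 Hz > 50 kOhm (open circuit / broken electrode)
R3  mean phase inside (-20 deg, 0 deg) at any frequency in 10 Hz - 1 kHz
    (near-resistive behaviour, e.g. an air bubble on the electrode)

Fitting minimizes the complex modulus-weighted residual

    ssq% = 100/N * sum_i [ (ReZ_i - ReZhat_i)^2 + (ImZ_i - ImZhat_i)^2 ] / |Z_i|^2

over free elements by bounded trust-region least squares on
log-transformed parameters (elements span several orders of magnitude),
with an iteration cap of 100.  Over a time course the series resistor R2
is fixed from the first kept timepoint and each fit warm-starts from the
previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .circuit import (
    ELEMENT_NAMES,
    SIMPLE_ELEMENT_NAMES,
    CircuitParams,
    ImpedanceSpectrum,
    SimpleCircuitParams,
    circuit_impedance,
    simple_circuit_impedance,
    simple_start_values,
    start_values,
)

logger = logging.getLogger(__name__)

#: Default QC thresholds (rule id -> value), pluggable.
DEFAULT_QC = {
    "phase_std_quantile": 0.75,
    "phase_std_max_deg": 4.0,
    "zmag_max_ohm": 50e3,
    "zmag_at_hz": 10.0,
    "resistive_phase_low_deg": -20.0,
    "resistive_phase_high_deg": 0.0,
    "resistive_band_hz": (10.0, 1e3),
}


@dataclass
class EISRecording:
    """All repeats of one electrode at one study day, on a shared grid."""

    electrode_id: str
    day: int
    repeats: list[ImpedanceSpectrum]
    construct_on: bool = True

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be non-negative")
        if not self.repeats:
            raise ValueError("recording needs at least one repeat")
        f0 = self.repeats[0].frequencies
        for rep in self.repeats[1:]:
            if not np.allclose(rep.frequencies, f0):
                raise ValueError("all repeats must share one frequency grid")

    def mean_spectrum(self) -> ImpedanceSpectrum:
        """Arithmetic mean of magnitude and phase across repeats, with stds."""
        mags = np.stack([r.z_mag for r in self.repeats])
        phases = np.stack([r.phase_deg for r in self.repeats])
        n = len(self.repeats)
        return ImpedanceSpectrum(
            frequencies=self.repeats[0].frequencies,
            z_mag=mags.mean(axis=0),
            phase_deg=phases.mean(axis=0),
            mag_std=mags.std(axis=0, ddof=1) if n > 1 else None,
            phase_std=phases.std(axis=0, ddof=1) if n > 1 else None,
        )


@dataclass(frozen=True)
class QCResult:
    keep: bool
    reasons: tuple[tuple[str, float], ...]  # (rule id, offending value)

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be true iff reasons is empty")


@dataclass(frozen=True)
class FitResult:
    params: CircuitParams | SimpleCircuitParams
    fixed_elements: frozenset[str]
    weighted_ssq: float
    n_iterations: int
    converged: bool
    capped: dict[str, bool] = field(default_factory=dict)


def qc_screen(recording: EISRecording, thresholds: dict | None = None) -> QCResult:
    """Apply the three exclusion rules; all fired rules are reported.

    Requires at least two repeats (phase std undefined otherwise).
    Rule R3 uses the open interval: boundary phases do not trigger it.
    """
    th = dict(DEFAULT_QC)
    if thresholds:
        th.update(thresholds)
    if len(recording.repeats) < 2:
        raise ValueError("qc_screen needs >= 2 repeats (std undefined for one)")
    mean = recording.mean_spectrum()
    reasons: list[tuple[str, float]] = []

    q = float(np.quantile(mean.phase_std, th["phase_std_quantile"]))
    if q > th["phase_std_max_deg"]:
        reasons.append(("R1", q))

    z10 = float(mean.z_mag[mean.nearest_index(th["zmag_at_hz"])])
    if z10 > th["zmag_max_ohm"]:
        reasons.append(("R2", z10))

    lo, hi = th["resistive_band_hz"]
    band = (mean.frequencies >= lo) & (mean.frequencies <= hi)
    in_window = (mean.phase_deg[band] > th["resistive_phase_low_deg"]) & (
        mean.phase_deg[band] < th["resistive_phase_high_deg"]
    )
    if np.any(in_window):
        worst = float(mean.phase_deg[band][in_window][0])
        reasons.append(("R3", worst))

    return QCResult(keep=not reasons, reasons=tuple(reasons))


def _model_impedance(params, frequencies):
    if isinstance(params, SimpleCircuitParams):
        return simple_circuit_impedance(params, frequencies)
    return circuit_impedance(params, frequencies)


def weighted_ssq(
    spectrum: ImpedanceSpectrum,
    params: CircuitParams | SimpleCircuitParams,
    weighting: str = "data",
) -> float:
    """Modulus-weighted mean squared complex residual, percentage scale.

    ``weighting="data"`` divides by |Z_data|^2 (default); ``"model"``
    divides by |Z_model|^2 (the alternative reading of the instrument's
    calc-modulus weighting).
    """
    z = spectrum.z
    zhat = _model_impedance(params, spectrum.frequencies)
    if np.any(np.abs(z) == 0):
        raise ValueError("zero-magnitude data point: modulus weighting undefined")
    w = np.abs(z) if weighting == "data" else np.abs(zhat)
    if np.any(w == 0):
        raise ValueError("zero-magnitude model point: modulus weighting undefined")
    resid = np.abs(z - zhat) ** 2 / w**2
    return float(100.0 * resid.mean())


class EquivalentCircuitFitter(BaseEstimator):
    """Complex nonlinear least-squares fit of an equivalent circuit to EIS data.

    sklearn-style estimator: ``fit(frequencies, z)`` with ``z`` the complex
    impedance; fitted state in trailing-underscore attributes.

    Parameters
    ----------
    model : {"full", "simple"}
        "full" = CPE + R1||C + R2; "simple" = legacy R_access + R_pol||C_pol.
    fixed : dict, optional
        Element name -> value held constant (returned bit-for-bit).
    start : CircuitParams | SimpleCircuitParams, optional
        Start values; derived from the spectrum endpoints when omitted.
    cpe_p_init : float
        Start value of the CPE exponent (heuristic; instrument convention 0.8).
    max_iter : int
        Outer iteration cap of the trust-region solver.
    bounds : (float, float)
        Per-element bounds, effectively unconstrained by default.
    weighting : {"data", "model"}
        Modulus-weighting convention, see :func:`weighted_ssq`.
    """

    def __init__(
        self,
        model: str = "full",
        fixed: dict | None = None,
        start=None,
        cpe_p_init: float = 0.8,
        max_iter: int = 100,
        bounds: tuple[float, float] = (1e-12, 1e6),
        weighting: str = "data",
        tol: float = 1e-10,
    ):
        self.model = model
        self.fixed = fixed
        self.start = start
        self.cpe_p_init = cpe_p_init
        self.max_iter = max_iter
        self.bounds = bounds
        self.weighting = weighting
        self.tol = tol

    def _element_names(self):
        return ELEMENT_NAMES if self.model == "full" else SIMPLE_ELEMENT_NAMES

    def _params_cls(self):
        return CircuitParams if self.model == "full" else SimpleCircuitParams

    def fit(self, frequencies, z):
        """Fit free circuit elements to complex impedance data."""
        frequencies = np.asarray(frequencies, dtype=float)
        z = np.asarray(z, dtype=complex)
        spectrum = ImpedanceSpectrum.from_complex(frequencies, z)
        names = self._element_names()
        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(names)
        if unknown:
            raise ValueError(f"unknown fixed elements for model {self.model!r}: {sorted(unknown)}")
        free = [n for n in names if n not in fixed]
        if not free:
            raise ValueError("all elements fixed: nothing to fit")

        if self.start is not None:
            start = self.start
        elif self.model == "full":
            start = start_values(spectrum, cpe_p_init=self.cpe_p_init)
        else:
            start = simple_start_values(spectrum)
        start_d = start.to_dict()
        start_d.update(fixed)

        lo, hi = self.bounds
        # cpe_p is a dimensionless exponent in (0, 1]; its bounds must not
        # inherit the SI-element range.
        def elem_bounds(name):
            if name == "cpe_p":
                return (1e-3, 1.0)
            return (lo, hi)

        x0 = np.log([np.clip(start_d[n], *elem_bounds(n)) for n in free])
        lb = np.log([elem_bounds(n)[0] for n in free])
        ub = np.log([elem_bounds(n)[1] for n in free])
        zabs = np.abs(z)
        n_pts = z.size
        cls = self._params_cls()

        def residuals(x):
            d = dict(start_d)
            d.update(zip(free, np.exp(x)))
            zhat = _model_impedance(cls.from_dict(d), frequencies)
            w = zabs if self.weighting == "data" else np.abs(zhat)
            r = (z - zhat) / w
            out = np.concatenate([r.real, r.imag])
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(
                    f"non-finite residuals at parameter vector {d!r}"
                )
            return out

        # scipy's TRF emits spurious divide-by-zero warnings when the
        # residual reaches exactly zero (noise-free data).
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            res = least_squares(
                residuals,
                x0,
                bounds=(lb, ub),
                method="trf",
                ftol=self.tol,
                xtol=None,
                gtol=None,
                max_nfev=self.max_iter * (len(free) + 1),
            )
        fitted = dict(start_d)
        fitted.update(zip(free, np.exp(res.x)))
        for name, value in fixed.items():
            fitted[name] = value  # bit-for-bit
        self.params_ = cls.from_dict(fitted)
        self.fixed_elements_ = frozenset(fixed)
        self.weighted_ssq_ = float(100.0 * np.sum(res.fun**2) / n_pts)
        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.capped_ = {
            n: bool(
                np.isclose(fitted[n], elem_bounds(n)[0], rtol=1e-3, atol=0)
                or np.isclose(fitted[n], elem_bounds(n)[1], rtol=1e-3, atol=0)
            )
            for n in free
        }
        return self

    def predict(self, frequencies) -> np.ndarray:
        """Model complex impedance at ``frequencies`` (after fit)."""
        return np.asarray(_model_impedance(self.params_, np.asarray(frequencies, float)))

    def result_(self) -> FitResult:
        return FitResult(
            params=self.params_,
            fixed_elements=self.fixed_elements_,
            weighted_ssq=self.weighted_ssq_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            capped=dict(self.capped_),
        )


def fit_spectrum(
    spectrum: ImpedanceSpectrum,
    start=None,
    fixed_elements: dict | None = None,
    model_kind: str = "full",
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`EquivalentCircuitFitter`."""
    fitter = EquivalentCircuitFitter(
        model=model_kind, fixed=fixed_elements, start=start, **kwargs
    )
    fitter.fit(spectrum.frequencies, spectrum.z)
    return fitter.result_()


def fit_timecourse(
    recordings: list[EISRecording],
    model_kind: str = "full",
    qc_thresholds: dict | None = None,
    **kwargs,
) -> list[FitResult | None]:
    """Fit one electrode's time course with fixed-R2 / warm-start conventions.

    The first QC-kept timepoint is fitted with all elements free from
    endpoint start values; R2 is fixed at that fitted value thereafter and
    each later fit warm-starts from the previous kept result.  QC-excluded
    timepoints yield ``None`` gap markers.
    """
    days = [r.day for r in recordings]
    if days != sorted(days):
        raise ValueError("recordings must be sorted by day")
    results: list[FitResult | None] = []
    r2_fixed: float | None = None
    prev_params = None
    for rec in recordings:
        qc = qc_screen(rec, thresholds=qc_thresholds)
        if not qc.keep:
            logger.info(
                "electrode %s day %d excluded by QC: %s", rec.electrode_id, rec.day, qc.reasons
            )
            results.append(None)
            continue
        spectrum = rec.mean_spectrum()
        if r2_fixed is None:
            fit = fit_spectrum(spectrum, model_kind=model_kind, **kwargs)
            if model_kind == "full":
                r2_fixed = fit.params.r2
            prev_params = fit.params
        else:
            fit = fit_spectrum(
                spectrum,
                start=prev_params,
                fixed_elements={"r2": r2_fixed},
                model_kind=model_kind,
                **kwargs,
            )
            prev_params = fit.params
        results.append(fit)
    if all(r is None for r in results):
        raise ValueError("no timepoint passed QC screening")
    return results
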