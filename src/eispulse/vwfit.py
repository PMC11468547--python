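"""Reverse fitting of bulk circuit elements from pulse voltage waveforms.

With the interface CPE (Y, p) and series resistor R2 pinned to their
day-2 EIS-fitted values, the bulk elements R1 and C are recovered from a
measured waveform by bounded least squares launched from every unique
pair of ``grid_n`` linearly spaced start values per element (30 x 30 =
900 local searches by default); the global best by sum of squared
voltage residuals wins.  Solutions landing on a bound are flagged as
capped -- capping at R1's lower and C's upper bound is the expected
failure mode when the waveform peak is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as _gamma
from sklearn.base import BaseEstimator

from .waveform import PulseSpec, VoltageWaveform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VWFitConfig:
    """Bounds, grid density and fixed elements of the waveform fit."""

    fixed_cpe_t: float
    fixed_cpe_p: float
    fixed_r2: float
    r1_bounds: tuple[float, float] = (50.0, 5000.0)
    c_bounds: tuple[float, float] = (1e-13, 1e-7)
    grid_n: int = 30
    log_spaced: bool = False  # starts on the raw linear scale by default
    cap_rtol: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("r1_bounds", "c_bounds"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= lo:
                raise ValueError(f"{name} must be positive with low < high")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        for name in ("fixed_cpe_t", "fixed_cpe_p", "fixed_r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fixed_cpe_p > 1:
            raise ValueError("fixed_cpe_p must lie in (0, 1]")


@dataclass(frozen=True)
class VWFitResult:
    r1: float
    c: float
    ssq: float  # V^2
    capped_r1: bool
    capped_c: bool
    start_used: tuple[float, float]


class _WaveformModel:
    """Precomputed pieces of the closed-form model over the fit window.

    Only the R1*(1 - exp(-t/(R1 C))) part depends on the free elements;
    the CPE + R2 contributions of the four current edges are fixed and
    evaluated once.
    """

    def __init__(self, times: np.ndarray, pulse: PulseSpec, config: VWFitConfig):
        edges = [
            (0.0, 1.0),
            (pulse.t0, -1.0),
            (pulse.t0 + pulse.gap, -1.0),
            (pulse.duration, 1.0),
        ]
        scale = pulse.sign * pulse.i_amp
        self.shifts = []
        fixed = np.zeros_like(times)
        y, p, r2 = config.fixed_cpe_t, config.fixed_cpe_p, config.fixed_r2
        for t_edge, amp in edges:
            s = times - t_edge
            on = s >= 0
            sp = np.where(on, s, 0.0)
            fixed += amp * np.where(on, sp**p / (y * _gamma(p + 1)) + r2, 0.0)
            self.shifts.append((sp, on, amp))
        self.fixed_part = scale * fixed
        self.scale = scale

    def __call__(self, r1: float, c: float) -> np.ndarray:
        out = np.zeros_like(self.fixed_part)
        tau = r1 * c
        for sp, on, amp in self.shifts:
            out += amp * np.where(on, r1 * (1.0 - np.exp(-sp / tau)), 0.0)
        return self.fixed_part + self.scale * out


def vw_residual(
    waveform: VoltageWaveform,
    r1: float,
    c: float,
    config: VWFitConfig,
    pulse: PulseSpec,
) -> float:
    """Sum of squared voltage residuals (V^2) at candidate (r1, c)."""
    if waveform.onset_time is None:
        raise ValueError("waveform is not aligned: onset_time unset")
    t = waveform.times - waveform.onset_time
    model = _WaveformModel(t, pulse, config)
    return float(np.sum((waveform.mean_v - model(r1, c)) ** 2))


class WaveformCircuitFitter(BaseEstimator):
    """Grid-multistart bounded least-squares fit of (R1, C) from a waveform.

    sklearn-style estimator: ``fit(times, v)`` with ``times`` relative to
    pulse onset.  Deterministic: the start grid has no randomness.

    Fitted attributes: ``r1_``, ``c_``, ``ssq_``, ``capped_r1_``,
    ``capped_c_``, ``start_used_``.
    """

    def __init__(self, pulse: PulseSpec, config: VWFitConfig):
        self.pulse = pulse
        self.config = config

    def _starts(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        if cfg.log_spaced:
            r1s = np.geomspace(*cfg.r1_bounds, cfg.grid_n)
            cs = np.geomspace(*cfg.c_bounds, cfg.grid_n)
        else:
            r1s = np.linspace(*cfg.r1_bounds, cfg.grid_n)
            cs = np.linspace(*cfg.c_bounds, cfg.grid_n)
        return r1s, cs

    def fit(self, times, v):
        times = np.asarray(times, dtype=float)
        v = np.asarray(v, dtype=float)
        cfg = self.config
        model = _WaveformModel(times, self.pulse, cfg)
        lb = np.array([cfg.r1_bounds[0], np.log(cfg.c_bounds[0])])
        ub = np.array([cfg.r1_bounds[1], np.log(cfg.c_bounds[1])])

        def residuals(x):
            return v - model(x[0], np.exp(x[1]))

        best = None
        r1s, cs = self._starts()
        for r1_0 in r1s:
            for c_0 in cs:
                x0 = np.array([r1_0, np.log(c_0)])
                try:
                    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                        res = least_squares(
                            residuals,
                            x0,
                            bounds=(lb, ub),
                            method="trf",
                            ftol=1e-12,
                            xtol=1e-12,
                            gtol=None,
                        )
                    ssq = float(np.sum(res.fun**2))
                    if not np.isfinite(ssq):
                        raise FloatingPointError("non-finite sum of squares")
                except FloatingPointError as exc:
                    logger.info("discarding start (%.3g, %.3g): %s", r1_0, c_0, exc)
                    continue
                if best is None or ssq < best[0]:
                    best = (ssq, float(res.x[0]), float(np.exp(res.x[1])), (float(r1_0), float(c_0)))
        if best is None:
            raise RuntimeError("all start points failed with non-finite model output")
        ssq, r1, c, start = best
        self.r1_, self.c_, self.ssq_, self.start_used_ = r1, c, ssq, start
        self.capped_r1_ = bool(
            np.isclose(r1, cfg.r1_bounds[0], rtol=cfg.cap_rtol, atol=0)
            or np.isclose(r1, cfg.r1_bounds[1], rtol=cfg.cap_rtol, atol=0)
        )
        self.capped_c_ = bool(
            np.isclose(c, cfg.c_bounds[0], rtol=cfg.cap_rtol, atol=0)
            or np.isclose(c, cfg.c_bounds[1], rtol=cfg.cap_rtol, atol=0)
        )
        self._model = model
        return self

    def predict(self, times=None) -> np.ndarray:
        """Best-fit model waveform over the fitted window."""
        if times is not None:
            model = _WaveformModel(np.asarray(times, float), self.pulse, self.config)
            return model(self.r1_, self.c_)
        return self._model(self.r1_, self.c_)

    def result_(self) -> VWFitResult:
        return VWFitResult(
            r1=self.r1_,
            c=self.c_,
            ssq=self.ssq_,
            capped_r1=self.capped_r1_,
            capped_c=self.capped_c_,
            start_used=self.start_used_,
        )


def fit_window(waveform: VoltageWaveform, pulse: PulseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (times, voltage) from onset through the pulse plus an equal tail."""
    if waveform.onset_time is None:
        raise ValueError("waveform is not aligned: onset_time unset (run detect_onset)")
    t = waveform.times - waveform.onset_time
    mask = (t >= 0) & (t <= 2.0 * pulse.duration)
    if not mask.any():
        raise ValueError("fit window lies outside the recorded waveform")
    return t[mask], waveform.mean_v[mask]


def vw_fit(waveform: VoltageWaveform, config: VWFitConfig, pulse: PulseSpec) -> VWFitResult:
    """Functional wrapper: align, window, grid-multistart fit."""
    times, v = fit_window(waveform, pulse)
    fitter = WaveformCircuitFitter(pulse=pulse, config=config)
    fitter.fit(times, v)
    return fitter.result_()
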