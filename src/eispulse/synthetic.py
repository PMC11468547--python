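"""Synthetic fibrosis cohorts: the statistical stand-in for the study data.

Each electrode carries a ground-truth circuit-parameter time course
emulating progressive fibrotic encapsulation: the bulk resistance R1
rises along a logistic with inflection between days 7 and 9, the bulk
capacitance C falls along a (geometric) logistic with inflection between
days 4 and 7, and the interface CPE and series resistor R2 stay
constant.  When a construct contracts off an electrode, parameters
revert to baseline from the next measurement day.  Every generated
measurement retains its generating parameters so recovered trajectories
can always be scored against truth.

All randomness flows from the config seed through one generator; equal
configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import CircuitParams, ImpedanceSpectrum, circuit_impedance, default_frequency_grid
from .eis import EISRecording
from .waveform import CATHODIC, PulseSpec, RawWaveformSet, simulate_waveform

DEFAULT_DAYS = (2, 4, 7, 9, 11, 14)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic fibrosis cohort.

    Baseline ranges place spectra in the regime of the measured data
    (tens of kOhm at 10 Hz, hundreds of Ohm at 100 kHz); trajectory
    fold-changes and inflection-day windows follow the reported bulk
    R1 / C dynamics.
    """

    seed: int
    n_electrodes: int = 30
    days: tuple[int, ...] = DEFAULT_DAYS
    r1_range: tuple[float, float] = (100.0, 250.0)
    c_range: tuple[float, float] = (1.5e-7, 6e-7)
    r2_range: tuple[float, float] = (50.0, 150.0)
    cpe_t_range: tuple[float, float] = (9e-7, 1.3e-6)
    cpe_p_range: tuple[float, float] = (0.78, 0.82)
    r1_fold_range: tuple[float, float] = (2.0, 4.0)
    r1_inflection: tuple[float, float] = (7.0, 9.0)
    c_fold_range: tuple[float, float] = (2.0, 10.0)
    c_inflection: tuple[float, float] = (4.0, 7.0)
    sigmoid_width_days: float = 1.5
    #: Weight of the shared "fibrosis severity" factor behind both fold
    #: changes (0 = independent draws, 1 = fully coupled).  Encapsulation
    #: drives the R1 rise and the C fall jointly, so their magnitudes
    #: co-vary across electrodes.
    severity_coupling: float = 0.7
    construct_off_days: dict[str, int] | None = None
    eis_mag_noise: float = 0.02  # log-normal sigma on |Z|
    eis_phase_noise_deg: float = 1.0
    n_eis_repeats: int = 3
    wf_noise_v: float = 2e-3  # additive Gaussian sigma, volt
    wf_offset_v: float = 5e-3  # per-repeat constant baseline offset sigma
    n_wf_repeats: int = 15
    wf_sampling_rate: float = 12.5e6
    wf_pre_stimulus_s: float = 100e-6
    wf_tail_s: float = 200e-6
    pulse: PulseSpec = field(default_factory=lambda: PulseSpec(i_amp=50e-6, t0=50e-6))

    def __post_init__(self) -> None:
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be ascending")
        for name in ("r1_fold_range", "c_fold_range"):
            if getattr(self, name)[0] <= 1:
                raise ValueError(f"{name} fold-changes must exceed 1")


@dataclass
class ElectrodeTruth:
    """Ground-truth trajectory of one electrode."""

    electrode_id: str
    days: tuple[int, ...]
    params_by_day: dict[int, CircuitParams]
    construct_on: dict[int, bool]
    off_day: int | None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    truth: list[ElectrodeTruth]
    eis: list[EISRecording]  # one per electrode/day
    waveforms: dict[tuple[str, int], RawWaveformSet]

    def truth_for(self, electrode_id: str) -> ElectrodeTruth:
        for t in self.truth:
            if t.electrode_id == electrode_id:
                return t
        raise KeyError(electrode_id)


def _logistic(day: float, inflection: float, width: float) -> float:
    return 1.0 / (1.0 + np.exp(-(day - inflection) / width))


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _electrode_trajectory(
    rng: np.random.Generator, config: CohortConfig, electrode_id: str
) -> ElectrodeTruth:
    r1_0 = rng.uniform(*config.r1_range)
    c_0 = _loguniform(rng, *config.c_range)
    r2 = rng.uniform(*config.r2_range)
    cpe_t = _loguniform(rng, *config.cpe_t_range)
    cpe_p = rng.uniform(*config.cpe_p_range)
    w = config.severity_coupling
    severity = rng.uniform()
    u_r = w * severity + (1.0 - w) * rng.uniform()
    u_c = w * severity + (1.0 - w) * rng.uniform()
    r1_fold = config.r1_fold_range[0] + np.ptp(config.r1_fold_range) * u_r
    c_fold = config.c_fold_range[0] + np.ptp(config.c_fold_range) * u_c
    r1_infl = rng.uniform(*config.r1_inflection)
    c_infl = rng.uniform(*config.c_inflection)
    off_day = (config.construct_off_days or {}).get(electrode_id)

    baseline = CircuitParams(cpe_t=cpe_t, cpe_p=cpe_p, r1=r1_0, c=c_0, r2=r2)
    params_by_day: dict[int, CircuitParams] = {}
    construct_on: dict[int, bool] = {}
    for day in config.days:
        if off_day is not None and day > off_day:
            params_by_day[day] = baseline
            construct_on[day] = False
            continue
        lr = _logistic(day, r1_infl, config.sigmoid_width_days)
        lc = _logistic(day, c_infl, config.sigmoid_width_days)
        params_by_day[day] = baseline.replace(
            r1=r1_0 * (1.0 + (r1_fold - 1.0) * lr),
            c=c_0 * c_fold**-lc,
        )
        construct_on[day] = True
    return ElectrodeTruth(
        electrode_id=electrode_id,
        days=config.days,
        params_by_day=params_by_day,
        construct_on=construct_on,
        off_day=off_day,
    )


def synth_eis(
    params: CircuitParams,
    mag_noise: float = 0.02,
    phase_noise_deg: float = 1.0,
    n_repeats: int = 3,
    rng: np.random.Generator | int | None = None,
    frequencies: np.ndarray | None = None,
    electrode_id: str = "e00",
    day: int = 0,
    construct_on: bool = True,
) -> EISRecording:
    """Noisy EIS repeats from the circuit model on the standard 41-point grid.

    Magnitude noise is multiplicative log-normal (sigma in log units,
    ~percent scale); phase noise is additive Gaussian in degrees.
    """
    if mag_noise < 0 or phase_noise_deg < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(rng)
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies, float)
    z = circuit_impedance(params, f)
    mag, phase = np.abs(z), np.rad2deg(np.angle(z))
    repeats = []
    for _ in range(n_repeats):
        m = mag * np.exp(mag_noise * rng.standard_normal(f.size))
        ph = np.clip(phase + phase_noise_deg * rng.standard_normal(f.size), -89.999, 90.0)
        repeats.append(ImpedanceSpectrum(frequencies=f, z_mag=m, phase_deg=ph))
    return EISRecording(
        electrode_id=electrode_id, day=day, repeats=repeats, construct_on=construct_on
    )


def synth_waveforms(
    params: CircuitParams,
    pulse: PulseSpec,
    noise_v: float = 2e-3,
    offset_v: float = 5e-3,
    n_repeats: int = 15,
    sampling_rate: float = 125e6,
    pre_stimulus_s: float = 100e-6,
    tail_s: float = 200e-6,
    rng: np.random.Generator | int | None = None,
) -> RawWaveformSet:
    """Raw repeated traces: dense simulated pulse response after a quiet
    pre-stimulus segment, plus additive noise and a per-repeat constant
    offset (environmental drift)."""
    if sampling_rate * pulse.t0 < 100:
        raise ValueError("sampling_rate must resolve the phase with >= 100 samples")
    if pre_stimulus_s < 80e-6:
        raise ValueError("pre-stimulus segment must span at least 80 us")
    rng = np.random.default_rng(rng)
    dt = 1.0 / sampling_rate
    n_pre = int(round(pre_stimulus_s * sampling_rate))
    times = (np.arange(n_pre + int(round((pulse.duration + tail_s) * sampling_rate))) - n_pre) * dt
    clean = simulate_waveform(params, pulse, times).mean_v
    n = times.size
    repeats = (
        clean[None, :]
        + noise_v * rng.standard_normal((n_repeats, n))
        + offset_v * rng.standard_normal((n_repeats, 1))
    )
    return RawWaveformSet(sampling_rate=sampling_rate, repeats=repeats, pre_stimulus_samples=n_pre)


def make_cohort(config: CohortConfig, generate_waveforms: bool = True) -> SyntheticCohort:
    """Generate truth trajectories plus noisy EIS (and optionally waveform)
    measurements for every electrode and day."""
    rng = np.random.default_rng(config.seed)
    truth: list[ElectrodeTruth] = []
    eis: list[EISRecording] = []
    waveforms: dict[tuple[str, int], RawWaveformSet] = {}
    for k in range(config.n_electrodes):
        eid = f"e{k:02d}"
        tr = _electrode_trajectory(rng, config, eid)
        truth.append(tr)
        for day in config.days:
            eis.append(
                synth_eis(
                    tr.params_by_day[day],
                    mag_noise=config.eis_mag_noise,
                    phase_noise_deg=config.eis_phase_noise_deg,
                    n_repeats=config.n_eis_repeats,
                    rng=rng,
                    electrode_id=eid,
                    day=day,
                    construct_on=tr.construct_on[day],
                )
            )
            if generate_waveforms:
                waveforms[(eid, day)] = synth_waveforms(
                    tr.params_by_day[day],
                    config.pulse,
                    noise_v=config.wf_noise_v,
                    offset_v=config.wf_offset_v,
                    n_repeats=config.n_wf_repeats,
                    sampling_rate=config.wf_sampling_rate,
                    pre_stimulus_s=config.wf_pre_stimulus_s,
                    tail_s=config.wf_tail_s,
                    rng=rng,
                )
    return SyntheticCohort(config=config, truth=truth, eis=eis, waveforms=waveforms)


def degenerate_recording(
    kind: str,
    seed: int = 0,
    frequencies: np.ndarray | None = None,
    electrode_id: str = "bad",
    day: int = 2,
) -> EISRecording:
    """Pathological recordings, each tripping exactly one exclusion rule.

    ``open_circuit``: CPE-like spectrum with |Z(10 Hz)| ~ 200 kOhm (rule R2).
    ``air_bubble``: near-resistive phase ~ -5 deg below 1 kHz (rule R3).
    ``noisy_phase``: sound spectrum with +-10 deg phase offsets across the
    three repeats, so every per-frequency phase std is exactly 10 deg
    (rule R1) while the mean phase is untouched.
    """
    rng = np.random.default_rng(seed)
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies, float)

    def _jitter(mag, phase, mag_sd=1e-3, ph_sd=0.1, ph_offsets=(0.0, 0.0, 0.0)):
        reps = []
        for off in ph_offsets:
            m = mag * np.exp(mag_sd * rng.standard_normal(f.size))
            ph = phase + off + ph_sd * rng.standard_normal(f.size)
            reps.append(ImpedanceSpectrum(f, m, np.clip(ph, -89.999, 90.0)))
        return reps

    if kind == "open_circuit":
        mag = 2e5 * (f / 10.0) ** -0.8
        phase = np.full(f.size, -72.0)
        reps = _jitter(mag, phase)
    elif kind == "air_bubble":
        mag = np.full(f.size, 1e4)
        phase = np.full(f.size, -5.0)
        reps = _jitter(mag, phase, ph_sd=0.05)
    elif kind == "noisy_phase":
        params = CircuitParams(cpe_t=1e-6, cpe_p=0.8, r1=500.0, c=5e-9, r2=200.0)
        z = circuit_impedance(params, f)
        reps = _jitter(np.abs(z), np.rad2deg(np.angle(z)), ph_sd=0.0, ph_offsets=(-10.0, 0.0, 10.0))
    else:
        raise ValueError(f"unknown degenerate kind {kind!r}")
    return EISRecording(electrode_id=electrode_id, day=day, repeats=reps, construct_on=False)
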