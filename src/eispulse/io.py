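"""File I/O and the end-to-end study driver.

The driver chains the full analysis the way the lab pipeline ran it:
QC screening -> EIS time-course circuit fitting (fixed R2, warm starts)
-> waveform preprocessing and onset detection -> marker extraction
(contact impedance, SPPR, day-2-normalized variants) -> SPPR-slope
inclusion rules -> reverse waveform fitting with day-2-fixed interface
elements -> marker/element and VW-vs-EIS correlations (with capped-fit
and R1 > 2 kOhm exclusion variants).

CSV schemas (long format):
  EIS:      electrode_id, day, repeat, frequency_hz, z_mag_ohm, phase_deg
            [, construct_on]
  waveform: electrode_id, day, pulse_polarity, repeat, time_s, voltage_v
  patient:  patient_id, electrode, visit, offset_us, phase, voltage_v,
            current_a [, mcl_cl]
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import ImpedanceSpectrum
from .eis import EISRecording, FitResult, fit_timecourse, qc_screen
from .markers import (
    MarkerSeries,
    PatientTelemetry,
    SlopeRefusal,
    contact_impedance,
    normalize_series,
    pearson_ci,
    sppr,
    sppr_slope,
)
from .synthetic import CohortConfig, make_cohort
from .vwfit import VWFitConfig, vw_fit
from .waveform import (
    CATHODIC,
    PulseSpec,
    RawWaveformSet,
    OnsetNotFoundError,
    detect_onset,
    preprocess,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised for malformed input tables (missing columns, bad rows)."""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

EIS_COLUMNS = ["electrode_id", "day", "repeat", "frequency_hz", "z_mag_ohm", "phase_deg"]
WAVEFORM_COLUMNS = ["electrode_id", "day", "pulse_polarity", "repeat", "time_s", "voltage_v"]
PATIENT_COLUMNS = ["patient_id", "electrode", "visit", "offset_us", "phase", "voltage_v", "current_a"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise SchemaError(f"{path}: non-numeric values in {col!r} at line(s) {list(bad[:5])}")
        if coerced.isna().any():
            bad = df.index[coerced.isna()] + 2
            raise SchemaError(f"{path}: empty cells in {col!r} at line(s) {list(bad[:5])}")
        df[col] = coerced
    return df


def read_eis_csv(path) -> list[EISRecording]:
    """Read the long-format EIS table into per-electrode/day recordings."""
    df = pd.read_csv(path)
    _require_columns(df, EIS_COLUMNS, path)
    df = _require_numeric(df, ["day", "repeat", "frequency_hz", "z_mag_ohm", "phase_deg"], path)
    key = ["electrode_id", "day", "repeat", "frequency_hz"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate (electrode, day, repeat, frequency) at lines {lines[:6]}")
    recordings = []
    for (eid, day), g in df.groupby(["electrode_id", "day"], sort=True):
        reps = []
        for _, rep in g.groupby("repeat", sort=True):
            rep = rep.sort_values("frequency_hz")
            reps.append(
                ImpedanceSpectrum(
                    frequencies=rep["frequency_hz"].to_numpy(),
                    z_mag=rep["z_mag_ohm"].to_numpy(),
                    phase_deg=rep["phase_deg"].to_numpy(),
                )
            )
        construct_on = bool(g["construct_on"].iloc[0]) if "construct_on" in g else True
        recordings.append(
            EISRecording(electrode_id=str(eid), day=int(day), repeats=reps, construct_on=construct_on)
        )
    return recordings


def write_eis_csv(recordings: list[EISRecording], path) -> None:
    rows = []
    for rec in recordings:
        for k, rep in enumerate(rec.repeats):
            for f, m, ph in zip(rep.frequencies, rep.z_mag, rep.phase_deg):
                rows.append(
                    {
                        "electrode_id": rec.electrode_id,
                        "day": rec.day,
                        "repeat": k,
                        "frequency_hz": f,
                        "z_mag_ohm": m,
                        "phase_deg": ph,
                        "construct_on": rec.construct_on,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_waveform_csv(path) -> dict[tuple[str, int, str], RawWaveformSet]:
    """Read the long-format waveform table into per-(electrode, day, polarity) sets."""
    df = pd.read_csv(path)
    _require_columns(df, WAVEFORM_COLUMNS, path)
    df = _require_numeric(df, ["day", "repeat", "time_s", "voltage_v"], path)
    out = {}
    for (eid, day, pol), g in df.groupby(["electrode_id", "day", "pulse_polarity"], sort=True):
        traces = []
        times = None
        for _, rep in g.groupby("repeat", sort=True):
            rep = rep.sort_values("time_s")
            traces.append(rep["voltage_v"].to_numpy())
            times = rep["time_s"].to_numpy()
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise SchemaError(f"{path}: non-uniform time grid for {(eid, day, pol)}")
        out[(str(eid), int(day), str(pol))] = RawWaveformSet(
            sampling_rate=1.0 / dt[0],
            repeats=np.vstack(traces),
            pre_stimulus_samples=int(np.sum(times < 0)),
        )
    return out


def write_waveform_csv(sets: dict, path) -> None:
    frames = []
    for (eid, day, pol), raw in sets.items():
        n = raw.repeats.shape[1]
        times = (np.arange(n) - raw.pre_stimulus_samples) / raw.sampling_rate
        for k, trace in enumerate(raw.repeats):
            frames.append(
                pd.DataFrame(
                    {
                        "electrode_id": eid,
                        "day": day,
                        "pulse_polarity": pol,
                        "repeat": k,
                        "time_s": times,
                        "voltage_v": trace,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_patient_csv(path) -> list[PatientTelemetry]:
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, path)
    df = _require_numeric(df, ["electrode", "offset_us", "phase", "voltage_v", "current_a"], path)
    out = []
    for (pid, el, visit), g in df.groupby(["patient_id", "electrode", "visit"], sort=True):
        phase1 = {
            float(r.offset_us): float(r.voltage_v) for r in g.itertuples() if r.phase == 1
        }
        phase2 = {
            float(r.offset_us): float(r.voltage_v) for r in g.itertuples() if r.phase == 2
        }
        mcl = float(g["mcl_cl"].iloc[0]) if "mcl_cl" in g and g["mcl_cl"].notna().any() else None
        out.append(
            PatientTelemetry(
                patient_id=str(pid),
                electrode_number=int(el),
                visit=str(visit),
                phase1_samples=phase1,
                phase2_samples=phase2,
                input_current=float(g["current_a"].iloc[0]),
                mcl_cl=mcl,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Inputs and settings of one end-to-end study run.

    Exactly one of (``eis_csv``, ``cohort``) must be set.
    """

    seed: int = 0
    eis_csv: str | None = None
    waveform_csv: str | None = None
    cohort: CohortConfig | None = None
    pulse: PulseSpec = field(default_factory=lambda: PulseSpec(i_amp=50e-6, t0=50e-6))
    baseline_day: int = 2
    qc_thresholds: dict | None = None
    cutoff_hz: float = 80e3
    downsample_factor: int = 20
    baseline_samples: int = 500
    vw_grid_n: int = 10
    vw_r1_bounds: tuple[float, float] = (50.0, 5000.0)
    vw_c_bounds: tuple[float, float] = (1e-13, 1e-7)
    r1_outlier_ohm: float = 2000.0
    eis_only: bool = False

    def __post_init__(self) -> None:
        if (self.eis_csv is None) == (self.cohort is None):
            raise ValueError("exactly one of eis_csv / cohort must be set")


@dataclass
class StudyReport:
    """Tidy tables of the full analysis; ready for external stats tooling."""

    qc: pd.DataFrame  # one row per recording: kept / reasons
    eis_fits: pd.DataFrame  # electrode, day, params, ssq
    markers: pd.DataFrame  # electrode, day, contact impedance, SPPR, relatives
    slopes: pd.DataFrame  # electrode, slope or refusal reason
    vw_fits: pd.DataFrame  # electrode, day, r1, c, caps
    correlations: pd.DataFrame  # name, r, ci_low, ci_high, n


def _correlation_row(name: str, x, y) -> dict | None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        logger.warning("correlation %s skipped: only %d pairs", name, int(ok.sum()))
        return None
    r, lo, hi = pearson_ci(x[ok], y[ok])
    return {"name": name, "r": r, "ci_low": lo, "ci_high": hi, "n": int(ok.sum())}


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full QC -> fit -> markers -> VW-fit -> correlation chain."""
    if config.cohort is not None:
        cohort = make_cohort(config.cohort, generate_waveforms=not config.eis_only)
        recordings = cohort.eis
        waveform_sets = {
            (eid, day, CATHODIC): raw for (eid, day), raw in cohort.waveforms.items()
        }
        downsample = max(
            1, int(round(config.cohort.wf_sampling_rate / 6.25e6))
        )
    else:
        recordings = read_eis_csv(config.eis_csv)
        if config.waveform_csv and not config.eis_only:
            waveform_sets = read_waveform_csv(config.waveform_csv)
        elif config.eis_only:
            waveform_sets = {}
        else:
            raise ValueError("no waveform input: pass waveform_csv or set eis_only")
        downsample = config.downsample_factor

    if not recordings:
        raise SchemaError("empty EIS input")

    # --- QC ledger ---------------------------------------------------------
    qc_rows = []
    for rec in recordings:
        q = qc_screen(rec, thresholds=config.qc_thresholds)
        qc_rows.append(
            {
                "electrode_id": rec.electrode_id,
                "day": rec.day,
                "construct_on": rec.construct_on,
                "kept": q.keep,
                "reasons": ";".join(f"{r}={v:.3g}" for r, v in q.reasons),
            }
        )
    qc_df = pd.DataFrame(qc_rows)
    if not qc_df["kept"].any():
        raise ValueError("empty post-QC dataset: every recording excluded")

    # --- EIS time-course fits ---------------------------------------------
    fit_rows = []
    fits_by_key: dict[tuple[str, int], FitResult] = {}
    for eid, group in _group_by_electrode(recordings):
        try:
            results = fit_timecourse(group, qc_thresholds=config.qc_thresholds)
        except ValueError as exc:
            logger.warning("electrode %s: %s", eid, exc)
            continue
        for rec, fit in zip(group, results):
            if fit is None:
                continue
            fits_by_key[(eid, rec.day)] = fit
            row = {"electrode_id": eid, "day": rec.day, "construct_on": rec.construct_on}
            row.update({k: float(v) for k, v in fit.params.to_dict().items()})
            row.update(
                weighted_ssq_pct=fit.weighted_ssq,
                converged=fit.converged,
                fixed_elements=";".join(sorted(fit.fixed_elements)),
            )
            fit_rows.append(row)
    eis_fits = pd.DataFrame(fit_rows)

    # --- Waveform preprocessing and markers --------------------------------
    marker_rows = []
    processed: dict[tuple[str, int], "object"] = {}
    for (eid, day, pol), raw in sorted(waveform_sets.items()):
        if pol != CATHODIC:
            continue  # markers are defined on the cathodic-leading pulse
        if (eid, day) not in fits_by_key:
            continue  # waveforms analyzed only when EIS was kept
        try:
            wf = preprocess(
                raw,
                cutoff_hz=config.cutoff_hz,
                downsample_factor=downsample,
                baseline_samples=config.baseline_samples,
            )
            wf.onset_time = detect_onset(wf)
        except (OnsetNotFoundError, ValueError) as exc:
            logger.warning("waveform (%s, %d) skipped: %s", eid, day, exc)
            continue
        processed[(eid, day)] = wf
        construct_on = bool(
            qc_df.query("electrode_id == @eid and day == @day")["construct_on"].iloc[0]
        )
        marker_rows.append(
            {
                "electrode_id": eid,
                "day": day,
                "construct_on": construct_on,
                "contact_impedance_ohm": contact_impedance(wf, config.pulse),
                "sppr_pct": sppr(wf, config.pulse),
            }
        )
    markers_df = pd.DataFrame(marker_rows)

    # normalized variants (baseline day, construct-on convention)
    if not markers_df.empty:
        rel_ci, rel_sp = [], []
        for eid, g in markers_df.groupby("electrode_id"):
            base = g[g["day"] == config.baseline_day]
            ci0 = base["contact_impedance_ohm"].iloc[0] if len(base) else np.nan
            sp0 = base["sppr_pct"].iloc[0] if len(base) else np.nan
            rel_ci.extend(g["contact_impedance_ohm"] / ci0)
            rel_sp.extend(g["sppr_pct"] / sp0)
        markers_df = markers_df.sort_values(["electrode_id", "day"]).reset_index(drop=True)
        markers_df["rel_contact_impedance"] = rel_ci
        markers_df["rel_sppr"] = rel_sp

    # --- SPPR slopes --------------------------------------------------------
    slope_rows = []
    for eid, g in (markers_df.groupby("electrode_id") if not markers_df.empty else []):
        series = MarkerSeries(
            electrode_id=eid,
            days=g["day"].to_numpy(),
            contact_impedance=g["contact_impedance_ohm"].to_numpy(),
            sppr=g["sppr_pct"].to_numpy(),
            construct_on=g["construct_on"].to_numpy(),
        )
        result = sppr_slope(series)
        if isinstance(result, SlopeRefusal):
            slope_rows.append({"electrode_id": eid, "slope_pct_per_day": np.nan,
                               "final_day": -1, "refusal": result.reason})
        else:
            slope_rows.append(
                {
                    "electrode_id": eid,
                    "slope_pct_per_day": result.slope,
                    "final_day": result.final_day,
                    "refusal": "",
                }
            )
    slopes_df = pd.DataFrame(slope_rows)

    # --- VW fits (fixed interface elements from the baseline-day EIS fit) --
    vw_rows = []
    for (eid, day), wf in sorted(processed.items()):
        day2 = fits_by_key.get((eid, config.baseline_day))
        if day2 is None:
            continue
        cfg = VWFitConfig(
            fixed_cpe_t=day2.params.cpe_t,
            fixed_cpe_p=day2.params.cpe_p,
            fixed_r2=day2.params.r2,
            r1_bounds=config.vw_r1_bounds,
            c_bounds=config.vw_c_bounds,
            grid_n=config.vw_grid_n,
        )
        res = vw_fit(wf, cfg, config.pulse)
        vw_rows.append(
            {
                "electrode_id": eid,
                "day": day,
                "r1": res.r1,
                "c": res.c,
                "ssq_v2": res.ssq,
                "capped_r1": res.capped_r1,
                "capped_c": res.capped_c,
            }
        )
    vw_df = pd.DataFrame(vw_rows)

    # --- Correlations -------------------------------------------------------
    corr_rows = []
    if not slopes_df.empty and not eis_fits.empty:
        merged = slopes_df[slopes_df["refusal"] == ""].merge(
            eis_fits, left_on=["electrode_id", "final_day"], right_on=["electrode_id", "day"]
        )
        for elem in ("r1", "c"):
            row = _correlation_row(
                f"sppr_slope_vs_final_{elem}", merged["slope_pct_per_day"], merged[elem]
            )
            if row:
                corr_rows.append(row)
    if not vw_df.empty and not eis_fits.empty:
        both = vw_df.merge(eis_fits, on=["electrode_id", "day"], suffixes=("_vw", "_eis"))
        uncapped = both[~(both["capped_r1"] | both["capped_c"])]
        for sub, tag in [(both, "all"), (uncapped, "uncapped")]:
            row = _correlation_row(f"vw_vs_eis_r1_{tag}", sub["r1_vw"], sub["r1_eis"])
            if row:
                corr_rows.append(row)
        row = _correlation_row("vw_vs_eis_c_uncapped", uncapped["c_vw"], uncapped["c_eis"])
        if row:
            corr_rows.append(row)
        trimmed = uncapped[uncapped["r1_vw"] <= config.r1_outlier_ohm]
        row = _correlation_row("vw_vs_eis_r1_uncapped_below_2k", trimmed["r1_vw"], trimmed["r1_eis"])
        if row:
            corr_rows.append(row)
    corr_df = pd.DataFrame(corr_rows)

    return StudyReport(
        qc=qc_df,
        eis_fits=eis_fits,
        markers=markers_df,
        slopes=slopes_df,
        vw_fits=vw_df,
        correlations=corr_df,
    )


def _group_by_electrode(recordings: list[EISRecording]):
    by: dict[str, list[EISRecording]] = {}
    for rec in recordings:
        by.setdefault(rec.electrode_id, []).append(rec)
    for eid in sorted(by):
        yield eid, sorted(by[eid], key=lambda r: r.day)


def write_report(report: StudyReport, out_dir, config: StudyConfig | None = None) -> None:
    """Write all report tables as CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("qc", "eis_fits", "markers", "slopes", "vw_fits", "correlations"):
        getattr(report, name).to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    manifest = {"tables": ["qc", "eis_fits", "markers", "slopes", "vw_fits", "correlations"]}
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config"] = json.loads(
            json.dumps(dataclasses.asdict(config), default=str)
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
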