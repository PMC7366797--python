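"""Stage orchestration: calibrate -> respond -> iso -> workenv -> report.

Each stage is a pure function of typed inputs; :func:`run_pipeline` chains
them over files and writes the artifact set plus a provenance sidecar
(package version, flags, input digests) so a rerun on identical inputs is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationFactor,
    CoefficientTable,
    IrradiationRun,
    air_kerma_to_hp10,
    calibration_factor,
)
from .io_tables import (
    read_readings,
    read_runs,
    render_report,
    responses_to_frame,
    write_calibration_factors,
    write_responses,
    write_workenv,
)
from .iso_geometry import ROT_ANGLES, iso_response, iso_response_per_dosemeter
from .response import ReadingSet, aggregate_response, single_response
from .workenv import FacilityProfile, WorkEnvResult, facility_response

__all__ = [
    "PipelineConfig",
    "calibrate_stage",
    "respond_stage",
    "iso_stage",
    "workenv_stage",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    runs_path: Path
    readings_path: Path
    coefficients_path: Path
    profiles_path: Path | None = None
    out_dir: Path = Path("out")
    weight_mode: str = "printed"  # ISO band weights: printed 3-decimal or exact
    method: str = "log_scale"  # working-environment aggregation
    seed: int | None = None  # recorded in provenance only

    def __post_init__(self) -> None:
        for p in (self.runs_path, self.readings_path, self.coefficients_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.profiles_path is not None and not Path(self.profiles_path).exists():
            raise FileNotFoundError(f"input file not found: {self.profiles_path}")


def calibrate_stage(
    runs: Sequence[IrradiationRun],
    reading_sets: Sequence[ReadingSet],
    coefficients: CoefficientTable,
) -> list[CalibrationFactor]:
    """Derive per-dosemeter (EPD) and per-lot (GB, LB) calibration factors.

    Uses the run(s) flagged role=calibration: the slab exposure's air kerma
    is converted to Hp(10) with the coefficient at the run's (energy,
    geometry), and CFs are reference Hp(10) over the slab readings.
    """
    cal_runs = [r for r in runs if r.role == "calibration"]
    if not cal_runs:
        raise ValueError("calibrate: no run with role=calibration")
    cfs: list[CalibrationFactor] = []
    for run in cal_runs:
        c = coefficients.get(run.mean_energy, run.geometry)
        reference_hp10 = air_kerma_to_hp10(run.reference_kerma, c)
        for rs in reading_sets:
            if rs.run_id != run.run_id:
                continue
            scope = "per_dosemeter" if rs.dosemeter_type == "EPD" else "per_lot"
            cfs.extend(
                calibration_factor(
                    rs.values, reference_hp10, scope, rs.dosemeter_type, rs.dosemeter_ids
                )
            )
    if not cfs:
        raise ValueError("calibrate: no reading sets matched the calibration run(s)")
    return cfs


def _cf_lookup(cfs: Sequence[CalibrationFactor]) -> dict[tuple[str, str | None], float]:
    return {(c.dosemeter_type, c.dosemeter_id): c.cf for c in cfs}


def respond_stage(
    runs: Sequence[IrradiationRun],
    reading_sets: Sequence[ReadingSet],
    cfs: Sequence[CalibrationFactor],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run mean responses plus the per-dosemeter long table.

    Returns ``(responses, per_dosemeter)``: the first is the machine twin of
    the published per-condition table (non-ISO rows), the second keeps each
    dosemeter's response for downstream per-dosemeter ISO synthesis. Zero
    readings (below detection limit) are excluded with a warning.
    """
    lookup = _cf_lookup(cfs)
    run_by_id = {r.run_id: r for r in runs}
    rows: list[dict] = []
    detail: list[dict] = []
    for rs in reading_sets:
        run = run_by_id.get(rs.run_id)
        if run is None:
            raise ValueError(f"respond: readings reference unknown run {rs.run_id!r}")
        if run.role != "phantom":
            continue
        values = []
        for did, reading in rs.readings:
            if reading <= 0:
                logger.warning(
                    "run %s (%s, %s): zero reading excluded (below detection limit)",
                    rs.run_id, rs.dosemeter_type, did,
                )
                continue
            cf = lookup.get((rs.dosemeter_type, did), lookup.get((rs.dosemeter_type, None)))
            if cf is None:
                raise ValueError(
                    f"respond: no calibration factor for {rs.dosemeter_type} {did!r}"
                )
            b = single_response(reading, cf, run.reference_kerma)
            values.append(b)
            detail.append(
                {
                    "run_id": rs.run_id,
                    "dosemeter_type": rs.dosemeter_type,
                    "dosemeter_id": did,
                    "mean_energy_keV": run.mean_energy,
                    "geometry": run.geometry,
                    "zenith_angle_deg": run.zenith_angle,
                    "B": b,
                }
            )
        if not values:
            logger.warning("run %s (%s): no usable readings", rs.run_id, rs.dosemeter_type)
            continue
        rv = aggregate_response(values)
        rows.append(
            {
                "run_id": rs.run_id,
                "dosemeter_type": rs.dosemeter_type,
                "mean_energy_keV": run.mean_energy,
                "geometry": run.geometry,
                "zenith_angle_deg": run.zenith_angle,
                "mean_B": rv.mean_B,
                "sd_log": rv.sd_log,
                "K": rv.K,
                "n": rv.n,
            }
        )
    return responses_to_frame(rows), pd.DataFrame(detail)


def iso_stage(
    responses: pd.DataFrame,
    per_dosemeter: pd.DataFrame | None = None,
    weight_mode: str = "printed",
) -> pd.DataFrame:
    """Append synthesized ISO rows (geometry=ISO) per (type, energy).

    With the per-dosemeter table available, each dosemeter position is
    synthesized across the five zenith angles and the four ISO values are
    aggregated, so the ISO K reflects spread after angle averaging;
    otherwise the mean-level combination with propagated K is used.
    """
    out_rows = []
    rot = responses[responses["geometry"] == "ROT"]
    for (dtype, energy), grp in rot.groupby(["dosemeter_type", "mean_energy_keV"]):
        angles = set(grp["zenith_angle_deg"].astype(float))
        if not set(ROT_ANGLES) <= angles:
            missing = sorted(set(ROT_ANGLES) - angles)
            raise ValueError(
                f"iso: {dtype} at {energy:g} keV missing rotational angle(s) {missing}"
            )
        rv = None
        if per_dosemeter is not None and not per_dosemeter.empty:
            sub = per_dosemeter[
                (per_dosemeter["dosemeter_type"] == dtype)
                & (per_dosemeter["mean_energy_keV"] == energy)
                & (per_dosemeter["geometry"] == "ROT")
            ]
            per_angle = {
                float(angle): dict(zip(g["dosemeter_id"], g["B"]))
                for angle, g in sub.groupby("zenith_angle_deg")
            }
            try:
                rv = iso_response_per_dosemeter(per_angle, weight_mode=weight_mode)
            except ValueError:
                rv = None  # fall back to mean-level synthesis
        if rv is None:
            from .response import ResponseValue

            per_mean = {
                float(r["zenith_angle_deg"]): ResponseValue(
                    r["mean_B"],
                    None if pd.isna(r["sd_log"]) else r["sd_log"],
                    None if pd.isna(r["K"]) else r["K"],
                    int(r["n"]),
                )
                for _, r in grp.iterrows()
            }
            rv = iso_response(per_mean, weight_mode=weight_mode)
        out_rows.append(
            {
                "run_id": f"ISO-{dtype}-{energy:g}",
                "dosemeter_type": dtype,
                "mean_energy_keV": energy,
                "geometry": "ISO",
                "zenith_angle_deg": np.nan,
                "mean_B": rv.mean_B,
                "sd_log": rv.sd_log,
                "K": rv.K,
                "n": rv.n,
            }
        )
    return pd.concat([responses, responses_to_frame(out_rows)], ignore_index=True)


def workenv_stage(
    responses: pd.DataFrame,
    profiles: Mapping[str, FacilityProfile],
    method: str = "log_scale",
    band_mixes: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> list[WorkEnvResult]:
    """Facility-level conversion factors for every (type, profile) pair."""
    from .response import ResponseValue

    results = []
    for dtype, grp in responses.groupby("dosemeter_type"):
        cells: dict[tuple[float, str], ResponseValue] = {}
        for _, r in grp.iterrows():
            geometry = r["geometry"]
            if geometry == "ROT" and float(r["zenith_angle_deg"]) != 90.0:
                continue  # ROT class means the 90 deg rotational row
            cells[(float(r["mean_energy_keV"]), geometry)] = ResponseValue(
                r["mean_B"],
                None if pd.isna(r["sd_log"]) else r["sd_log"],
                None if pd.isna(r["K"]) else r["K"],
                int(r["n"]),
            )
        for profile in profiles.values():
            results.append(
                facility_response(
                    profile, cells, dtype, band_mixes=band_mixes, method=method
                )
            )
    return results


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage over the configured files; return the artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    runs = _stage("read", read_runs, config.runs_path)
    reading_sets = _stage("read", read_readings, config.readings_path, runs)
    coefficients = _stage("read", CoefficientTable.from_csv, config.coefficients_path)

    cfs = _stage("calibrate", calibrate_stage, runs, reading_sets, coefficients)
    artifacts["cf"] = out / "cf.csv"
    write_calibration_factors(cfs, artifacts["cf"])

    responses, per_dosemeter = _stage("respond", respond_stage, runs, reading_sets, cfs)
    responses_iso = _stage("iso", iso_stage, responses, per_dosemeter, config.weight_mode)
    artifacts["responses"] = out / "responses.csv"
    write_responses(responses_iso, artifacts["responses"])

    workenv_results: list[WorkEnvResult] = []
    if config.profiles_path is not None:
        from .workenv import load_profiles

        profiles = _stage("workenv", load_profiles, config.profiles_path)
        workenv_results = _stage(
            "workenv", workenv_stage, responses_iso, profiles, config.method
        )
        artifacts["workenv"] = out / "workenv.csv"
        write_workenv(workenv_results, artifacts["workenv"])

    artifacts["report"] = out / "report.txt"
    _stage("report", render_report, responses_iso, workenv_results, artifacts["report"])

    provenance = {
        "package": "doseresp",
        "version": __version__,
        "flags": {"weight_mode": config.weight_mode, "method": config.method},
        "seed": config.seed,
        "inputs": {
            "runs": _digest(config.runs_path),
            "readings": _digest(config.readings_path),
            "coefficients": _digest(config.coefficients_path),
            "profiles": _digest(config.profiles_path) if config.profiles_path else None,
        },
        "outputs": {k: _digest(v) for k, v in artifacts.items()},
    }
    artifacts["provenance"] = out / "provenance.json"
    artifacts["provenance"].write_text(json.dumps(provenance, indent=2) + "\n")
    return artifacts
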