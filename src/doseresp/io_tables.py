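"""Readers/writers for the CSV/JSON dialects and plain-text reports.

All persisted doses carry explicit unit suffixes in their column names
(mSv, mGy, mSv per mGy); nothing is inferred. Readers validate row by row
and report the offending row number in error messages.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DOSEMETER_TYPES, CalibrationFactor, IrradiationRun
from .response import ReadingSet, increment_readings
from .util import round_display
from .workenv import WorkEnvResult

__all__ = [
    "read_runs",
    "read_readings",
    "read_calibration_factors",
    "write_calibration_factors",
    "write_responses",
    "read_responses",
    "write_workenv",
    "render_report",
]

logger = logging.getLogger(__name__)

RUNS_COLUMNS = [
    "run_id", "role", "source_quality", "mean_energy_keV", "geometry",
    "zenith_angle_deg", "dose_rate_mGy_h", "duration_s", "n_rotations",
    "reference_distance_m",
]
READINGS_COLUMNS = ["run_id", "dosemeter_type", "dosemeter_id", "reading_mSv", "phase"]
RESPONSES_COLUMNS = [
    "run_id", "dosemeter_type", "mean_energy_keV", "geometry",
    "zenith_angle_deg", "mean_B", "sd_log", "K", "n",
]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_runs(path: str | Path) -> list[IrradiationRun]:
    """Parse runs.csv into typed irradiation runs; duplicate ids rejected."""
    df = pd.read_csv(path)
    missing = set(RUNS_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no runs")
    dupes = df["run_id"][df["run_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicated run_id(s) {list(dupes)}")
    runs = []
    for i, row in df.iterrows():
        try:
            n_rot = _opt(row.get("n_rotations"))
            runs.append(
                IrradiationRun(
                    run_id=str(row["run_id"]),
                    role=str(row.get("role", "phantom")),
                    source_quality=str(row["source_quality"]),
                    mean_energy=float(row["mean_energy_keV"]),
                    geometry=str(row["geometry"]),
                    zenith_angle=_opt(row.get("zenith_angle_deg")),
                    dose_rate=float(row["dose_rate_mGy_h"]),
                    duration=float(row["duration_s"]),
                    n_rotations=int(n_rot) if n_rot is not None else None,
                    reference_distance=_opt(row.get("reference_distance_m")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    return runs


def read_readings(
    path: str | Path, runs: Sequence[IrradiationRun] | None = None
) -> list[ReadingSet]:
    """Parse readings.csv into one ReadingSet per (run, dosemeter type).

    Rows with phase ``pre``/``post`` (cumulative EPD displays) are
    differenced per dosemeter id; phase ``single`` rows are taken as is.
    Zero readings (below detection limit / background) are kept at this
    stage; the response stage excludes them with a warning.
    """
    df = pd.read_csv(path)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no readings")
    bad_type = df[~df["dosemeter_type"].isin(DOSEMETER_TYPES)]
    if not bad_type.empty:
        i = bad_type.index[0]
        raise ValueError(
            f"{path}, row {i + 2}: unknown dosemeter type {bad_type['dosemeter_type'].iloc[0]!r}"
        )
    bad_phase = df[~df["phase"].isin(["pre", "post", "single"])]
    if not bad_phase.empty:
        i = bad_phase.index[0]
        raise ValueError(f"{path}, row {i + 2}: unknown phase {bad_phase['phase'].iloc[0]!r}")
    neg = df[df["reading_mSv"] < 0]
    if not neg.empty:
        i = neg.index[0]
        raise ValueError(f"{path}, row {i + 2}: negative reading {neg['reading_mSv'].iloc[0]}")
    known_ids = {r.run_id for r in runs} if runs is not None else None
    sets: list[ReadingSet] = []
    for (run_id, dtype), grp in df.groupby(["run_id", "dosemeter_type"], sort=False):
        run_id = str(run_id)
        if known_ids is not None and run_id not in known_ids:
            raise ValueError(f"{path}: readings reference unknown run_id {run_id!r}")
        phases = set(grp["phase"])
        if phases == {"single"}:
            readings = tuple(
                (str(r["dosemeter_id"]), float(r["reading_mSv"])) for _, r in grp.iterrows()
            )
            cumulative = False
        elif phases == {"pre", "post"}:
            pre = grp[grp["phase"] == "pre"].set_index("dosemeter_id")["reading_mSv"]
            post = grp[grp["phase"] == "post"].set_index("dosemeter_id")["reading_mSv"]
            if set(pre.index) != set(post.index):
                raise ValueError(
                    f"{path}: run {run_id} ({dtype}): pre/post dosemeter ids do not match"
                )
            ids = sorted(pre.index)
            inc = increment_readings([float(pre[d]) for d in ids], [float(post[d]) for d in ids])
            readings = tuple((str(d), v) for d, v in zip(ids, inc))
            cumulative = True
        else:
            raise ValueError(
                f"{path}: run {run_id} ({dtype}): mixed phases {sorted(phases)}; "
                "expected 'single' or 'pre'+'post'"
            )
        sets.append(ReadingSet(run_id, str(dtype), readings, is_cumulative=cumulative))
    return sets


def write_calibration_factors(cfs: Iterable[CalibrationFactor], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "dosemeter_type": c.dosemeter_type,
                "scope": c.scope,
                "dosemeter_id": c.dosemeter_id if c.dosemeter_id is not None else "",
                "cf": c.cf,
            }
            for c in cfs
        ]
    ).to_csv(path, index=False)


def read_calibration_factors(path: str | Path) -> list[CalibrationFactor]:
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        did = row.get("dosemeter_id")
        if pd.isna(did) or did == "":
            did = None
        else:
            did = str(did)
        try:
            out.append(
                CalibrationFactor(str(row["dosemeter_type"]), str(row["scope"]), float(row["cf"]), did)
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    return out


def responses_to_frame(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Normalize response-stage records into the responses.csv layout."""
    df = pd.DataFrame(list(rows))
    for col in RESPONSES_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RESPONSES_COLUMNS]


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_workenv(results: Iterable[WorkEnvResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "dosemeter_type": r.dosemeter_type,
                "facility": r.facility,
                "method": r.method,
                "B_workenv": r.B_workenv,
                "K_workenv": r.K_workenv if r.K_workenv is not None else np.nan,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def _response_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Pivot responses into the published layout: geometry rows, energy columns."""
    df = responses.copy()
    df["row"] = np.where(
        df["geometry"] == "ROT",
        "ROT(" + df["zenith_angle_deg"].astype(float).map("{:g}".format) + "°)",
        df["geometry"],
    )
    order = ["AP", "ROT(30°)", "ROT(60°)", "ROT(90°)", "ROT(120°)", "ROT(150°)", "ISO"]
    blocks = []
    for dtype, grp in df.groupby("dosemeter_type", sort=True):
        b = grp.pivot_table(index="row", columns="mean_energy_keV", values="mean_B")
        k = grp.pivot_table(index="row", columns="mean_energy_keV", values="K")
        b = b.reindex([r for r in order if r in b.index])
        k = k.reindex(b.index)
        merged = pd.concat(
            {"mean B (mSv/mGy)": b.map(lambda v: round_display(v, 2)),
             "K": k.map(lambda v: round_display(v, 3) if pd.notna(v) else v)},
            axis=1,
        )
        merged.insert(0, ("", "dosemeter_type"), dtype)
        blocks.append(merged)
    return pd.concat(blocks)


def render_report(
    responses: pd.DataFrame,
    workenv: Sequence[WorkEnvResult] | None,
    out_path: str | Path,
) -> str:
    """Write a plain-text report: per-condition responses, then facility factors.

    Mean responses print to 2 decimals and K to 3, mirroring the published
    table layouts. Missing cells render blank and are listed as warnings.
    """
    lines: list[str] = []
    lines.append("Per-condition dosemeter response (mean B in mSv per mGy air kerma; K = exp(1.96 x SD of ln B))")
    lines.append("")
    table = _response_table(responses)
    lines.append(table.to_string(na_rep=""))
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        lines.append("")
        lines.append(f"warning: {n_missing} cell(s) missing, rendered blank")
        logger.warning("report: %d missing cell(s)", n_missing)
    if workenv:
        lines.append("")
        lines.append("Working-environment conversion factor by facility type (reading per air kerma)")
        lines.append("")
        wdf = pd.DataFrame(
            [
                {
                    "dosemeter_type": r.dosemeter_type,
                    "facility": r.facility,
                    "method": r.method,
                    "B (mSv/mGy)": round_display(r.B_workenv, 2),
                    "K": round_display(r.K_workenv, 3) if r.K_workenv is not None else "",
                }
                for r in workenv
            ]
        )
        lines.append(wdf.to_string(index=False))
    text = "\n".join(lines) + "\n"
    Path(out_path).write_text(text)
    return text
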