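"""Loaders for the small fixture tables shipped with the package.

The fixtures transcribe the published experiment: the irradiation design
(sources, dose rates, durations, geometries), the per-condition response
table, the standard-condition conversion coefficient, the facility
profiles, and the historical dosemeter grouping.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .calibration import CoefficientTable, IrradiationRun
from .legacy_compat import GroupMap, load_groups
from .response import ResponseValue, uncertainty_k
from .workenv import FacilityProfile, load_profiles

__all__ = [
    "data_path",
    "load_run_design",
    "load_coefficients",
    "load_printed_responses",
    "printed_response_map",
    "load_facility_profiles",
    "load_legacy_groups",
]


def data_path(name: str) -> Path:
    """Filesystem path of a shipped data file."""
    return Path(resources.files("doseresp.data") / name)


def load_run_design(path: str | Path | None = None) -> list[IrradiationRun]:
    """The experiment's irradiation runs (shipped design unless overridden)."""
    from .io_tables import read_runs  # local import: io_tables imports this module's peers

    return read_runs(data_path("runs.csv") if path is None else path)


def load_coefficients(path: str | Path | None = None) -> CoefficientTable:
    return CoefficientTable.from_csv(data_path("coefficients.csv") if path is None else path)


def load_printed_responses() -> pd.DataFrame:
    """Published per-condition mean responses and uncertainties.

    Columns: dosemeter_type, geometry (AP|ROT|ISO), zenith_angle_deg
    (ROT only), mean_energy_keV, mean_B (mSv/mGy), K.
    """
    df = pd.read_csv(data_path("responses_printed.csv"))
    return df


def printed_response_map(
    dosemeter_type: str,
    geometries: tuple[str, ...] = ("AP", "ISO"),
    n: int = 4,
) -> dict[tuple[float, str], ResponseValue]:
    """Published responses of one type keyed (energy keV, geometry class).

    ROT entries are keyed by class "ROT" at the 90 deg zenith angle (the
    rotational-geometry row a custom profile would use). sd_log is
    back-derived from the printed K.
    """
    df = load_printed_responses()
    df = df[df["dosemeter_type"] == dosemeter_type]
    out: dict[tuple[float, str], ResponseValue] = {}
    for _, row in df.iterrows():
        geometry = row["geometry"]
        if geometry == "ROT" and row["zenith_angle_deg"] != 90:
            continue
        if geometry not in geometries:
            continue
        out[(float(row["mean_energy_keV"]), geometry)] = _printed_value(row, n)
    return out


def _printed_value(row: pd.Series, n: int) -> ResponseValue:
    import math

    sd_log = math.log(float(row["K"])) / 1.96
    return ResponseValue(float(row["mean_B"]), sd_log, uncertainty_k(sd_log), n)


def load_facility_profiles(path: str | Path | None = None) -> dict[str, FacilityProfile]:
    return load_profiles(data_path("profiles.json") if path is None else path)


def load_legacy_groups(path: str | Path | None = None) -> GroupMap:
    return load_groups(data_path("groups.json") if path is None else path)
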