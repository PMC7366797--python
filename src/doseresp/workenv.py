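"""Working-environment conversion factors by nuclear-facility type.

A worker's dose arrives spread over photon energies and incidence
geometries. Facility profiles give the assumed fractions of dose per
photon-energy band (0-100, 100-300, 300-3000 keV) and per geometry
(AP, ISO, ROT): nuclear power plants (NPP) 10%/90% over the two upper
bands, mixed-activities (MA) facilities 20%/80%, both 50% AP / 50% ISO.
The 100-300 keV band response is represented by the measured 119 and
207 keV responses mixed 25:75; the 300-3000 keV band by 662 keV.

The facility-level factor is the doubly weighted mean of the measured
per-condition responses. The default aggregates on the log scale
(a weighted geometric mean), consistent with the lognormal uncertainty
model; an arithmetic alternative is available and, by AM-GM, never
smaller.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .calibration import DOSEMETER_TYPES
from .response import ResponseValue, uncertainty_k

__all__ = [
    "ENERGY_BANDS",
    "GEOMETRY_CLASSES",
    "DEFAULT_BAND_MIXES",
    "FacilityProfile",
    "WorkEnvResult",
    "band_response",
    "facility_response",
    "load_profiles",
]

ENERGY_BANDS = ("band_0_100", "band_100_300", "band_300_3000")
GEOMETRY_CLASSES = ("AP", "ISO", "ROT")

#: Measured energies representing each band: 25:75 mix of 119/207 keV for
#: 100-300 keV, the single 662 keV point for 300-3000 keV. No measurement
#: exists below 119 keV, so the 0-100 band has no default representation.
DEFAULT_BAND_MIXES: dict[str, tuple[tuple[float, float], ...]] = {
    "band_100_300": ((119.0, 0.25), (207.0, 0.75)),
    "band_300_3000": ((662.0, 1.0),),
}

_METHODS = ("log_scale", "arithmetic")


def _check_fractions(name: str, fractions: Mapping[str, float], keys: Sequence[str]) -> None:
    unknown = set(fractions) - set(keys)
    if unknown:
        raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
    for k, v in fractions.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}: fraction {k}={v} outside [0, 1]")
    total = sum(fractions.get(k, 0.0) for k in keys)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class FacilityProfile:
    """Dose fractions by photon-energy band and by incidence geometry."""

    name: str
    energy_fractions: Mapping[str, float]
    geometry_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_fractions(f"profile {self.name} energies", self.energy_fractions, ENERGY_BANDS)
        _check_fractions(f"profile {self.name} geometries", self.geometry_fractions, GEOMETRY_CLASSES)


@dataclass(frozen=True)
class WorkEnvResult:
    dosemeter_type: str
    facility: str
    B_workenv: float  # mSv per mGy
    K_workenv: float | None
    method: str

    def __post_init__(self) -> None:
        if self.dosemeter_type not in DOSEMETER_TYPES:
            raise ValueError(f"unknown dosemeter type {self.dosemeter_type!r}")
        if self.B_workenv <= 0:
            raise ValueError(f"B_workenv must be > 0, got {self.B_workenv}")
        if self.K_workenv is not None and self.K_workenv < 1:
            raise ValueError(f"K_workenv must be >= 1, got {self.K_workenv}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")


def band_response(
    components: Sequence[tuple[float, float]],
    responses: Mapping[float, ResponseValue],
    method: str = "log_scale",
) -> ResponseValue:
    """Mix measured per-energy responses into one band response.

    ``components`` is a list of (energy keV, weight); weights must sum
    to 1. ``log_scale`` forms exp(sum w ln B); ``arithmetic`` forms
    sum w B. sd_log is propagated as sqrt(sum (w sd_e)^2) assuming
    independent energies.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if not components:
        raise ValueError("band has no components")
    total_w = sum(w for _, w in components)
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"component weights sum to {total_w}, expected 1")
    missing = [e for e, _ in components if e not in responses]
    if missing:
        raise ValueError(f"no response available at energy {missing} keV")
    if method == "arithmetic":
        mean_b = sum(w * responses[e].mean_B for e, w in components)
    else:
        mean_b = math.exp(sum(w * math.log(responses[e].mean_B) for e, w in components))
    sds = [responses[e].sd_log for e, _ in components]
    if any(s is None for s in sds):
        sd_log, k = None, None
    else:
        sd_log = math.sqrt(sum((w * responses[e].sd_log) ** 2 for e, w in components))
        k = uncertainty_k(sd_log)
    n = min(responses[e].n for e, _ in components)
    return ResponseValue(mean_b, sd_log, k, n)


def _flat_cell_weights(
    profile: FacilityProfile,
    band_mixes: Mapping[str, Sequence[tuple[float, float]]],
) -> dict[tuple[float, str], float]:
    """Collapse band x geometry x component weighting to per-(energy, geometry) weights."""
    cells: dict[tuple[float, str], float] = {}
    for geometry, gw in profile.geometry_fractions.items():
        if gw == 0.0:
            continue
        for band, bw in profile.energy_fractions.items():
            if bw == 0.0:
                continue
            if band not in band_mixes:
                raise ValueError(
                    f"profile {profile.name}: band {band} has weight {bw} "
                    "but no band mix defines its measured energies"
                )
            for energy, cw in band_mixes[band]:
                key = (energy, geometry)
                cells[key] = cells.get(key, 0.0) + gw * bw * cw
    return cells


def facility_response(
    profile: FacilityProfile,
    responses: Mapping[tuple[float, str], ResponseValue],
    dosemeter_type: str,
    band_mixes: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    method: str = "log_scale",
) -> WorkEnvResult:
    """Working-environment conversion factor for one dosemeter type.

    ``responses`` maps (energy keV, geometry class) to the measured
    response. Energy-band and geometry weights multiply through to a flat
    per-cell weighting; the cells are combined as a weighted geometric
    (``log_scale``) or arithmetic mean. K is propagated on the log scale
    assuming independent cells: sd = sqrt(sum (w_cell sd_cell)^2).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    band_mixes = DEFAULT_BAND_MIXES if band_mixes is None else band_mixes
    cells = _flat_cell_weights(profile, band_mixes)
    missing = [c for c in cells if c not in responses]
    if missing:
        raise ValueError(
            f"profile {profile.name}: no response for cell(s) "
            + ", ".join(f"({e:g} keV, {g})" for e, g in sorted(missing))
        )
    if method == "arithmetic":
        mean_b = sum(w * responses[c].mean_B for c, w in cells.items())
    else:
        mean_b = math.exp(sum(w * math.log(responses[c].mean_B) for c, w in cells.items()))
    sds = [responses[c].sd_log for c in cells]
    if any(s is None for s in sds):
        k = None
    else:
        sd_log = math.sqrt(sum((w * responses[c].sd_log) ** 2 for c, w in cells.items()))
        k = uncertainty_k(sd_log)
    return WorkEnvResult(dosemeter_type, profile.name, mean_b, k, method)


def load_profiles(path: str | Path) -> dict[str, FacilityProfile]:
    """Read named facility profiles from a JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        name: FacilityProfile(name, spec["energy_fractions"], spec["geometry_fractions"])
        for name, spec in raw.items()
    }
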