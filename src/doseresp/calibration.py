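"""Reference doses and calibration factors.

An irradiation run delivers a known air kerma (dose rate x duration) to a
phantom. Before the anthropomorphic-phantom runs, dosemeters are exposed on
a water slab phantom under the standard condition (Cs-137, 662 keV, AP);
the known air kerma is converted to the personal dose equivalent Hp(10)
with a conversion coefficient c (mSv per mGy), and a calibration factor
CF = reference Hp(10) / reading corrects each dosemeter's individual
sensitivity. Electronic personal dosemeters (EPD) are calibrated one by
one; passive badges (GB, LB) are uniform within a lot and share a single
lot CF computed from the mean reading.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DOSEMETER_TYPES",
    "ROTATION_PERIOD_S",
    "IrradiationRun",
    "CoefficientTable",
    "CalibrationFactor",
    "reference_air_kerma",
    "air_kerma_to_hp10",
    "calibration_factor",
]

DOSEMETER_TYPES = ("EPD", "GB", "LB")

#: Rotation period of the phantom support device, seconds per revolution.
ROTATION_PERIOD_S = 45.0

_ROT_ANGLES = (30.0, 60.0, 90.0, 120.0, 150.0)
_DESIGN_ENERGIES = (119.0, 207.0, 662.0)


@dataclass(frozen=True)
class IrradiationRun:
    """One source/geometry/duration configuration of the experiment.

    ``role`` distinguishes the slab-phantom calibration exposure from the
    anthropomorphic-phantom response runs; positions of dosemeters on the
    phantom are metadata and carry no computation.
    """

    run_id: str
    source_quality: str
    mean_energy: float  # keV
    geometry: str  # "AP" | "ROT"
    dose_rate: float  # mGy/h air kerma at the reference distance
    duration: float  # s
    zenith_angle: float | None = None  # deg, ROT only
    n_rotations: int | None = None
    reference_distance: float | None = None  # m
    role: str = "phantom"  # "phantom" | "calibration"

    def __post_init__(self) -> None:
        if self.dose_rate <= 0:
            raise ValueError(f"run {self.run_id}: dose_rate must be > 0")
        if self.duration <= 0:
            raise ValueError(f"run {self.run_id}: duration must be > 0")
        if self.geometry not in ("AP", "ROT"):
            raise ValueError(f"run {self.run_id}: unknown geometry {self.geometry!r}")
        if self.geometry == "ROT":
            if self.zenith_angle is None:
                raise ValueError(f"run {self.run_id}: ROT geometry requires a zenith angle")
            if self.zenith_angle not in _ROT_ANGLES:
                raise ValueError(
                    f"run {self.run_id}: zenith angle {self.zenith_angle} not in {_ROT_ANGLES}"
                )
        elif self.zenith_angle is not None:
            raise ValueError(f"run {self.run_id}: zenith angle given for AP geometry")
        if self.role not in ("phantom", "calibration"):
            raise ValueError(f"run {self.run_id}: unknown role {self.role!r}")
        if self.mean_energy not in _DESIGN_ENERGIES:
            warnings.warn(
                f"run {self.run_id}: mean energy {self.mean_energy} keV is outside "
                f"the study design energies {_DESIGN_ENERGIES}",
                stacklevel=2,
            )
        if self.n_rotations is not None:
            expected = self.n_rotations * ROTATION_PERIOD_S
            if abs(self.duration - expected) > ROTATION_PERIOD_S / 2:
                # e.g. 445 s printed with 11 rotations (495 s at 45 s/rev):
                # the reference kerma is consistent with the duration, so the
                # duration wins and the rotation count is only flagged.
                warnings.warn(
                    f"run {self.run_id}: duration {self.duration} s inconsistent with "
                    f"{self.n_rotations} rotations at {ROTATION_PERIOD_S} s/rev "
                    f"({expected:.0f} s); using the duration",
                    stacklevel=2,
                )

    @property
    def reference_kerma(self) -> float:
        """Reference air kerma delivered by this run, mGy (unrounded)."""
        return reference_air_kerma(self.dose_rate, self.duration)

    @property
    def angle_label(self) -> str:
        """Geometry label used in tables: ``AP`` or ``ROT(θ°)``."""
        if self.geometry == "AP":
            return "AP"
        return f"ROT({self.zenith_angle:g}°)"


@dataclass(frozen=True)
class CoefficientTable:
    """Hp(10) per air kerma conversion coefficients by energy and geometry/angle."""

    entries: tuple[tuple[float, str, float], ...]  # (energy keV, geometry label, c)

    def __post_init__(self) -> None:
        for energy, geometry, c in self.entries:
            if c <= 0:
                raise ValueError(
                    f"coefficient for ({energy} keV, {geometry}) must be > 0, got {c}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, str, float]]) -> "CoefficientTable":
        return cls(tuple((float(e), str(g), float(c)) for e, g, c in pairs))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls.from_pairs(
            (row["energy_keV"], row["geometry"], row["coefficient_mSv_per_mGy"])
            for row in rows
        )

    def get(self, energy: float, geometry: str) -> float:
        """Exact-match lookup of c (mSv/mGy) at (energy, geometry)."""
        for e, g, c in self.entries:
            if e == energy and g == geometry:
                return c
        raise KeyError(f"no conversion coefficient for ({energy} keV, {geometry})")


@dataclass(frozen=True)
class CalibrationFactor:
    """Multiplier applied to raw readings: reference Hp(10) over reading (mSv/mSv)."""

    dosemeter_type: str
    scope: str  # "per_dosemeter" | "per_lot"
    cf: float
    dosemeter_id: str | None = None

    def __post_init__(self) -> None:
        if self.dosemeter_type not in DOSEMETER_TYPES:
            raise ValueError(f"unknown dosemeter type {self.dosemeter_type!r}")
        if self.cf <= 0 or not math.isfinite(self.cf):
            raise ValueError(f"calibration factor must be finite and > 0, got {self.cf}")
        if self.scope not in ("per_dosemeter", "per_lot"):
            raise ValueError(f"unknown calibration scope {self.scope!r}")
        # EPDs are individually calibrated; passive badges are lot-uniform.
        required = "per_dosemeter" if self.dosemeter_type == "EPD" else "per_lot"
        if self.scope != required:
            raise ValueError(
                f"{self.dosemeter_type} requires scope={required!r}, got {self.scope!r}"
            )
        if self.scope == "per_dosemeter" and self.dosemeter_id is None:
            raise ValueError("per_dosemeter calibration factor needs a dosemeter_id")


def reference_air_kerma(dose_rate: float, duration: float) -> float:
    """Air kerma (mGy) delivered at ``dose_rate`` mGy/h for ``duration`` s.

    Returned unrounded; table display rounds to 2 decimals separately.
    """
    if dose_rate <= 0:
        raise ValueError(f"dose_rate must be > 0, got {dose_rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    return dose_rate * duration / 3600.0


def air_kerma_to_hp10(kerma: float, c: float) -> float:
    """Convert air kerma (mGy) to Hp(10) (mSv) with coefficient ``c`` (mSv/mGy)."""
    if kerma < 0:
        raise ValueError(f"kerma must be >= 0, got {kerma}")
    if c <= 0:
        raise ValueError(f"conversion coefficient must be > 0, got {c}")
    return kerma * c


def calibration_factor(
    readings: Sequence[float],
    reference_hp10: float,
    scope: str,
    dosemeter_type: str,
    dosemeter_ids: Sequence[str] | None = None,
) -> list[CalibrationFactor]:
    """Calibration factor(s) from slab-phantom readings.

    ``per_dosemeter`` returns one CF per reading (reference / reading_i);
    ``per_lot`` returns a single CF (reference / mean reading). A zeroed
    dosemeter cannot be calibrated, so non-positive readings are rejected.
    """
    if len(readings) == 0:
        raise ValueError("readings must be non-empty")
    if reference_hp10 <= 0:
        raise ValueError(f"reference_hp10 must be > 0, got {reference_hp10}")
    for r in readings:
        if r <= 0:
            raise ValueError(f"cannot calibrate against non-positive reading {r}")
    if scope == "per_dosemeter":
        if dosemeter_ids is None:
            dosemeter_ids = [f"{dosemeter_type}-{i + 1}" for i in range(len(readings))]
        if len(dosemeter_ids) != len(readings):
            raise ValueError("dosemeter_ids must align with readings")
        return [
            CalibrationFactor(dosemeter_type, "per_dosemeter", reference_hp10 / r, did)
            for did, r in zip(dosemeter_ids, readings)
        ]
    if scope == "per_lot":
        mean_reading = sum(readings) / len(readings)
        return [CalibrationFactor(dosemeter_type, "per_lot", reference_hp10 / mean_reading)]
    raise ValueError(f"unknown calibration scope {scope!r}")
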