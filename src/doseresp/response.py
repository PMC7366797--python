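"""Dosemeter response B (mSv per mGy air kerma) and its uncertainty.

Each run irradiates four dosemeters of one type simultaneously; the
response of one dosemeter is reading x CF / reference kerma, and the run's
response is the arithmetic mean of the four. Spread across the four
dosemeters is summarised on the log scale: sd_log is the sample SD of
ln B, and the multiplicative 95% uncertainty factor is K = exp(1.96 x
sd_log), under a lognormal model for B.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import DOSEMETER_TYPES

__all__ = [
    "ReadingSet",
    "ResponseValue",
    "increment_readings",
    "single_response",
    "aggregate_response",
    "deviation_rate_sd",
    "uncertainty_k",
]

logger = logging.getLogger(__name__)

#: z-quantile defining the 95% multiplicative uncertainty band.
Z_95 = 1.96


@dataclass(frozen=True)
class ReadingSet:
    """Raw readings of one run for one dosemeter type.

    ``is_cumulative`` marks EPD readings, whose display accumulates across
    runs; increments are taken with :func:`increment_readings` before any
    response computation.
    """

    run_id: str
    dosemeter_type: str
    readings: tuple[tuple[str, float], ...]  # (dosemeter_id, reading mSv)
    is_cumulative: bool = False

    def __post_init__(self) -> None:
        if self.dosemeter_type not in DOSEMETER_TYPES:
            raise ValueError(f"unknown dosemeter type {self.dosemeter_type!r}")
        if len(self.readings) == 0:
            raise ValueError(f"run {self.run_id}: reading set must be non-empty")
        for did, r in self.readings:
            if r < 0:
                raise ValueError(f"run {self.run_id}, dosemeter {did}: negative reading {r}")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(r for _, r in self.readings)

    @property
    def dosemeter_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.readings)


@dataclass(frozen=True)
class ResponseValue:
    """Mean response with log-scale spread over the dosemeters of a run.

    ``sd_log`` and ``K`` are ``None`` when n = 1 (no spread estimate).
    """

    mean_B: float  # mSv per mGy
    sd_log: float | None
    K: float | None
    n: int

    def __post_init__(self) -> None:
        if self.mean_B <= 0:
            raise ValueError(f"mean_B must be > 0, got {self.mean_B}")
        if (self.sd_log is None) != (self.K is None):
            raise ValueError("sd_log and K must both be present or both absent")
        if self.K is not None:
            if self.K < 1:
                raise ValueError(f"K must be >= 1, got {self.K}")
            if not math.isclose(self.K, math.exp(Z_95 * self.sd_log), rel_tol=1e-12):
                raise ValueError("K must equal exp(1.96 x sd_log)")


def uncertainty_k(sd_log: float) -> float:
    """Multiplicative 95% uncertainty factor K = exp(1.96 x SD of ln B)."""
    if sd_log < 0:
        raise ValueError(f"sd_log must be >= 0, got {sd_log}")
    return math.exp(Z_95 * sd_log)


def increment_readings(pre: Sequence[float], post: Sequence[float]) -> list[float]:
    """Element-wise post - pre for cumulative (EPD) displays.

    Lists must be aligned by dosemeter; a cumulative reading cannot
    decrease, so negative increments are rejected.
    """
    if len(pre) != len(post):
        raise ValueError(f"pre ({len(pre)}) and post ({len(post)}) differ in length")
    out = []
    for i, (a, b) in enumerate(zip(pre, post)):
        if b < a:
            raise ValueError(f"reading {i} decreased from {a} to {b} mSv")
        out.append(b - a)
    return out


def single_response(reading: float, cf: float, reference_kerma: float) -> float:
    """Response of one dosemeter: reading (mSv) x CF / reference kerma (mGy)."""
    if reading <= 0:
        raise ValueError(f"reading must be > 0, got {reading}")
    if cf <= 0:
        raise ValueError(f"calibration factor must be > 0, got {cf}")
    if reference_kerma <= 0:
        raise ValueError(f"reference_kerma must be > 0, got {reference_kerma}")
    return reading * cf / reference_kerma


def aggregate_response(values: Sequence[float]) -> ResponseValue:
    """Summarise per-dosemeter responses of one run.

    mean_B is the arithmetic mean; sd_log is the sample SD (n-1) of ln B;
    K = exp(1.96 x sd_log). With a single value no spread can be estimated
    and sd_log/K are absent.
    """
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"all responses must be > 0, got {arr.min()}")
    mean_b = float(arr.mean())
    if arr.size == 1:
        return ResponseValue(mean_b, None, None, 1)
    sd_log = float(np.std(np.log(arr), ddof=1))
    return ResponseValue(mean_b, sd_log, uncertainty_k(sd_log), int(arr.size))


def deviation_rate_sd(reading_sets: Sequence[ReadingSet]) -> dict[str, float]:
    """Pooled measurement-error SD per dosemeter type, in percent.

    For each reading set the individual deviation rates from the set mean,
    (r_i - mean)/mean, are computed; rates are pooled across all sets of a
    type and summarised as the pooled SD with per-set degrees of freedom,
    sqrt(sum of squared rates / sum over sets of (n_set - 1)), x 100.
    Subtracting each set's own mean removes a 1/n_set share of the
    variance, so the per-set degrees of freedom (rather than one pooled
    n - 1) make the estimate consistent for the per-reading relative SD.
    Sets with fewer than two readings carry no spread information and are
    skipped with a warning.
    """
    sum_sq: dict[str, float] = {}
    dof: dict[str, int] = {}
    for rs in reading_sets:
        vals = np.asarray(rs.values, dtype=float)
        if vals.size < 2:
            logger.warning(
                "run %s (%s): %d reading(s), skipped in deviation-rate pooling",
                rs.run_id, rs.dosemeter_type, vals.size,
            )
            continue
        mean = vals.mean()
        if mean <= 0:
            logger.warning(
                "run %s (%s): non-positive mean reading, skipped", rs.run_id, rs.dosemeter_type
            )
            continue
        rates = (vals - mean) / mean
        sum_sq[rs.dosemeter_type] = sum_sq.get(rs.dosemeter_type, 0.0) + float(rates @ rates)
        dof[rs.dosemeter_type] = dof.get(rs.dosemeter_type, 0) + (vals.size - 1)
    return {
        dtype: math.sqrt(sum_sq[dtype] / dof[dtype]) * 100.0
        for dtype in sum_sq
        if dof[dtype] >= 1
    }
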