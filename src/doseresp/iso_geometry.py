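"""Isotropic-geometry response synthesized from rotational exposures.

A truly isotropic field delivers dose uniformly over the sphere. The
experiment approximates it by rotating the phantom about axes at five
zenith angles (30, 60, 90, 120, 150 deg) and weighting each rotational
response B_ROT(theta) by the solid-angle fraction of its zenith band:
w = (cos(theta_lo) - cos(theta_hi)) / 2, the normalized integral of
sin(theta)/2 over the band. The bands 0-45, 45-75, 75-105, 105-135 and
135-180 deg partition the sphere, with weights 0.1464, 0.2241, 0.2588,
0.2241, 0.1464 (printed to three decimals as 0.146/0.224/0.259, summing to
0.999 — the printed coefficients are kept unrenormalized in ``printed``
mode so published table cells are reproduced exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .response import ResponseValue, aggregate_response, uncertainty_k

__all__ = [
    "ZenithBand",
    "band_weight",
    "default_band_set",
    "printed_weights",
    "iso_response",
    "iso_response_per_dosemeter",
    "ROT_ANGLES",
]

ROT_ANGLES = (30.0, 60.0, 90.0, 120.0, 150.0)

#: Band edges keyed by representative zenith angle.
_DEFAULT_EDGES = {
    30.0: (0.0, 45.0),
    60.0: (45.0, 75.0),
    90.0: (75.0, 105.0),
    120.0: (105.0, 135.0),
    150.0: (135.0, 180.0),
}


def band_weight(theta_lo: float, theta_hi: float) -> float:
    """Solid-angle fraction of the zenith band [theta_lo, theta_hi] (degrees)."""
    if not (0.0 <= theta_lo < theta_hi <= 180.0):
        raise ValueError(
            f"band must satisfy 0 <= lo < hi <= 180, got ({theta_lo}, {theta_hi})"
        )
    return (math.cos(math.radians(theta_lo)) - math.cos(math.radians(theta_hi))) / 2.0


@dataclass(frozen=True)
class ZenithBand:
    representative_angle: float
    theta_lo: float
    theta_hi: float

    def __post_init__(self) -> None:
        band_weight(self.theta_lo, self.theta_hi)  # validates the bounds
        if not (self.theta_lo <= self.representative_angle <= self.theta_hi):
            raise ValueError(
                f"representative angle {self.representative_angle} outside band "
                f"[{self.theta_lo}, {self.theta_hi}]"
            )

    @property
    def weight(self) -> float:
        return band_weight(self.theta_lo, self.theta_hi)


def default_band_set() -> list[ZenithBand]:
    """The five-band partition of [0, 180] deg used for ISO synthesis."""
    return [ZenithBand(rep, lo, hi) for rep, (lo, hi) in _DEFAULT_EDGES.items()]


def printed_weights(bands: Sequence[ZenithBand] | None = None) -> dict[float, float]:
    """Band weights rounded to 3 decimals, unrenormalized (they sum to 0.999)."""
    bands = default_band_set() if bands is None else list(bands)
    return {b.representative_angle: round(b.weight, 3) for b in bands}


def _weights(bands: Sequence[ZenithBand] | None, weight_mode: str) -> dict[float, float]:
    bands = default_band_set() if bands is None else list(bands)
    if weight_mode == "printed":
        return printed_weights(bands)
    if weight_mode == "exact":
        return {b.representative_angle: b.weight for b in bands}
    raise ValueError(f"weight_mode must be 'printed' or 'exact', got {weight_mode!r}")


def _check_angles(present: Sequence[float], weights: Mapping[float, float]) -> None:
    missing = [a for a in weights if a not in present]
    if missing:
        raise ValueError(f"missing rotational response at zenith angle(s) {missing}")


def iso_response(
    rot: Mapping[float, ResponseValue],
    bands: Sequence[ZenithBand] | None = None,
    weight_mode: str = "printed",
) -> ResponseValue:
    """Weighted combination of rotational responses into the ISO response.

    ``rot`` maps each representative zenith angle to its run-level
    response. The spread of the ISO value is propagated from the per-angle
    sd_log assuming independent angles: sd = sqrt(sum (w x sd_i)^2); when
    per-dosemeter responses are available, prefer
    :func:`iso_response_per_dosemeter`, which estimates the spread from the
    four individually synthesized dosemeters instead.
    """
    weights = _weights(bands, weight_mode)
    _check_angles(list(rot), weights)
    mean_b = sum(w * rot[a].mean_B for a, w in weights.items())
    sds = [rot[a].sd_log for a in weights]
    if any(s is None for s in sds):
        sd_log = None
        k = None
    else:
        sd_log = math.sqrt(sum((w * rot[a].sd_log) ** 2 for a, w in weights.items()))
        k = uncertainty_k(sd_log)
    n = min(rot[a].n for a in weights)
    return ResponseValue(mean_b, sd_log, k, n)


def iso_response_per_dosemeter(
    rot_per_dosemeter: Mapping[float, Mapping[str, float]],
    bands: Sequence[ZenithBand] | None = None,
    weight_mode: str = "printed",
) -> ResponseValue:
    """ISO response with spread estimated across dosemeter positions.

    ``rot_per_dosemeter`` maps zenith angle -> {dosemeter_id: B}. Each
    dosemeter present at every angle is synthesized separately, and the
    resulting per-dosemeter ISO values are aggregated; the ISO uncertainty
    K therefore reflects between-dosemeter spread after angle averaging,
    which is smaller than any single-angle K.
    """
    weights = _weights(bands, weight_mode)
    _check_angles(list(rot_per_dosemeter), weights)
    common_ids = set.intersection(
        *(set(rot_per_dosemeter[a]) for a in weights)
    )
    if not common_ids:
        raise ValueError("no dosemeter id present at every zenith angle")
    per_dosemeter = [
        sum(w * rot_per_dosemeter[a][did] for a, w in weights.items())
        for did in sorted(common_ids)
    ]
    return aggregate_response(per_dosemeter)
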