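"""Bridge to historical dosemeter-response data expressed per Hp(10).

Older response studies report readings per delivered Hp(10) (mSv/mSv).
Multiplying by the air-kerma-to-Hp(10) conversion coefficient c (mSv/mGy)
puts them on the same per-air-kerma scale as the modern measurements:

    [reading / Hp(10)] x [Hp(10) / air kerma] = [reading / air kerma]

Historical model codes are grouped to the dosemeter classes used in Japan
before 2000 (old film badge, multi-element film badge, TLD) and each
group's response is the unweighted mean over its members. Numeric legacy
values are user-supplied; only the grouping ships with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "ENERGY_MATCH_TOL_KEV",
    "LegacyResponse",
    "GroupMap",
    "per_hp10_to_per_kerma",
    "group_average",
    "load_groups",
]

#: Nominal band energies differ slightly between studies (118 vs 119 keV,
#: 208 vs 207 keV); energies within this tolerance are treated as the same.
ENERGY_MATCH_TOL_KEV = 2.0


@dataclass(frozen=True)
class LegacyResponse:
    model_code: str
    response_per_hp10: float  # mSv/mSv
    energy: float  # keV
    geometry: str

    def __post_init__(self) -> None:
        if self.response_per_hp10 <= 0:
            raise ValueError(
                f"{self.model_code}: response_per_hp10 must be > 0, "
                f"got {self.response_per_hp10}"
            )


@dataclass(frozen=True)
class GroupMap:
    """Disjoint grouping of historical model codes into dosemeter classes."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name} has no members")
            for m in members:
                if m in seen:
                    raise ValueError(f"model {m} in both {seen[m]} and {name}")
                seen[m] = name


def per_hp10_to_per_kerma(response_per_hp10: float, c: float) -> float:
    """Convert a per-Hp(10) response (mSv/mSv) to per air kerma (mSv/mGy)."""
    if response_per_hp10 <= 0:
        raise ValueError(f"response_per_hp10 must be > 0, got {response_per_hp10}")
    if c <= 0:
        raise ValueError(f"conversion coefficient must be > 0, got {c}")
    return response_per_hp10 * c


def _matches(r: LegacyResponse, energy: float, geometry: str) -> bool:
    return abs(r.energy - energy) <= ENERGY_MATCH_TOL_KEV and r.geometry == geometry


def group_average(
    group_map: GroupMap,
    responses: Sequence[LegacyResponse],
    energy: float,
    geometry: str,
) -> dict[str, float]:
    """Unweighted mean response per group at one (energy, geometry).

    Every member of a group must have a response at the requested
    condition; a single-member group returns that member's value.
    """
    out: dict[str, float] = {}
    for name, members in group_map.groups.items():
        values = []
        for m in members:
            found = [r for r in responses if r.model_code == m and _matches(r, energy, geometry)]
            if not found:
                raise ValueError(
                    f"group {name}: no response for model {m} at "
                    f"({energy:g} keV, {geometry})"
                )
            if len(found) > 1:
                raise ValueError(
                    f"group {name}: {len(found)} responses for model {m} at "
                    f"({energy:g} keV, {geometry})"
                )
            values.append(found[0].response_per_hp10)
        out[name] = sum(values) / len(values)
    return out


def load_groups(path: str | Path) -> GroupMap:
    """Read the model-code grouping from a JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    return GroupMap({name: tuple(members) for name, members in raw.items()})
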