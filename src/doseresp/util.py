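"""Small numeric helpers shared across the pipeline.

All chained computation runs at full float precision; rounding here is
either *display* rounding (table cells) or *device* rounding (a dosemeter
display truncated to its minimum unit). Both use round-half-to-even on the
decimal representation so results do not depend on platform printf
behaviour.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

__all__ = ["round_display", "round_to_unit"]


def round_display(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, half to even.

    Operates on the shortest decimal representation of the float, so a
    value computed as 1.285 (binary-nearest) rounds to 1.28, not to
    whatever the extra binary digits would suggest.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


def round_to_unit(x: float, unit: float) -> float:
    """Round ``x`` to the nearest multiple of ``unit`` (half to even).

    ``unit == 0`` disables rounding. Used to emulate a dosemeter display
    with a minimum measurement unit (0.01 mSv for the instruments studied).
    """
    if unit < 0:
        raise ValueError("rounding unit must be >= 0")
    if unit == 0:
        return float(x)
    d_unit = Decimal(repr(float(unit)))
    n = (Decimal(repr(float(x))) / d_unit).to_integral_value(rounding=ROUND_HALF_EVEN)
    return float(n * d_unit)
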