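"""Half-up rounding used for every reported percentage."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero at `ndigits` decimals.

    Python's built-in round() is banker's rounding; the conventional
    "half-up" rule is what printed summary percentages follow.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: int, total: int, ndigits: int = 2) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, ndigits)
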