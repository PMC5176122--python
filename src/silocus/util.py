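"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def mean_half_up(values, ndigits: int = 2) -> float:
    """Mean of decimal-valued inputs, rounded half up without float drift.

    Summing printed decimals like 0.18 + 0.02 in binary floats can land a
    hair below the true decimal sum and flip a half-up rounding; averaging
    in decimal arithmetic keeps table-style means exact.
    """
    if not values:
        raise ValueError("mean of empty sequence")
    total = sum(Decimal(repr(v)) for v in values)
    q = Decimal(1).scaleb(-ndigits)
    return float((total / len(values)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike Python's banker's rounding.

    Table-style reporting conventions round half up; ``round()`` would turn
    2.5 into 2.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
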