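"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at `ndigits` decimals.

    Python's builtin round() is banker's rounding; the reported summary
    percentages use conventional half-up rounding, applied uniformly.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
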