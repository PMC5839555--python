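"""Display rounding used throughout the package.

Percentages are rounded half-up (15/35 = 42.857 -> 42.9), matching how the
validation tables are conventionally printed; Python's built-in ``round`` is
banker's rounding and would differ at exact halves.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
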