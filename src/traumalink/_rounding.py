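"""Half-up decimal rounding, as registries print their percentages."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` half away from zero at ``ndigits`` decimals.

    Works on the decimal (printed) representation, so 44.35 -> 44.4 even
    where binary floats would tie-break downwards.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    result = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(result)


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
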