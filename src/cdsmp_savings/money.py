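"""Rounding and rendering of currency, counts and percentages.

All internal arithmetic in this package is carried unrounded (double
precision); rounding is a rendering concern, with two deliberate exceptions
that mirror the spreadsheet's own chain: utilization reductions are whole
percentage points, and the per-participant program cost is whole dollars.
The rounding mode everywhere is half-away-from-zero (218.75 -> 219,
562.5054 -> 562.51), not banker's rounding.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_away", "usd", "whole", "percent"]


def _dec(x: float) -> Decimal:
    # repr() gives the shortest decimal string that round-trips the float,
    # which is the value the user actually sees.
    return Decimal(repr(float(x)))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(_dec(x).quantize(exp, rounding=ROUND_HALF_UP))


def usd(x: float) -> str:
    """Render a dollar amount to the cent with thousands separators: 1,513.05."""
    return f"{_dec(x).quantize(Decimal('0.01'), rounding=ROUND_HALF_UP):,.2f}"


def whole(x: float) -> str:
    """Render to the nearest whole unit (persons, dollars): 180,614,335."""
    return f"{_dec(x).quantize(Decimal(1), rounding=ROUND_HALF_UP):,.0f}"


def percent(fraction: float) -> str:
    """Render a fraction as a percentage without trailing zeros: 0.05 -> '5%'."""
    return f"{fraction * 100:g}%"
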