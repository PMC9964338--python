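"""Number formatting shared by report writers.

Two display conventions coexist in the published tables this package
reproduces: diagnostic-accuracy percentages are rounded half-up to two
decimals, while band-stratification percentages are truncated toward zero.
Both are provided here so facsimile output matches cell for cell.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (school rounding), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    """Drop digits beyond ``ndigits`` without rounding."""
    factor = 10**ndigits
    return math.floor(x * factor) / factor


def fmt_percent(value: float | None, ndigits: int = 2) -> str:
    """Render a proportion as a percentage string; ``None`` renders as '-'."""
    if value is None:
        return "-"
    return f"{round_half_up(100.0 * value, ndigits):.{ndigits}f}%"


def fmt_ratio(value: float | None, ndigits: int = 2) -> str:
    """Render a likelihood ratio; ``None`` (undefined) renders as '-'."""
    if value is None:
        return "-"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
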