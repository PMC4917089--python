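"""Shared helpers: errors and half-up decimal rounding for reported ratios."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


class TableFormatError(ValueError):
    """A table on disk violates the expected format."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def round_half_up(value, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (the convention of reported
    percentages such as 71.66, 82.28)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 2) -> float | None:
    """100*count/denominator rounded half-up; ``None`` when the denominator
    is zero (undefined, never reported as 0)."""
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-ndigits)
    val = Decimal(count) * 100 / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def exact_ratio(a: int, b: int, ndigits: int = 2) -> float | None:
    """a/b as an exactly-rounded (half-up) decimal; ``None`` for b == 0."""
    if b == 0:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(a) / Decimal(b)).quantize(q, rounding=ROUND_HALF_UP))
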