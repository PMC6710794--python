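"""Exact EUR arithmetic.

All accounting-bearing quantities are carried as :class:`decimal.Decimal`
quantized to cents, so that column sums and accounting identities hold
exactly. Composed costs are rounded to cents with banker's rounding
(ROUND_HALF_EVEN), which is what reproduces the published tariff totals;
whole-euro *display* rounding is half-up, matching how the headline
figures are printed.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_EVEN, ROUND_HALF_UP

CENT = Decimal("0.01")


def eur(value) -> Decimal:
    """Convert a number (or numeric string) to an exact Decimal EUR amount.

    Floats are converted through ``str`` so that a YAML/CSV value such as
    ``140.80`` becomes Decimal('140.8'), not the binary float expansion.
    """
    if isinstance(value, Decimal):
        return value
    return Decimal(str(value))


def cents(value) -> Decimal:
    """Quantize an amount to cents (banker's rounding)."""
    return eur(value).quantize(CENT, rounding=ROUND_HALF_EVEN)


def round_eur(value) -> int:
    """Round to whole euros for display, half away from zero (-346.20 -> -346)."""
    return int(eur(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
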