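"""Exact currency arithmetic.

All monetary amounts are held internally as euro cents: plain ``int`` where
the quantity is exact by construction, :class:`fractions.Fraction` (of cents)
where a division has occurred (amortized fixed-cost shares, per-trainee
means).  Rounding happens once, at the display boundary, and is always
half-up — the convention that reproduces a fixed cost of 132 377 split twelve
ways as 11 031 and five hundred ways as 265.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Union

#: An exact amount in euro cents.
CentAmount = Union[int, Fraction]


def round_half_up(x: Union[int, float, Fraction]) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Python's builtin ``round`` is banker's rounding; displayed currency and
    percentage figures here use the commercial half-up convention instead.
    """
    return int(math.floor(Fraction(x) + Fraction(1, 2)))


def cents(euro_amount: Union[int, str, float, Fraction]) -> int:
    """Convert a euro amount to an exact integer number of cents.

    Floats go through their decimal string form so that e.g. ``200.0`` and
    ``24.5`` convert exactly; amounts with sub-cent precision are rejected.
    """
    if isinstance(euro_amount, float):
        frac = Fraction(str(euro_amount))
    else:
        frac = Fraction(euro_amount)
    c = frac * 100
    if c.denominator != 1:
        raise ValueError(f"{euro_amount!r} is not an exact number of cents")
    return int(c)


def eur(amount_cents: CentAmount) -> int:
    """Display an exact cent amount as whole euros, rounded half-up."""
    return round_half_up(Fraction(amount_cents) / 100)


def eur_exact(amount_cents: CentAmount) -> Fraction:
    """Exact euro value of a cent amount, as a Fraction."""
    return Fraction(amount_cents) / 100
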