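"""Exact-rational helpers shared across the package.

All stoichiometry, ledgers and yields are kept as :class:`fractions.Fraction`
until the reporting boundary, where values are rounded half-up to match the
printed precision of laboratory reports (1.5151... -> 1.5).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def parse_rational(text: str | int | float | Fraction) -> Fraction:
    """Parse ``"p/q"``, plain integers, or decimal strings into a Fraction.

    Decimal strings are parsed exactly ("3.3" -> 33/10), never via binary float.
    """
    if isinstance(text, Fraction):
        return text
    if isinstance(text, int):
        return Fraction(text)
    if isinstance(text, float):
        # floats only arrive from interactive use; go through repr for sanity
        return Fraction(Decimal(repr(text)))
    s = str(text).strip()
    if "/" in s:
        num, den = s.split("/", 1)
        return Fraction(int(num.strip()), int(den.strip()))
    return Fraction(Decimal(s))


def format_rational(x: Fraction) -> str:
    """Serialize a Fraction as ``"p/q"`` (or ``"p"`` for integers)."""
    x = Fraction(x)
    if x.denominator == 1:
        return str(x.numerator)
    return f"{x.numerator}/{x.denominator}"


def round_fraction_half_up(x: Fraction, decimals: int = 1) -> float:
    """Round an exact rational half-up (away from zero) at ``decimals``.

    Done entirely in integer arithmetic so that ties like 1/20 -> 0.1 are
    decided exactly, then converted to float for display.
    """
    scale = 10**decimals
    scaled = Fraction(x) * scale
    if scaled >= 0:
        q = math.floor(scaled + Fraction(1, 2))
    else:
        q = -math.floor(-scaled + Fraction(1, 2))
    return q / scale


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round a measured (float) quantity half-up at ``decimals``."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
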