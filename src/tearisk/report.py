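"""Report-layer number formatting.

Risk tables print hazard quotients on the PERCENT scale in two-significant-
figure scientific notation ("1.7 x 10^-2").  Internally everything is a
dimensionless float at full precision; these helpers exist only at the
output boundary.

Rounding goes through ``Decimal(repr(x))`` with ROUND_HALF_UP: the repr
round-trip collapses binary noise to the shortest decimal (so a column sum
that is decimally exactly half-way, e.g. 0.0455, rounds up to 4.6e-2 the
way a desk calculation would), and half-up matches the convention of
published risk tables.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    exponent = d.adjusted()  # floor(log10(|x|))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def format_sci(x: float, sig: int = 2) -> str:
    """Two-sig-fig scientific notation, e.g. 1.671e-4 -> '1.7 x 10^-4'."""
    if x == 0:
        return "0"
    r = round_sig(x, sig)
    exponent = math.floor(math.log10(abs(r)))
    mantissa = r / 10**exponent
    # guard against 9.99.. -> 10.0 spill after the division
    if abs(mantissa) >= 10:
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.{sig - 1}f} x 10^{exponent}"


def format_hq_percent(hq_value: float, sig: int = 2) -> str:
    """Render a dimensionless HQ/HI on the percent scale.

    e.g. HQ = 1.671e-4 -> '1.7 x 10^-2' (percent).
    """
    return format_sci(hq_value * 100.0, sig)


def agrees_to_sig(computed: float, printed: float, sig: int = 2) -> bool:
    """Whether ``computed`` matches a value printed at ``sig`` significant
    figures: the difference is at most half a unit in the printed value's
    last significant digit (so exact half-way cases pass either way)."""
    if printed == 0:
        return computed == 0
    exponent = math.floor(math.log10(abs(printed)))
    half_ulp = 0.5 * 10.0 ** (exponent - sig + 1)
    return abs(computed - printed) <= half_ulp * (1 + 1e-9)
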