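"""Display rounding helpers.

Monetary values are carried unrounded (double precision) through the whole
model; rounding happens only when a report is rendered.  The rounding mode
is half-away-from-zero, the convention used in the expenditure tables this
package reproduces.  Before rounding to display precision, values are
snapped to 9 decimal places to absorb binary floating-point representation
noise (e.g. 0.765 stored as 0.76499999999999968 must still display as 0.77).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: decimals used for the noise-absorbing pre-quantisation
_SNAP = Decimal("1e-9")


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    d = Decimal(repr(float(value))).quantize(_SNAP, rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def format_amount(value: float, ndigits: int, floor: bool = True) -> str:
    """Format a monetary amount at ``ndigits`` decimals.

    Positive values too small to register at the display precision are
    shown as a floor string (``"<0.01"`` at 2 decimals, ``"<0.1"`` at 1),
    mirroring how small expenditure cells are conventionally printed.
    Exact zeros print as zero.  Set ``floor=False`` to disable.
    """
    threshold = 0.5 * 10.0 ** (-ndigits)
    if floor and 0.0 < value < threshold:
        return "<" + ("%.*f" % (ndigits, 10.0 ** (-ndigits)))
    return "%.*f" % (ndigits, round_half_away(value, ndigits))
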