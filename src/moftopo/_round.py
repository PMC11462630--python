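"""Half-up decimal rounding used for all printed-precision comparisons."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; tabulated reference
    values in this package follow the conventional half-up rule instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
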