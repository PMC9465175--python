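"""Half-up decimal rounding, applied only at report edges."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
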