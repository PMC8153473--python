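"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (report parity with printed tables).

    Python's built-in round() is banker's rounding; census/variation tables
    are printed with conventional half-up rounding.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
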