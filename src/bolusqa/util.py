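"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as clinical tables are printed.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of treatment-planning reports on exact ties
    (e.g. 0.125 -> 0.13, not 0.12).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
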