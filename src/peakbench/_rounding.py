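"""Half-up rounding, used everywhere a printed table cell is reproduced."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to *ndigits* decimals with ties going away from zero-ward up."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_int(fraction: float) -> int:
    """A fraction in [0, 1+] as an integer percentage, half-up."""
    return int(round_half_up(fraction * 100.0, 0))


def percent_ratio(numerator: int, denominator: int) -> int:
    """Integer percentage of an exact integer ratio, half-up.

    Exact at tie boundaries (e.g. 1150/2000 -> 58) where the float route
    would round down.
    """
    q = (Decimal(numerator) * 100) / Decimal(denominator)
    return int(q.quantize(Decimal(1), rounding=ROUND_HALF_UP))
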