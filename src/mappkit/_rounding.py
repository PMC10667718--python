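"""Half-up rounding helpers.

Python's builtin ``round`` is banker's rounding; the reporting conventions
here are half-up, so all percentage formatting goes through these two
functions.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, ties away from zero-half up."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_sig_half_up(value: float, sig: int = 2) -> float:
    """Round ``value`` to ``sig`` significant figures, half-up."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if value == 0:
        return 0.0
    # Decimal.adjusted() gives the exponent of the most significant digit
    # without the float-log10 edge cases at exact powers of ten.
    exponent = Decimal(repr(value)).adjusted()
    return round_half_up(value, sig - 1 - exponent)
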