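"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the survey-report convention).

    Python's built-in ``round`` uses banker's rounding, which would print
    59/116 as 50.8%; published survey tables use half-away-from-zero (50.9%).
    """
    if math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def check_proportion(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)
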