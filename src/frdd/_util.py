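"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Python's built-in ``round`` and numpy round half to even; survey reports
    conventionally round 160.8 -> 161 and 100.5 -> 101, so all reported
    figures go through this helper.
    """
    quantum = Decimal(1).scaleb(-decimals)
    # repr() gives the shortest decimal string that round-trips the float,
    # avoiding artefacts like Decimal(0.145) = 0.1449999...
    out = Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(out)


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))
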