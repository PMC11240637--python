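"""Small shared helpers: display rounding and base classification."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

UNAMBIGUOUS = frozenset("ACGT")

#: IUPAC codes (and N) treated as missing data at a position.
AMBIGUOUS = frozenset("RYSWKMBDHVN")


def round_half_up(x: float, ndigits: int) -> float:
    """Round to `ndigits` decimals with ties away from zero.

    Report tables print half-up values (0.5 -> 1 at integer precision); Python's
    built-in banker's rounding would disagree on exact ties. Full precision is
    always retained internally — this is for display and frozen comparisons only.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def is_unambiguous(base: str) -> bool:
    return base in UNAMBIGUOUS
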