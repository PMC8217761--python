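"""Half-up rounding helpers.

All monetary and display rounding in this package is round-half-up (the
convention of the reimbursement tables the inputs come from), not Python's
default banker's rounding. Internal values are never rounded; these helpers
are applied only at reporting boundaries.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "usd_to_billions"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero-ward up.

    >>> round_half_up(2.5)
    3.0
    >>> round_half_up(6172.5)
    6173.0
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def usd_to_billions(usd: float, ndigits: int = 2) -> float:
    """Convert a dollar amount to billions, rounded half-up to ``ndigits``."""
    return round_half_up(usd / 1e9, ndigits)
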