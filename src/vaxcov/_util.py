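"""Small shared helpers."""

from __future__ import annotations

import decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed survey tables).

    Python's built-in ``round`` uses banker's rounding; published coverage
    tables round 0.05 up to 0.1.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or a ready Generator; never touch global state."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
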