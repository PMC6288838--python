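"""Small shared helpers: seeded RNG plumbing and half-up rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def rng_from(seed) -> np.random.Generator:
    """Return a Generator from a seed, SeedSequence or existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Split one seed into ``n`` independent generators (splittable contract)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used for printed percentages).

    numpy/python round half to even, which would turn 0.575 -> 0.57; printed
    values in this field use the grade-school rule instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
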