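"""Shared numeric helpers: reporting-grade rounding and RNG substreams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in all printed tables.

    Python's built-in ``round`` is banker's rounding (0.25 -> 0.2); reported
    percentages instead round 0.25 -> 0.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def median_even_mean(values) -> float:
    """Median with the even-length case as the mean of the central pair."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(arr))


def substream(seed: int, *keys) -> np.random.Generator:
    """A child RNG keyed by (seed, *keys).

    Each (platform, sample) pair draws from its own substream, so adding a
    sample or platform never perturbs the draws of another.  Keys may be
    strings or ints; strings are folded through SeedSequence's entropy spawn.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(int.from_bytes(k.encode(), "little") % (2**32))
        else:
            ints.append(int(k) % (2**32))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *ints]))
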