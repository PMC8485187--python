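"""Uniform sampling of bounded integer compositions.

The simulator draws an instrument *total* first (severity bands are the
quantity of interest) and then needs item-level responses that re-score
to exactly that total.  Items are drawn uniformly over all compositions
of the total into ``k`` parts, each within ``0..cap`` — uniform by
sequential conditional sampling against an exact composition-count table.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["composition_counts", "sample_composition"]


@lru_cache(maxsize=None)
def composition_counts(k: int, cap: int) -> np.ndarray:
    """``counts[j, t]`` = number of length-``j`` sequences with parts in
    0..cap summing to ``t``, for j <= k."""
    counts = np.zeros((k + 1, k * cap + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for j in range(1, k + 1):
        for t in range(j * cap + 1):
            counts[j, t] = sum(
                counts[j - 1, t - x] for x in range(min(cap, t) + 1)
            )
    return counts


def sample_composition(total: int, k: int, cap: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Draw uniformly among all ways to write ``total`` as ``k`` parts in 0..cap."""
    if not 0 <= total <= k * cap:
        raise ValueError(f"total {total} infeasible for {k} parts capped at {cap}")
    counts = composition_counts(k, cap)
    parts = []
    rem = total
    for j in range(k, 0, -1):
        weights = [counts[j - 1, rem - x] for x in range(min(cap, rem) + 1)]
        cum = np.cumsum(weights)
        u = rng.random() * cum[-1]
        x = int(np.searchsorted(cum, u, side="right"))
        parts.append(x)
        rem -= x
    return tuple(parts)
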