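"""Independent brute-force oracles used by the property and acceptance
tests.  These deliberately avoid the library code paths they check."""

from __future__ import annotations

import numpy as np


def max_matching_cardinality(
    pred: np.ndarray, ref: np.ndarray, tolerance_s: float
) -> int:
    """Exhaustive maximum bipartite matching size under |dt| <= tolerance.

    Recursion over predictions; exponential, only for tiny instances.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    feasible = [
        [j for j in range(ref.size) if abs(pred[i] - ref[j]) <= tolerance_s + 1e-12]
        for i in range(pred.size)
    ]

    best = 0

    def recurse(i: int, used: set, count: int) -> None:
        nonlocal best
        if count + (len(feasible) - i) <= best:
            return
        if i == len(feasible):
            best = max(best, count)
            return
        recurse(i + 1, used, count)  # leave prediction i unmatched
        for j in feasible[i]:
            if j not in used:
                used.add(j)
                recurse(i + 1, used, count + 1)
                used.remove(j)

    recurse(0, set(), 0)
    return best


def brute_force_suppression(
    peaks: list[tuple[float, float]], min_gap_s: float = 0.15
) -> list[tuple[float, float]]:
    """Naive simulation of close-peak removal: repeatedly scan all pairs,
    take the closest pair with gap < min_gap_s (strict), drop its weaker
    member (ties: the later one), until none remain.

    ``peaks`` is a list of (time_s, strength).
    """
    alive = sorted(peaks)
    while True:
        offending = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                gap = abs(alive[j][0] - alive[i][0])
                if gap < min_gap_s:
                    if offending is None or gap < offending[0]:
                        offending = (gap, i, j)
        if offending is None:
            return alive
        _, i, j = offending
        a, b = alive[i], alive[j]
        drop = b if a[1] >= b[1] else a
        alive.remove(drop)
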