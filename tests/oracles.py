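"""Independent reference implementations used only to check the package.

These are deliberately naive: exhaustive enumeration for the
hypergeometric tail and a from-scratch step-up procedure for BH.  They
share no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe
    whose first K elements are 'special'.  Exact for small N."""
    special = set(range(K))
    total = comb(N, n)
    hits = sum(
        1 for subset in combinations(range(N), n)
        if len(special.intersection(subset)) >= k
    )
    return hits / total


def overlap_tail_table(K: int, n: int, N: int) -> list[float]:
    """P(overlap >= k) for k = 0..n, from one enumeration pass."""
    special = set(range(K))
    counts = [0] * (n + 1)
    for subset in combinations(range(N), n):
        counts[len(special.intersection(subset))] += 1
    total = comb(N, n)
    tails = np.cumsum(counts[::-1])[::-1] / total
    return list(tails)


def bh_stepup_reference(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up coded from the definition:
    sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1, return in the input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        value = p[idx] * m / rank
        running_min = min(running_min, value)
        adjusted_sorted[rank - 1] = min(running_min, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
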