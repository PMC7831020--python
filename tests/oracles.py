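"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the exact-test oracle
enumerates every table with the observed margins from the factorial formula,
and the labeling oracle is a plain breadth-first flood fill.
"""

from itertools import product
from math import comb, factorial

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by direct enumeration of the margin orbit."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def point_prob(aa: int) -> float:
        bb, cc = row1 - aa, col1 - aa
        dd = n - row1 - col1 + aa
        if min(bb, cc, dd) < 0:
            return 0.0
        num = (
            factorial(row1) * factorial(n - row1) * factorial(col1) * factorial(n - col1)
        )
        den = (
            factorial(aa) * factorial(bb) * factorial(cc) * factorial(dd) * factorial(n)
        )
        return num / den

    p_obs = point_prob(a)
    total = 0.0
    for aa in range(0, min(row1, col1) + 1):
        p = point_prob(aa)
        if p > 0 and p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def all_tables_up_to_n(n_max: int):
    """Every 2x2 nonnegative-integer table with 1 <= total <= n_max."""
    for a, b, c, d in product(range(n_max + 1), repeat=4):
        if 1 <= a + b + c + d <= n_max:
            yield a, b, c, d


_OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3)
        if sum(abs(x) for x in o) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3)
         if 1 <= sum(abs(x) for x in o) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3)
         if any(o)],
}


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first connected-component labeling of a binary 3-D array."""
    offsets = _OFFSETS[connectivity]
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    shape = mask.shape
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        next_label += 1
        queue = [seed]
        labels[seed] = next_label
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = next_label
                    queue.append((nx, ny, nz))
    return labels


def labelings_equivalent(l1: np.ndarray, l2: np.ndarray) -> bool:
    """Same partition of the foreground, up to label renumbering."""
    if (l1 > 0).sum() != (l2 > 0).sum() or l1.max() != l2.max():
        return False
    forward: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for v1, v2 in zip(l1[l1 > 0], l2[l1 > 0]):
        if v2 == 0:
            return False
        if forward.setdefault(v1, v2) != v2 or reverse.setdefault(v2, v1) != v1:
            return False
    return True


def exact_mannwhitney_pvalues(n1: int, n2: int):
    """Null distribution of the two-sided exact Mann-Whitney p at (n1, n2).

    Enumerates all C(n1+n2, n1) rank assignments; returns the achievable
    two-sided p-values (used to pin the smallest achievable p)."""
    from itertools import combinations

    n = n1 + n2
    total = comb(n, n1)
    u_counts: dict[int, int] = {}
    for ranks in combinations(range(n), n1):
        u = sum(ranks) - n1 * (n1 - 1) // 2
        u_counts[u] = u_counts.get(u, 0) + 1
    pvals = set()
    for u in u_counts:
        u_star = max(u, n1 * n2 - u)
        tail = sum(cnt for uu, cnt in u_counts.items()
                   if max(uu, n1 * n2 - uu) >= u_star)
        pvals.add(tail / total)
    return sorted(pvals)
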