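"""Independent brute-force references used by the tests.

The exhaustive H2' oracle enumerates every non-negative integer matrix with
the observed row and column totals to find the true minimum joint entropy;
the package's greedy packing heuristic is checked against it on small
matrices.
"""

import numpy as np


def _compositions(total, bounds):
    """All tuples of non-negative ints summing to ``total`` within ``bounds``."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    for first in range(min(total, bounds[0]) + 1):
        for rest in _compositions(total - first, bounds[1:]):
            yield (first,) + rest


def h2_prime_exhaustive(mat: np.ndarray) -> float:
    """H2' with the minimum entropy found by exhaustive enumeration.

    The maximum entropy under fixed marginals is attained by the
    independence product of marginals (a closed form); the minimum is found
    by branch-and-bound over all integer matrices with the same totals.
    Only feasible for small integer matrices.
    """
    mat = np.asarray(mat, dtype=float)
    n = mat.sum()
    p = mat / n
    r, c = p.sum(axis=1), p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h2 = ent(p.ravel())
    h2_max = ent(r) + ent(c)
    row_tot = np.rint(mat.sum(axis=1)).astype(int)
    col_tot = np.rint(mat.sum(axis=0)).astype(int)

    best = np.inf

    def rec(i, rem_cols, acc):
        nonlocal best
        if acc >= best:
            return
        if i == len(row_tot):
            best = min(best, acc)
            return
        for comp in _compositions(row_tot[i], tuple(rem_cols)):
            q = np.asarray(comp) / n
            rec(i + 1, rem_cols - np.asarray(comp), acc + ent(q))

    rec(0, col_tot.copy(), 0.0)
    h2_min = best
    if h2_max - h2_min <= 1e-12:
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))
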