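"""Independent oracles used by the test suite.

These deliberately take different algorithmic routes than the package:
recursive path enumeration instead of iterative DP, per-offset vectorized
equality instead of hash indexing, base-by-base bitmaps instead of
interval arithmetic, explicit tail enumeration instead of log-space sums.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import List, Set, Tuple

import numpy as np


def brute_global_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Best global alignment score by memoized path recursion."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = max(best, s + rec(i + 1, j + 1, "D"))
        if i < len(a):
            g = gap_extend if prev == "U" else gap_open
            best = max(best, g + rec(i + 1, j, "U"))
        if j < len(b):
            g = gap_extend if prev == "L" else gap_open
            best = max(best, g + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "")


def brute_seed_pairs(
    seq: str, k: int, lo: int, hi: int
) -> Set[Tuple[int, int]]:
    """All same-strand exact k-mer pairs with spacing in [lo, hi].

    Vectorized per-offset comparison of k-mer integer codes (quadratic
    scan over offsets, not a hash index).
    """
    n = len(seq) - k + 1
    if n <= 0:
        return set()
    codes = np.zeros(n, dtype=np.int64)
    enc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}[c] for c in seq])
    valid = np.ones(n, dtype=bool)
    code = 0
    for i in range(k):
        code = code * 5 + enc[i]
    # rolling code base 5 (N gets its own digit and never matches a valid base)
    power = 5 ** (k - 1)
    codes[0] = code
    for i in range(1, n):
        code = (code - enc[i - 1] * power) * 5 + enc[i + k - 1]
        codes[i] = code
    has_n = np.array(["N" in seq[i : i + k] for i in range(n)])
    valid &= ~has_n
    out: Set[Tuple[int, int]] = set()
    for d in range(lo, min(hi, n - 1) + 1):
        eq = (codes[:-d] == codes[d:]) & valid[:-d] & valid[d:]
        for p1 in np.nonzero(eq)[0]:
            out.add((int(p1), int(p1) + d))
    return out


def expected_ltr_mismatch(rate_r: float, age_T: float, transition_fraction: float = 0.5) -> float:
    """Closed-form expected mismatch proportion between the two LTRs.

    The per-event process (transition with prob f, each transversion with
    prob (1-f)/2) is a Kimura-type chain with transition rate a = f*r and
    per-transversion rate b = (1-f)*r/2 over a total branch of t = 2T.
    """
    t = 2.0 * age_T
    a = transition_fraction * rate_r
    b = (1.0 - transition_fraction) * rate_r / 2.0
    P = 0.25 + 0.25 * math.exp(-4.0 * b * t) - 0.5 * math.exp(-2.0 * (a + b) * t)
    Q = 0.5 - 0.5 * math.exp(-4.0 * b * t)
    return P + Q


def bitmap_union_length(intervals: List[Tuple[int, int]], size: int) -> int:
    """Base-by-base occupancy bitmap (oracle for interval unions)."""
    mask = np.zeros(size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())


def enumerate_fisher_upper(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher p by explicit enumeration of margin-fixed tables."""
    n_row1, n_col1, N = a + b, a + c, a + b + c + d

    def table_prob(x: int) -> float:
        return (
            math.comb(n_col1, x)
            * math.comb(N - n_col1, n_row1 - x)
            / math.comb(N, n_row1)
        )

    lo = max(0, n_row1 + n_col1 - N)
    hi = min(n_row1, n_col1)
    return sum(table_prob(x) for x in range(max(a, lo), hi + 1))


def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """Random additive distance matrix with its true internal splits.

    Builds a random rooted binary tree over the taxa, assigns random
    branch lengths, and returns exact path-length distances plus the
    canonical non-trivial bipartitions (side not containing taxon 0).
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    # start with each taxon as a subtree; join at random until one remains
    subtrees = [{"leaves": frozenset([t]), "depths": {t: 0.0}} for t in taxa]
    splits: Set[frozenset] = set()
    D = {t: {} for t in taxa}
    while len(subtrees) > 1:
        idx = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(idx[1])
        left = subtrees.pop(idx[0])
        ll = float(rng.uniform(0.05, 1.0))
        lr = float(rng.uniform(0.05, 1.0))
        for ta in left["leaves"]:
            for tb in right["leaves"]:
                d = left["depths"][ta] + ll + right["depths"][tb] + lr
                D[ta][tb] = D[tb][ta] = d
        merged = {
            "leaves": left["leaves"] | right["leaves"],
            "depths": {
                **{t: d + ll for t, d in left["depths"].items()},
                **{t: d + lr for t, d in right["depths"].items()},
            },
        }
        for side in (left["leaves"], right["leaves"]):
            if 1 < len(side) < n_taxa - 1:
                splits.add(side)
        subtrees.append(merged)
    mat = np.zeros((n_taxa, n_taxa))
    for i, ta in enumerate(taxa):
        for j, tb in enumerate(taxa):
            if i != j:
                mat[i, j] = D[ta][tb]
    ref = taxa[0]
    canon = set()
    for side in splits:
        if ref in side:
            side = frozenset(taxa) - side
        if 1 < len(side) < n_taxa - 1:
            canon.add(frozenset(side))
    return taxa, mat, canon
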