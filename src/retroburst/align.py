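"""Pairwise global alignment with affine gaps and deterministic tie-breaking.

This is the alignment primitive used for LTR-pair dating, consensus
building and family clustering.  The traceback prefers, on score ties,
the diagonal move, then the vertical ("up": gap in the second sequence),
then the horizontal move — so the reported alignment is stable across
runs and platforms.

Gap scoring follows the first-char convention: a gap of length L costs
``gap_open + (L - 1) * gap_extend``.

An optional ``band`` restricts the DP to ``|i - j| <= band`` which is
exact whenever the optimal alignment stays inside the band (always true
for the indel-free divergence simulated by :mod:`retroburst.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

NEG_INF = float("-inf")

# traceback pointer codes
_DIAG, _UP, _LEFT = 0, 1, 2
_FROM_M, _FROM_X, _FROM_Y = 0, 1, 2


@dataclass
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def identity(self) -> float:
        """Matches / aligned columns, gap columns included."""
        matches = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-" and x != "N"
        )
        return matches / len(self.aligned_a) if self.aligned_a else 0.0


def global_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    band: Optional[int] = None,
) -> GlobalAlignment:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps.

    ``N`` never matches anything (scored as mismatch).  Raises on empty
    input.  ``band=None`` runs the full DP.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    if band is not None:
        band = max(band, abs(n - m) + 1)

    def in_band(i: int, j: int) -> bool:
        return band is None or abs(i - j) <= band

    # three-state affine DP: M diagonal, X gap in b (consume a), Y gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # packed 3x2-bit pointers

    M[0][0] = 0.0
    for i in range(1, n + 1):
        if not in_band(i, 0):
            break
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        if not in_band(0, j):
            break
        Y[0][j] = gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = a[i - 1]
        lo = 1 if band is None else max(1, i - band)
        hi = m if band is None else min(m, i + band)
        row_m, row_x, row_y, row_p = M[i], X[i], Y[i], ptr[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(lo, hi + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != "N") else mismatch
            # M: diagonal move; source preference M > X > Y on ties
            best = prev_m[j - 1]
            src = _FROM_M
            if prev_x[j - 1] > best:
                best, src = prev_x[j - 1], _FROM_X
            if prev_y[j - 1] > best:
                best, src = prev_y[j - 1], _FROM_Y
            row_m[j] = best + s if best != NEG_INF else NEG_INF
            p = src
            # X: consume a[i-1], gap in b ("up")
            best = prev_m[j] + gap_open
            src = _FROM_M
            if prev_x[j] + gap_extend > best:
                best, src = prev_x[j] + gap_extend, _FROM_X
            if prev_y[j] + gap_open > best:
                best, src = prev_y[j] + gap_open, _FROM_Y
            row_x[j] = best
            p |= src << 2
            # Y: consume b[j-1], gap in a ("left")
            best = row_m[j - 1] + gap_open
            src = _FROM_M
            if row_x[j - 1] + gap_open > best:
                best, src = row_x[j - 1] + gap_open, _FROM_X
            if row_y[j - 1] + gap_extend > best:
                best, src = row_y[j - 1] + gap_extend, _FROM_Y
            row_y[j] = best
            p |= src << 4
            row_p[j] = p

    # final state preference: M (diagonal) > X (up) > Y
    score, state = M[n][m], _FROM_M
    if X[n][m] > score:
        score, state = X[n][m], _FROM_X
    if Y[n][m] > score:
        score, state = Y[n][m], _FROM_Y
    if score == NEG_INF:
        raise ValueError("band too narrow: no alignment found")

    out_a: list = []
    out_b: list = []
    i, j = n, m
    while i > 0 or j > 0:
        if i == 0:
            state = _FROM_Y
        elif j == 0:
            state = _FROM_X
        if state == _FROM_M:
            src = ptr[i][j] & 3
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _FROM_X:
            src = (ptr[i][j] >> 2) & 3 if j > 0 else (_FROM_M if i == 1 else _FROM_X)
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            src = (ptr[i][j] >> 4) & 3 if i > 0 else (_FROM_M if j == 1 else _FROM_Y)
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = src
    return GlobalAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


def banded_identity(a: str, b: str, band: int = 30) -> float:
    """Identity (matches / columns) of the banded global alignment."""
    return global_align(a, b, band=band).identity()
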