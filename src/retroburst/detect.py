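"""Structural detection of full-length LTR retrotransposon candidates.

Seed stage: exact same-strand k-mer pairs whose start distance falls in
the expected LTR spacing range.  Seeds on (nearly) the same diagonal are
chained and extended outward ungapped with an X-drop rule, choosing the
boundary that maximizes the cumulative +1/-2 score.  Candidates are then
filtered on LTR length, identity and (optionally) a flanking target-site
duplication, with greedy overlap resolution on ``identity * min(LTR
lengths)``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .seqio import ElementAnnotation

_EXT_MATCH = 1.0
_EXT_MISMATCH = -2.0
_EXT_XDROP = 20.0


@dataclass
class DetectorParams:
    seed_k: int = 20
    ltr_len_range: Tuple[int, int] = (100, 1500)
    ltr_start_spacing_range: Tuple[int, int] = (1000, 15000)
    min_ltr_identity: float = 0.80
    tsd_len_range: Tuple[int, int] = (4, 6)
    require_tsd: bool = False
    band_width: int = 30

    def __post_init__(self) -> None:
        if self.seed_k < 1:
            raise ValueError("seed_k must be positive")
        for name in ("ltr_len_range", "ltr_start_spacing_range", "tsd_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty")
        if not 0.0 < self.min_ltr_identity <= 1.0:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class CandidateElement:
    seq_id: str
    start: int
    end: int
    ltr5: Tuple[int, int]
    ltr3: Tuple[int, int]
    ltr_identity: float
    tsd: Optional[str] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.ltr5[0] < self.ltr5[1] <= self.ltr3[0] < self.ltr3[1] <= self.end):
            raise ValueError("LTR intervals must be ordered and inside the element")


def find_seed_pairs(
    records: Sequence[Tuple[str, str]], params: DetectorParams
) -> List[Tuple[str, int, int]]:
    """Exact same-strand k-mer match pairs with spacing in range.

    Returns ``(seq_id, pos1, pos2)`` with ``pos1 < pos2`` and
    ``pos2 - pos1`` inside ``ltr_start_spacing_range``; k-mers containing
    N never match.
    """
    k = params.seed_k
    lo, hi = params.ltr_start_spacing_range
    pairs: List[Tuple[str, int, int]] = []
    for seq_id, seq in records:
        if len(seq) < k:
            continue
        index: Dict[str, List[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append(i)
        for positions in index.values():
            if len(positions) < 2:
                continue
            for a, p1 in enumerate(positions):
                for p2 in positions[a + 1 :]:
                    d = p2 - p1
                    if d > hi:
                        break
                    if d >= lo:
                        pairs.append((seq_id, p1, p2))
    pairs.sort()
    return pairs


def _extend_chain(
    seq: str, p1_lo: int, p1_hi: int, diag: int, max_ltr: int
) -> Tuple[int, int]:
    """Ungapped X-drop extension of a repeat pair along one diagonal.

    The two copies are ``[s, e)`` and ``[s + diag, e + diag)``; returns
    the boundaries ``(s, e)`` of the first copy that maximize the
    cumulative +1/-2 score.
    """
    n = len(seq)

    def step_score(i: int) -> float:
        a, b = seq[i], seq[i + diag]
        return _EXT_MATCH if (a == b and a != "N") else _EXT_MISMATCH

    # right extension from p1_hi
    best_e, cur, best = p1_hi, 0.0, 0.0
    i = p1_hi
    limit_e = min(p1_lo + max_ltr, n - diag, p1_lo + diag)  # copies must not overlap
    while i < limit_e:
        cur += step_score(i)
        i += 1
        if cur > best:
            best, best_e = cur, i
        elif cur < best - _EXT_XDROP:
            break
    # left extension from p1_lo
    best_s, cur, best = p1_lo, 0.0, 0.0
    i = p1_lo - 1
    limit_s = max(0, best_e - max_ltr, best_e - diag)
    while i >= limit_s:
        cur += step_score(i)
        if cur > best:
            best, best_s = cur, i
        elif cur < best - _EXT_XDROP:
            break
        i -= 1
    return best_s, best_e


def extend_seed_chain(
    records: Sequence[Tuple[str, str]],
    seed_pairs: Sequence[Tuple[str, int, int]],
    params: DetectorParams,
) -> List[CandidateElement]:
    """Chain collinear seeds and extend each chain into a candidate."""
    seqs = dict(records)
    max_ltr = params.ltr_len_range[1]
    # group by sequence and diagonal (within band_width)
    by_seq: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for seq_id, p1, p2 in seed_pairs:
        by_seq[seq_id].append((p2 - p1, p1))
    candidates: List[CandidateElement] = []
    seen: set = set()
    for seq_id, items in sorted(by_seq.items()):
        items.sort()
        seq = seqs[seq_id]
        chains: List[List[Tuple[int, int]]] = []
        for d, p1 in items:
            placed = False
            for chain in chains:
                d0 = chain[0][0]
                if abs(d - d0) <= params.band_width and any(
                    abs(p1 - q1) <= max_ltr for _, q1 in chain
                ):
                    chain.append((d, p1))
                    placed = True
                    break
            if not placed:
                chains.append([(d, p1)])
        for chain in chains:
            # modal diagonal anchors the ungapped extension
            diag_counts: Dict[int, int] = defaultdict(int)
            for d, _ in chain:
                diag_counts[d] += 1
            diag = max(diag_counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            anchor = [p1 for d, p1 in chain if d == diag]
            p1_lo, p1_hi = min(anchor), max(anchor) + params.seed_k
            s, e = _extend_chain(seq, p1_lo, p1_hi, diag, max_ltr)
            if e <= s:
                continue
            ltr_len = e - s
            matches = sum(
                1 for i in range(s, e) if seq[i] == seq[i + diag] and seq[i] != "N"
            )
            identity = matches / ltr_len
            key = (seq_id, s, e, diag)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                CandidateElement(
                    seq_id=seq_id,
                    start=s,
                    end=e + diag,
                    ltr5=(s, e),
                    ltr3=(s + diag, e + diag),
                    ltr_identity=identity,
                    score=identity * ltr_len,
                )
            )
    candidates.sort(key=lambda c: (c.seq_id, c.start, c.end))
    return candidates


def detect_tsd(
    records: Sequence[Tuple[str, str]],
    candidate: CandidateElement,
    tsd_len_range: Tuple[int, int] = (4, 6),
) -> Optional[str]:
    """Longest exact 4-6 bp duplication flanking the element.

    Searches the windows immediately 5' and 3' of the element; ties are
    broken toward longer matches, then leftmost in the 5' window.
    Returns None at sequence edges or when no shared word exists.
    """
    seq = dict(records)[candidate.seq_id]
    lo, hi = tsd_len_range
    if candidate.start < lo or candidate.end > len(seq) - lo:
        return None
    left = seq[max(0, candidate.start - hi) : candidate.start]
    right = seq[candidate.end : candidate.end + hi]
    for length in range(hi, lo - 1, -1):
        for i in range(len(left) - length + 1):
            word = left[i : i + length]
            if "N" not in word and word in right:
                return word
    return None


def filter_candidates(
    candidates: Sequence[CandidateElement],
    records: Sequence[Tuple[str, str]],
    params: DetectorParams,
) -> List[CandidateElement]:
    """Apply length/identity/TSD filters and greedy overlap resolution."""
    min_len, max_len = params.ltr_len_range
    kept: List[CandidateElement] = []
    for cand in candidates:
        l5 = cand.ltr5[1] - cand.ltr5[0]
        l3 = cand.ltr3[1] - cand.ltr3[0]
        if not (min_len <= l5 <= max_len and min_len <= l3 <= max_len):
            continue
        if cand.ltr_identity < params.min_ltr_identity:
            continue
        cand.tsd = detect_tsd(records, cand, params.tsd_len_range)
        if params.require_tsd and cand.tsd is None:
            continue
        cand.score = cand.ltr_identity * min(l5, l3)
        kept.append(cand)
    # greedy selection by score, dropping overlaps with better candidates
    kept.sort(key=lambda c: (-c.score, c.seq_id, c.start))
    selected: List[CandidateElement] = []
    for cand in kept:
        overlap = any(
            s.seq_id == cand.seq_id and s.start < cand.end and cand.start < s.end
            for s in selected
        )
        if not overlap:
            selected.append(cand)
    selected.sort(key=lambda c: (c.seq_id, c.start, c.end))
    return selected


def detect_elements(
    records: Sequence[Tuple[str, str]], params: Optional[DetectorParams] = None
) -> List[CandidateElement]:
    """Full detection pipeline: seed, chain+extend, filter."""
    if params is None:
        params = DetectorParams()
    seeds = find_seed_pairs(records, params)
    candidates = extend_seed_chain(records, seeds, params)
    return filter_candidates(candidates, records, params)


def candidates_to_annotations(
    candidates: Sequence[CandidateElement],
) -> List[ElementAnnotation]:
    out = []
    for i, c in enumerate(candidates):
        out.append(
            ElementAnnotation(
                element_id=f"cand_{i:04d}",
                seq_id=c.seq_id,
                start=c.start,
                end=c.end,
                ltr5=c.ltr5,
                ltr3=c.ltr3,
                attributes={
                    "Identity": f"{c.ltr_identity:.4f}",
                    "TSD": c.tsd or ".",
                },
            )
        )
    return out
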