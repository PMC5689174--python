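"""Family clustering, consensus building, copy annotation and census.

Detected elements are clustered into families by single-linkage on
pairwise identity (80/80 convention: >= 0.80 identity over >= 0.80 mutual
length coverage), each family is summarized by a majority-rule consensus,
and the consensus library is mapped back onto the genome with a
seed-and-extend scan on both strands.  Quantification reports, per family
and in aggregate, copy counts, full-length copy counts (annotation
covering >= 95% of its consensus) and percent genome coverage computed on
interval unions (never double-counted).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .seqio import ElementAnnotation

FULL_COPY_FRACTION = 0.95


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="global")
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def _pair_alignment_rows(a: str, b: str) -> Tuple[str, str]:
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _pair_identity(a: str, b: str) -> float:
    """Matches / aligned columns (gap columns included) of the optimal
    global alignment."""
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def _kmer_identity_bound(a: str, b: str, k: int = 8, threshold: float = 0.08) -> bool:
    """Cheap prefilter: True when the pair could plausibly reach ~0.8
    identity (shared k-mer fraction above threshold)."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return False
    return len(ka & kb) / min(len(ka), len(kb)) >= threshold


@dataclass
class Family:
    family_id: str
    members: List[ElementAnnotation]
    consensus: str = ""
    classification: str = "LTR"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family needs at least one member")


@dataclass
class CopyAnnotation:
    seq_id: str
    start: int
    end: int
    family_id: str
    identity: float
    fraction_of_consensus: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_of_consensus <= 1.0:
            raise ValueError("fraction_of_consensus must be in (0, 1]")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class FamilyQuantification:
    label: str
    n_families: int
    n_copies: int
    n_full_copies: int
    coverage_percent: float

    def __post_init__(self) -> None:
        if self.n_full_copies > self.n_copies:
            raise ValueError("full copies cannot exceed copies")
        if not 0.0 <= self.coverage_percent <= 100.0:
            raise ValueError("coverage_percent out of range")


# ---------------------------------------------------------------------------
# Clustering


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _element_seq(records: Dict[str, str], el: ElementAnnotation) -> str:
    return records[el.seq_id][el.start : el.end]


def cluster_copies(
    elements: Sequence[ElementAnnotation],
    records: Sequence[Tuple[str, str]],
    min_identity: float = 0.80,
    min_mutual_coverage: float = 0.80,
) -> List[Family]:
    """Single-linkage clustering of elements into families.

    Two elements are linked when the shorter is >= ``min_mutual_coverage``
    of the longer and their banded global identity is >= ``min_identity``.
    Families are numbered by the genome position of their leftmost member.
    """
    if not elements:
        raise ValueError("no elements to cluster")
    seqs = dict(records)
    ordered = sorted(elements, key=lambda e: (e.seq_id, e.start, e.end))
    texts = [_element_seq(seqs, el) for el in ordered]
    uf = _UnionFind(len(ordered))
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            li, lj = len(texts[i]), len(texts[j])
            if min(li, lj) / max(li, lj) < min_mutual_coverage:
                continue
            if uf.find(i) == uf.find(j):
                continue
            if not _kmer_identity_bound(texts[i], texts[j]):
                continue
            if _pair_identity(texts[i], texts[j]) >= min_identity:
                uf.union(i, j)
    groups: Dict[int, List[ElementAnnotation]] = defaultdict(list)
    for i, el in enumerate(ordered):
        groups[uf.find(i)].append(el)
    families = []
    for n, root in enumerate(sorted(groups, key=lambda r: (ordered[r].seq_id, ordered[r].start))):
        families.append(Family(family_id=f"FAM_{n + 1:03d}", members=groups[root]))
    return families


# ---------------------------------------------------------------------------
# Consensus


def build_consensus(
    family: Family, records: Sequence[Tuple[str, str]]
) -> str:
    """Majority-rule consensus from a star alignment to the longest member.

    Per-column ties resolve to the longest member's base; columns where
    the majority votes a gap are dropped, so the output carries no gaps.
    """
    seqs = dict(records)
    texts = [_element_seq(seqs, el) for el in family.members]
    anchor = max(texts, key=len)
    if len(texts) == 1:
        return anchor
    # votes[i][base]: bases aligned to anchor position i across members
    votes: List[Dict[str, int]] = [defaultdict(int) for _ in anchor]
    for ch, tally in zip(anchor, votes):
        tally[ch] += 1
    for text in texts:
        if text is anchor:
            continue
        row_a, row_b = _pair_alignment_rows(anchor, text)
        pos = -1
        for a, b in zip(row_a, row_b):
            if a != "-":
                pos += 1
                votes[pos][b] += 1
            # insertions relative to the anchor are ignored
    out: List[str] = []
    for ch, tally in zip(anchor, votes):
        best = max(tally.values())
        winners = sorted(b for b, c in tally.items() if c == best)
        pick = ch if ch in winners else winners[0]
        if pick != "-":
            out.append(pick)
    return "".join(out)


def build_family_library(
    families: Sequence[Family], records: Sequence[Tuple[str, str]]
) -> List[Family]:
    for fam in families:
        fam.consensus = build_consensus(fam, records)
    return list(families)


# ---------------------------------------------------------------------------
# Copy annotation (seed-and-extend of consensus against the genome)

_SEED_K = 13
_CHAIN_BAND = 40
_CHAIN_MAX_GAP = 600


def _seed_hits(seq: str, consensus: str, k: int) -> List[Tuple[int, int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(consensus) - k + 1):
        kmer = consensus[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    hits = []
    for g in range(len(seq) - k + 1):
        kmer = seq[g : g + k]
        for c in index.get(kmer, ()):
            hits.append((g, c))
    return hits


def _chain_hits(hits: List[Tuple[int, int]], k: int) -> List[Tuple[int, int, int, int]]:
    """Group (genome_pos, cons_pos) hits into collinear chains.

    Returns ``(g_start, g_end, c_start, c_end)`` per chain.
    """
    chains: List[List[Tuple[int, int]]] = []
    hits = sorted(hits, key=lambda h: (h[0] - h[1], h[0]))
    for g, c in hits:
        placed = False
        for chain in chains:
            g0, c0 = chain[-1]
            if abs((g - c) - (g0 - c0)) <= _CHAIN_BAND and abs(g - g0) <= _CHAIN_MAX_GAP:
                chain.append((g, c))
                placed = True
                break
        if not placed:
            chains.append([(g, c)])
    out = []
    for chain in chains:
        gs = [g for g, _ in chain]
        cs = [c for _, c in chain]
        out.append((min(gs), max(gs) + k, min(cs), max(cs) + k))
    return out


def _extend_ends(
    seq: str, consensus: str, g_start: int, g_end: int, c_start: int, c_end: int
) -> Tuple[int, int, int, int]:
    """Ungapped X-drop extension of a chain toward the consensus ends."""
    best, cur = 0.0, 0.0
    g, c = g_start - 1, c_start - 1
    bg, bc = g_start, c_start
    while g >= 0 and c >= 0:
        cur += 1.0 if seq[g] == consensus[c] != "N" else -2.0
        if cur > best:
            best, bg, bc = cur, g, c
        elif cur < best - 12.0:
            break
        g, c = g - 1, c - 1
    g_start, c_start = bg, bc
    best, cur = 0.0, 0.0
    g, c = g_end, c_end
    bg, bc = g_end, c_end
    while g < len(seq) and c < len(consensus):
        cur += 1.0 if seq[g] == consensus[c] != "N" else -2.0
        g, c = g + 1, c + 1
        if cur > best:
            best, bg, bc = cur, g, c
        elif cur < best - 12.0:
            break
    return g_start, bg, c_start, bc


def annotate_copies(
    records: Sequence[Tuple[str, str]],
    library: Sequence[Family],
    min_identity: float = 0.80,
    min_hit_len: int = 80,
) -> List[CopyAnnotation]:
    """Map every family consensus onto both strands of the genome.

    Overlapping hits of one family on one sequence are merged into a
    single copy; ``fraction_of_consensus`` is the union of the consensus
    spans covered by the merged hits (capped at 1).
    """
    if not library:
        raise ValueError("empty consensus library")
    annotations: List[CopyAnnotation] = []
    for seq_id, seq in records:
        for fam in library:
            cons = fam.consensus
            if not cons:
                raise ValueError(f"family {fam.family_id} has no consensus")
            raw: List[Tuple[int, int, int, int, float]] = []
            for strand, oriented in ((1, cons), (-1, str(Seq(cons).reverse_complement()))):
                for g_s, g_e, c_s, c_e in _chain_hits(_seed_hits(seq, oriented, _SEED_K), _SEED_K):
                    g_s, g_e, c_s, c_e = _extend_ends(seq, oriented, g_s, g_e, c_s, c_e)
                    if g_e - g_s < min_hit_len:
                        continue
                    identity = _pair_identity(seq[g_s:g_e], oriented[c_s:c_e])
                    if identity < min_identity:
                        continue
                    if strand < 0:  # map consensus span back to forward coordinates
                        c_s, c_e = len(cons) - c_e, len(cons) - c_s
                    raw.append((g_s, g_e, c_s, c_e, identity))
            # merge genome-overlapping hits of this family
            raw.sort()
            merged: List[List] = []
            for g_s, g_e, c_s, c_e, ident in raw:
                if merged and g_s <= merged[-1][1]:
                    m = merged[-1]
                    w_old, w_new = m[1] - m[0], g_e - g_s
                    m[1] = max(m[1], g_e)
                    m[2].append((c_s, c_e))
                    m[3] = (m[3] * w_old + ident * w_new) / (w_old + w_new)
                else:
                    merged.append([g_s, g_e, [(c_s, c_e)], ident])
            for g_s, g_e, spans, ident in merged:
                covered = interval_union_length(spans)
                annotations.append(
                    CopyAnnotation(
                        seq_id=seq_id,
                        start=g_s,
                        end=g_e,
                        family_id=fam.family_id,
                        identity=min(1.0, ident),
                        fraction_of_consensus=min(1.0, covered / len(cons)),
                    )
                )
    annotations = _resolve_cross_family_overlaps(annotations)
    annotations.sort(key=lambda a: (a.seq_id, a.start, a.family_id))
    return annotations


def _resolve_cross_family_overlaps(
    annotations: List[CopyAnnotation],
) -> List[CopyAnnotation]:
    """Keep the best-scoring annotation where different families overlap.

    A copy is dropped when more than half of it lies under a
    higher-scoring annotation of another family (the short homologous
    fragments that shared domains produce between related families).
    """

    def score(a: CopyAnnotation) -> float:
        return a.identity * (a.end - a.start)

    kept: List[CopyAnnotation] = []
    for cand in sorted(annotations, key=lambda a: (-score(a), a.seq_id, a.start)):
        shadowed = False
        for k in kept:
            if k.seq_id != cand.seq_id or k.family_id == cand.family_id:
                continue
            overlap = min(k.end, cand.end) - max(k.start, cand.start)
            if overlap > 0.5 * (cand.end - cand.start):
                shadowed = True
                break
        if not shadowed:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Quantification


def interval_union_length(intervals: Sequence[Tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def quantify(
    copies: Sequence[CopyAnnotation],
    families: Sequence[Family],
    records: Sequence[Tuple[str, str]],
    full_copy_fraction: float = FULL_COPY_FRACTION,
) -> List[FamilyQuantification]:
    """Per-family census rows plus per-classification and TOTAL rows.

    Coverage is ``100 * |union of annotated intervals| / genome length``;
    aggregate rows use the union over their member families' intervals,
    so overlaps are never double-counted.
    """
    genome_len = sum(len(s) for _, s in records)
    by_family: Dict[str, List[CopyAnnotation]] = defaultdict(list)
    for c in copies:
        by_family[c.family_id].append(c)
    rows: List[FamilyQuantification] = []
    class_of = {f.family_id: f.classification for f in families}

    def make_row(label: str, fam_ids: List[str], n_families: int) -> FamilyQuantification:
        anns = [a for fid in fam_ids for a in by_family.get(fid, [])]
        ivs = [(a.seq_id, a.start, a.end) for a in anns]
        union = 0
        for sid in {s for s, _, _ in ivs}:
            union += interval_union_length([(s, e) for q, s, e in ivs if q == sid])
        return FamilyQuantification(
            label=label,
            n_families=n_families,
            n_copies=len(anns),
            n_full_copies=sum(1 for a in anns if a.fraction_of_consensus >= full_copy_fraction),
            coverage_percent=100.0 * union / genome_len if genome_len else 0.0,
        )

    for fam in sorted(families, key=lambda f: f.family_id):
        rows.append(make_row(fam.family_id, [fam.family_id], 1))
    by_class: Dict[str, List[str]] = defaultdict(list)
    for fam in families:
        by_class[fam.classification].append(fam.family_id)
    for label in sorted(by_class):
        rows.append(make_row(label, by_class[label], len(by_class[label])))
    rows.append(make_row("TOTAL", [f.family_id for f in families], len(families)))
    return rows


def run_census(
    records: Sequence[Tuple[str, str]],
    elements: Sequence[ElementAnnotation],
    min_identity: float = 0.80,
    min_mutual_coverage: float = 0.80,
    two_pass: bool = True,
) -> Tuple[List[Family], List[CopyAnnotation], List[FamilyQuantification]]:
    """Cluster -> consensus -> annotate (optionally two-pass) -> census.

    The second pass re-annotates with only those families that retained at
    least one full-length copy in the first pass.
    """
    families = cluster_copies(elements, records, min_identity, min_mutual_coverage)
    # propagate element classification labels to families (majority)
    for fam in families:
        labels = [
            "LTR/" + m.attributes["Superfamily"]
            for m in fam.members
            if m.attributes.get("Superfamily") not in (None, "unknown")
        ]
        if labels:
            fam.classification = max(sorted(set(labels)), key=labels.count)
    build_family_library(families, records)
    copies = annotate_copies(records, families, min_identity)
    if two_pass:
        with_full = {
            c.family_id for c in copies if c.fraction_of_consensus >= FULL_COPY_FRACTION
        }
        retained = [f for f in families if f.family_id in with_full]
        if retained and len(retained) < len(families):
            families = retained
            copies = annotate_copies(records, families, min_identity)
    return families, copies, quantify(copies, families, records)
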