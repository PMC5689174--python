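"""Reverse-transcriptase phylogeny: extract, align, NJ, bootstrap, root.

RT peptides are pulled from the best reverse-transcriptase domain hit of
each taxon, aligned progressively (k-mer guide tree, profile-profile
global alignment), converted to Poisson-corrected distances and fed to a
canonical Saitou-Nei neighbor-joining with nonparametric bootstrap
support.  Internal node naming is derived from sorted leaf sets, so the
topology and all tie-breaks are invariant to input taxon order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .classify import DomainHit

_B62 = substitution_matrices.load("BLOSUM62")
_GAP_OPEN = -11.0
_GAP_EXTEND = -1.0


class SaturatedPairError(ValueError):
    """A pairwise distance is undefined (p >= 1); remove the taxon."""


# ---------------------------------------------------------------------------
# Extraction


def extract_rt_peptides(
    sequences: Dict[str, str],
    hits: Dict[str, Sequence[DomainHit]],
) -> Dict[str, str]:
    """Translate the best RT hit of each taxon on its coding strand.

    Taxa without an RT hit are skipped (the caller decides whether that
    is an error).  Stop codons are retained as ``*``.
    """
    peptides: Dict[str, str] = {}
    for taxon in sorted(sequences):
        rt = [h for h in hits.get(taxon, []) if h.domain == "RT"]
        if not rt:
            continue
        best = max(rt, key=lambda h: h.score)
        seq = sequences[taxon]
        sub = seq[best.start : best.end]
        if best.frame < 0:
            sub = str(Seq(sub).reverse_complement())
        sub = sub[: len(sub) - len(sub) % 3]
        peptides[taxon] = str(Seq(sub).translate())
    return peptides


# ---------------------------------------------------------------------------
# Progressive alignment


@dataclass
class PeptideAlignment:
    rows: List[Tuple[str, str]]  # (taxon_id, aligned peptide)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def taxa(self) -> List[str]:
        return [t for t, _ in self.rows]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _pair_score(ca: str, cb: str) -> float:
    if ca == "-" or cb == "-":
        return 0.0
    try:
        return float(_B62[ca, cb])
    except (KeyError, IndexError):
        return 0.0


def _profile_cols(rows: List[str]) -> List[List[str]]:
    return [[row[j] for row in rows] for j in range(len(rows[0]))]


def _col_score(col_a: List[str], col_b: List[str]) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            total += _pair_score(x, y)
    return total / (len(col_a) * len(col_b))


def _align_profiles(rows_a: List[str], rows_b: List[str]) -> Tuple[List[str], List[str]]:
    """Affine-gap global alignment of two alignment profiles."""
    A, B = _profile_cols(rows_a), _profile_cols(rows_b)
    n, m = len(A), len(B)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = _GAP_OPEN + (i - 1) * _GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = _GAP_OPEN + (j - 1) * _GAP_EXTEND
    for i in range(1, n + 1):
        col_a = A[i - 1]
        for j in range(1, m + 1):
            s = _col_score(col_a, B[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + _GAP_OPEN, X[i - 1][j] + _GAP_EXTEND,
                          Y[i - 1][j] + _GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] + _GAP_OPEN, X[i][j - 1] + _GAP_OPEN,
                          Y[i][j - 1] + _GAP_EXTEND)
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = n, m
    state = max(((M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")), key=lambda t: t[0])[1]
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            prev = max(
                ((M[i - 1][j - 1], "M"), (X[i - 1][j - 1], "X"), (Y[i - 1][j - 1], "Y")),
                key=lambda t: t[0],
            )[1]
            out_a.append("A")
            out_b.append("B")
            i, j = i - 1, j - 1
        elif state == "X":
            cands = [(M[i - 1][j] + _GAP_OPEN, "M"), (X[i - 1][j] + _GAP_EXTEND, "X"),
                     (Y[i - 1][j] + _GAP_OPEN, "Y")]
            prev = max(cands, key=lambda t: t[0])[1]
            out_a.append("A")
            out_b.append("-")
            i -= 1
        else:
            cands = [(M[i][j - 1] + _GAP_OPEN, "M"), (X[i][j - 1] + _GAP_OPEN, "X"),
                     (Y[i][j - 1] + _GAP_EXTEND, "Y")]
            prev = max(cands, key=lambda t: t[0])[1]
            out_a.append("-")
            out_b.append("B")
            j -= 1
        state = prev
    ops_a = "".join(reversed(out_a))
    ops_b = "".join(reversed(out_b))
    new_a: List[str] = []
    new_b: List[str] = []
    for row in rows_a:
        it = iter(row)
        new_a.append("".join(next(it) if op == "A" else "-" for op in ops_a))
    for row in rows_b:
        it = iter(row)
        new_b.append("".join(next(it) if op == "B" else "-" for op in ops_b))
    return new_a, new_b


def align_peptides(peptides: Dict[str, str], trim_gap_fraction: float = 0.5) -> PeptideAlignment:
    """Progressive multiple alignment with a UPGMA k-mer guide tree.

    Columns with more than ``trim_gap_fraction`` gaps are removed.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 sequences to align")
    taxa = sorted(peptides)
    # UPGMA on k-mer distances drives the merge order
    clusters: Dict[int, List[str]] = {i: [t] for i, t in enumerate(taxa)}
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            dist[(i, j)] = _kmer_distance(peptides[taxa[i]], peptides[taxa[j]])
    profiles: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([t], [peptides[t]]) for i, t in enumerate(taxa)
    }
    next_id = len(taxa)
    while len(profiles) > 1:
        (i, j), _ = min(
            ((key, d) for key, d in dist.items() if key[0] in profiles and key[1] in profiles),
            key=lambda kv: (kv[1], kv[0]),
        )
        names_i, rows_i = profiles.pop(i)
        names_j, rows_j = profiles.pop(j)
        new_i, new_j = _align_profiles(rows_i, rows_j)
        merged = (names_i + names_j, new_i + new_j)
        size_i, size_j = len(clusters[i]), len(clusters[j])
        clusters[next_id] = clusters[i] + clusters[j]
        for k in list(profiles):
            d_ik = dist.get((min(i, k), max(i, k)), 0.0)
            d_jk = dist.get((min(j, k), max(j, k)), 0.0)
            dist[(min(next_id, k), max(next_id, k))] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        profiles[next_id] = merged
        next_id += 1
    names, rows = profiles.popitem()[1]
    # restore canonical taxon order and trim gappy columns
    order = {t: i for i, t in enumerate(taxa)}
    paired = sorted(zip(names, rows), key=lambda nr: order[nr[0]])
    ncols = len(rows[0])
    keep = [
        j
        for j in range(ncols)
        if sum(r[j] == "-" for _, r in paired) <= trim_gap_fraction * len(paired)
    ]
    trimmed = [(t, "".join(r[j] for j in keep)) for t, r in paired]
    return PeptideAlignment(rows=trimmed)


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(aln: PeptideAlignment) -> Tuple[List[str], np.ndarray]:
    """Poisson-corrected p-distances over mutually ungapped columns.

    Saturated pairs (p >= 1 or no shared columns) get ``inf``.
    """
    if len(aln.rows) < 3:
        raise ValueError("need at least 3 taxa for a distance matrix")
    taxa = aln.taxa
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i][1], aln.rows[j][1]
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                d = math.inf
            else:
                p = sum(1 for x, y in shared if x != y) / len(shared)
                d = math.inf if p >= 1.0 else -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return taxa, D


def p_distance_matrix(aln: PeptideAlignment) -> Tuple[List[str], np.ndarray]:
    """Uncorrected p-distance alternative (config-exposed)."""
    taxa, D = distance_matrix(aln)
    return taxa, 1.0 - np.exp(-D)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class PhyloTree:
    """Unrooted-or-rooted tree as an undirected adjacency with lengths."""

    adjacency: Dict[str, List[Tuple[str, float]]]
    leaves: Set[str]
    root: Optional[str] = None
    supports: Dict[FrozenSet[str], float] = field(default_factory=dict)

    def neighbors(self, node: str) -> List[Tuple[str, float]]:
        return self.adjacency[node]

    def _side_leaves(self, node: str, parent: str) -> Set[str]:
        out: Set[str] = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if cur in self.leaves:
                out.add(cur)
            for nbr, _ in self.adjacency[cur]:
                if nbr != par:
                    stack.append((nbr, cur))
        return out

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Canonical non-trivial bipartitions (side without the min leaf)."""
        ref = min(self.leaves)
        out: Set[FrozenSet[str]] = set()
        seen_edges = set()
        for u in self.adjacency:
            for v, _ in self.adjacency[u]:
                edge = frozenset((u, v))
                if edge in seen_edges:
                    continue
                seen_edges.add(edge)
                side = self._side_leaves(v, u)
                if ref in side:
                    side = self.leaves - side
                if 1 < len(side) < len(self.leaves) - 1:
                    out.add(frozenset(side))
        return out

    def newick(self) -> str:
        start = self.root
        if start is None:
            start = next(n for n in sorted(self.adjacency) if n not in self.leaves)
        ref = min(self.leaves)

        def fmt(node: str, parent: Optional[str], length: Optional[float]) -> str:
            children = [(n, l) for n, l in self.adjacency[node] if n != parent]
            if not children:
                label = node
            else:
                inner = ",".join(fmt(n, node, l) for n, l in sorted(children))
                label = f"({inner})"
                if parent is not None and self.supports:
                    side = self._side_leaves(node, parent)
                    if ref in side:
                        side = self.leaves - side
                    sup = self.supports.get(frozenset(side))
                    if sup is not None:
                        label += f"{sup:.3f}"
            if length is not None:
                label += f":{length:.6g}"
            return label

        return fmt(start, None, None) + ";"


def nj_tree(taxa: Sequence[str], D: np.ndarray) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei Q-criterion).

    Deterministic: ties in Q break on the sorted pair of node names, and
    internal nodes are named from the sorted leaf set they subtend.
    Negative branch lengths are clamped to zero.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(D)):
        bad = [
            (taxa[i], taxa[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not math.isfinite(D[i, j])
        ]
        raise SaturatedPairError(
            f"saturated pairwise distances {bad[:3]}; remove one of each pair"
        )
    nodes: List[str] = list(taxa)
    leafset: Dict[str, Tuple[str, ...]] = {t: (t,) for t in taxa}
    dist: Dict[FrozenSet[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((taxa[i], taxa[j]))] = float(D[i, j])
    adjacency: Dict[str, List[Tuple[str, float]]] = {t: [] for t in taxa}

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(nodes) > 3:
        m = len(nodes)
        r = {a: sum(d(a, b) for b in nodes if b != a) for a in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        new_leaves = tuple(sorted(leafset[a] + leafset[b]))
        new = "|".join(new_leaves)
        leafset[new] = new_leaves
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        adjacency[new] = []
        adjacency[new].append((a, la))
        adjacency[new].append((b, lb))
        adjacency[a].append((new, la))
        adjacency[b].append((new, lb))
        for c in nodes:
            if c in (a, b):
                continue
            dist[frozenset((new, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        nodes = [c for c in nodes if c not in (a, b)]
        nodes.append(new)
        nodes.sort()
    # join the last three nodes on a central vertex
    a, b, c = sorted(nodes)
    center = "|".join(sorted(leafset[a] + leafset[b] + leafset[c])) + "|*"
    adjacency[center] = []
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = max(0.5 * (d(x, y) + d(x, z) - d(y, z)), 0.0)
        adjacency[center].append((x, lx))
        adjacency[x].append((center, lx))
    return PhyloTree(adjacency=adjacency, leaves=set(taxa))


def bootstrap_support(
    aln: PeptideAlignment, n_replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap bipartition supports."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    taxa, D = distance_matrix(aln)
    tree = nj_tree(taxa, D)
    counts: Dict[FrozenSet[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ncols = aln.n_columns
    n_ok = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, ncols, size=ncols)
        rep = PeptideAlignment(
            rows=[(t, "".join(s[i] for i in idx)) for t, s in aln.rows]
        )
        try:
            rep_taxa, rep_D = distance_matrix(rep)
            rep_tree = nj_tree(rep_taxa, rep_D)
        except (SaturatedPairError, ValueError):
            continue
        n_ok += 1
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if n_ok == 0:
        raise SaturatedPairError("all bootstrap replicates were saturated")
    tree.supports = {bp: c / n_ok for bp, c in counts.items()}
    return tree


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge (idempotent)."""
    if outgroup not in tree.leaves:
        raise ValueError(f"unknown outgroup taxon {outgroup!r}")
    adjacency = {k: list(v) for k, v in tree.adjacency.items()}
    if tree.root is not None and any(n == outgroup for n, _ in adjacency.get(tree.root, [])):
        return PhyloTree(adjacency, set(tree.leaves), tree.root, dict(tree.supports))
    (nbr, length) = adjacency[outgroup][0]
    root = "__root__"
    adjacency[outgroup] = [(root, length / 2.0)]
    adjacency[nbr] = [(n, l) for n, l in adjacency[nbr] if n != outgroup]
    adjacency[nbr].append((root, length / 2.0))
    adjacency[root] = [(outgroup, length / 2.0), (nbr, length / 2.0)]
    return PhyloTree(adjacency, set(tree.leaves), root, dict(tree.supports))
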