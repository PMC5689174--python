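"""Internal-domain detection and Gypsy/Copia classification.

Candidate elements are translated in all six frames and scanned against a
small bundled peptide library (one canonical reference per domain) with
local alignment under BLOSUM62.  Classification uses domain order on the
coding strand: reverse transcriptase before integrase means Gypsy,
integrase before reverse transcriptase means Copia; a chromodomain hit
downstream of the integrase flags the Chromoviridae lineage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import ElementAnnotation, read_fasta

CORE_DOMAINS = ("GAG", "AP", "RT", "RH", "INT", "CHROMO")

GYPSY_ORDER = ("GAG", "AP", "RT", "RH", "INT")
COPIA_ORDER = ("GAG", "AP", "INT", "RT", "RH")


@dataclass
class DomainLibrary:
    """Reference peptides and score thresholds for the domain scan."""

    entries: List[Tuple[str, str, str]]  # (domain_name, ref_id, peptide)
    min_score: Dict[str, float]
    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty domain library")
        present = {d for d, _, _ in self.entries}
        missing = {"AP", "RT", "INT"} - present
        if missing:
            raise ValueError(f"library lacks core domains: {sorted(missing)}")

    def references(self, domain: str) -> List[Tuple[str, str]]:
        return [(rid, pep) for d, rid, pep in self.entries if d == domain]

    @property
    def domains(self) -> List[str]:
        seen: List[str] = []
        for d, _, _ in self.entries:
            if d not in seen:
                seen.append(d)
        return seen


@dataclass
class DomainHit:
    domain: str
    frame: int  # +1..+3, -1..-3
    start: int  # nucleotide interval on the element, 0-based half-open
    end: int
    score: float
    identity: float

    @property
    def strand(self) -> int:
        return 1 if self.frame > 0 else -1


@dataclass
class Classification:
    superfamily: str  # Gypsy | Copia | unknown
    chromoviridae: bool
    evidence: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chromoviridae and self.superfamily != "Gypsy":
            raise ValueError("chromoviridae flag requires Gypsy superfamily")


def load_default_library() -> DomainLibrary:
    """Load the bundled reference peptides and calibrated thresholds."""
    data = importlib.resources.files("retroburst") / "data"
    peptides = read_fasta(str(data / "domain_library.fasta"))
    sheet = yaml.safe_load((data / "domain_thresholds.yaml").read_text())
    entries = []
    for rid, pep in peptides:
        domain = rid.split("_")[0]
        entries.append((domain, rid, pep))
    return DomainLibrary(
        entries=entries,
        min_score={k: float(v) for k, v in sheet["min_score"].items()},
        matrix_name=sheet.get("matrix", "BLOSUM62"),
        gap_open=float(sheet.get("gap_open", -11)),
        gap_extend=float(sheet.get("gap_extend", -1)),
    )


def six_frame_translate(seq: str) -> Dict[int, str]:
    """Translate ``seq`` in all six frames; stops rendered as ``*``."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    frames: Dict[int, str] = {}
    for f in (1, 2, 3):
        for strand, s in ((1, seq), (-1, rc)):
            sub = s[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[strand * f] = str(Seq(sub).translate()) if sub else ""
    return frames


def _make_aligner(library: DomainLibrary) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(library.matrix_name)
    aligner.open_gap_score = library.gap_open
    aligner.extend_gap_score = library.gap_extend
    return aligner


def _peptide_to_nt(frame: int, pep_start: int, pep_end: int, seq_len: int) -> Tuple[int, int]:
    f = abs(frame)
    if frame > 0:
        return (f - 1) + 3 * pep_start, (f - 1) + 3 * pep_end
    # coordinates were on the reverse complement
    rc_start, rc_end = (f - 1) + 3 * pep_start, (f - 1) + 3 * pep_end
    return seq_len - rc_end, seq_len - rc_start


def scan_domains(element_seq: str, library: DomainLibrary) -> List[DomainHit]:
    """Scan all six frames against every library reference.

    Overlapping hits for the same domain are collapsed to the best score;
    hits below the domain's ``min_score`` are dropped.
    """
    aligner = _make_aligner(library)
    frames = six_frame_translate(element_seq)
    hits: List[DomainHit] = []
    for domain in library.domains:
        threshold = library.min_score.get(domain, 0.0)
        domain_hits: List[DomainHit] = []
        for rid, ref in library.references(domain):
            for frame, pep in frames.items():
                if not pep:
                    continue
                score = aligner.score(ref, pep)
                if score < threshold:
                    continue
                aln = aligner.align(ref, pep)[0]
                ref_blocks, qry_blocks = aln.aligned
                pep_start = int(qry_blocks[0][0])
                pep_end = int(qry_blocks[-1][1])
                matches = sum(
                    1
                    for rb, qb in zip(ref_blocks, qry_blocks)
                    for k in range(rb[1] - rb[0])
                    if ref[rb[0] + k] == pep[qb[0] + k]
                )
                cols = aln.length
                nt_start, nt_end = _peptide_to_nt(frame, pep_start, pep_end, len(element_seq))
                domain_hits.append(
                    DomainHit(
                        domain=domain,
                        frame=frame,
                        start=nt_start,
                        end=nt_end,
                        score=float(score),
                        identity=matches / cols if cols else 0.0,
                    )
                )
        hits.extend(_collapse_overlaps(domain_hits))
    hits.sort(key=lambda h: (h.start, h.domain))
    return hits


def _collapse_overlaps(hits: List[DomainHit]) -> List[DomainHit]:
    kept: List[DomainHit] = []
    for hit in sorted(hits, key=lambda h: -h.score):
        if all(hit.end <= k.start or hit.start >= k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def classify_element(hits: Sequence[DomainHit]) -> Classification:
    """Classify one element from its domain hits.

    The coding strand is the strand of the best RT hit (best total score
    if RT is absent); ordering on the minus strand reverses genomic
    coordinates.  Requires both RT and INT for a superfamily call.
    """
    if not hits:
        return Classification("unknown", False, [])
    rt_hits = [h for h in hits if h.domain == "RT"]
    if rt_hits:
        strand = max(rt_hits, key=lambda h: h.score).strand
    else:
        plus = sum(h.score for h in hits if h.strand > 0)
        minus = sum(h.score for h in hits if h.strand < 0)
        strand = 1 if plus >= minus else -1
    coding = [h for h in hits if h.strand == strand]
    # coding-strand order: genomic start on +, reversed on -
    coding.sort(key=lambda h: h.start if strand > 0 else -h.end)
    evidence = [h.domain for h in coding]
    by_domain: Dict[str, int] = {}
    for idx, h in enumerate(coding):
        if h.domain not in by_domain:  # keep first occurrence in coding order
            by_domain[h.domain] = idx
    if "RT" not in by_domain or "INT" not in by_domain:
        return Classification("unknown", False, evidence)
    if by_domain["RT"] < by_domain["INT"]:
        chromo = "CHROMO" in by_domain and by_domain["CHROMO"] > by_domain["INT"]
        return Classification("Gypsy", chromo, evidence)
    return Classification("Copia", False, evidence)


def classify_elements(
    genome_records: Sequence[Tuple[str, str]],
    elements: Sequence[ElementAnnotation],
    library: Optional[DomainLibrary] = None,
) -> Tuple[List[ElementAnnotation], List[Tuple[str, DomainHit]]]:
    """Scan and classify every element; annotate GFF attributes in place.

    Returns the annotated elements and a flat ``(element_id, hit)`` table.
    """
    if library is None:
        library = load_default_library()
    seqs = dict(genome_records)
    all_hits: List[Tuple[str, DomainHit]] = []
    for el in elements:
        seq = seqs[el.seq_id][el.start : el.end]
        hits = scan_domains(seq, library)
        cls = classify_element(hits)
        el.attributes["Superfamily"] = cls.superfamily
        el.attributes["Chromoviridae"] = str(cls.chromoviridae).lower()
        el.attributes["Domains"] = ",".join(cls.evidence)
        all_hits.extend((el.element_id, h) for h in hits)
    return list(elements), all_hits


def null_score_distribution(
    library: DomainLibrary,
    length: int = 3000,
    gc_fraction: float = 0.5,
    n_replicates: int = 100,
    seed: int = 0,
) -> Dict[str, List[float]]:
    """Best per-domain local-alignment scores on random sequences.

    Used to calibrate ``min_score`` (shipped thresholds are the 99th
    percentile of this distribution at the default parameters).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    aligner = _make_aligner(library)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    out: Dict[str, List[float]] = {d: [] for d in library.domains}
    for _ in range(n_replicates):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
        frames = six_frame_translate(seq)
        for domain in library.domains:
            best = 0.0
            for _, ref in library.references(domain):
                for pep in frames.values():
                    if pep:
                        best = max(best, aligner.score(ref, pep))
            out[domain].append(best)
    return out
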