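"""Synthetic genomes with LTR-retrotransposon insertions of known age.

The simulator plants full-length elements (two initially identical
terminal repeats flanking a coding interior), truncated copies and solo
LTRs into a random background, duplicating a 4-6 bp target site at each
insertion.  Each LTR copy diverges independently from the ancestral
repeat under a transition-biased substitution process, so the expected
between-LTR divergence of an element inserted T years ago is
``~ 2 * rate_r * T`` (before multiple-hit correction) — exactly the
quantity the dating stage estimates back.

Also generates gene -> GO-term tables with planted term enrichment in a
"secreted" subset, the input of the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .classify import (
    COPIA_ORDER,
    CORE_DOMAINS,
    GYPSY_ORDER,
    DomainLibrary,
    load_default_library,
)
from .seqio import ElementAnnotation, read_elements_gff, write_elements_gff

NT = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# synonymous codons per amino acid (standard code, stops excluded); the
# back-translation draws one per residue so that two templates encoding
# the same peptide still diverge at the nucleotide level, as real
# families do — otherwise the detector would see cross-family repeats
_SYN_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_AAS = sorted(_SYN_CODONS)


@dataclass
class Genome:
    """Ordered named nucleotide sequences over {A,C,G,T,N}."""

    records: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids")
        for rid, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence {rid!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"illegal characters in {rid!r}: {sorted(bad)}")

    def sequence(self, seq_id: str) -> str:
        for rid, seq in self.records:
            if rid == seq_id:
                return seq
        raise KeyError(seq_id)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


@dataclass
class FamilyTemplate:
    """Ancestral element: one LTR plus a coding interior with domains."""

    family_id: str
    ltr_sequence: str
    internal_sequence: str
    domain_layout: List[Tuple[str, int, int]]  # (name, start, end) on interior
    superfamily_truth: str  # Gypsy | Copia

    def __post_init__(self) -> None:
        if not 100 <= len(self.ltr_sequence) <= 1500:
            raise ValueError("LTR length must be in [100, 1500]")
        prev_end = -1
        order = [name for name, _, _ in self.domain_layout]
        for name, s, e in self.domain_layout:
            if s < prev_end:
                raise ValueError("domain intervals overlap or are unordered")
            prev_end = e
        if self.superfamily_truth == "Gypsy":
            if "RT" in order and "INT" in order and order.index("RT") > order.index("INT"):
                raise ValueError("Gypsy template must order RT before INT")
        elif self.superfamily_truth == "Copia":
            if "RT" in order and "INT" in order and order.index("INT") > order.index("RT"):
                raise ValueError("Copia template must order INT before RT")
        else:
            raise ValueError(f"unknown superfamily {self.superfamily_truth!r}")

    @property
    def element_sequence(self) -> str:
        return self.ltr_sequence + self.internal_sequence + self.ltr_sequence

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_sequence) + len(self.internal_sequence)


@dataclass
class TruthInsertion:
    """Ground-truth record for one planted copy (0-based half-open)."""

    family_id: str
    sequence_id: str
    element_interval: Tuple[int, int]
    ltr5_interval: Optional[Tuple[int, int]]
    ltr3_interval: Optional[Tuple[int, int]]
    tsd: str
    age_T: float
    truncated: bool = False
    solo_ltr: bool = False

    def __post_init__(self) -> None:
        if self.age_T < 0:
            raise ValueError("age_T must be >= 0")
        s, e = self.element_interval
        for iv in (self.ltr5_interval, self.ltr3_interval):
            if iv is not None and not (s <= iv[0] < iv[1] <= e):
                raise ValueError("LTR interval outside element interval")
        if self.ltr5_interval and self.ltr3_interval:
            if self.ltr5_interval[0] >= self.ltr3_interval[0]:
                raise ValueError("ltr5 must precede ltr3")


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_insertions: int = 5  # per family
    ages: List[float] = field(default_factory=lambda: [5e6])
    rate_r: float = 1.05e-9
    transition_fraction: float = 0.5
    indel_rate: float = 0.0
    truncation_fraction: float = 0.0
    solo_ltr_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_r <= 0:
            raise ValueError("rate_r must be positive")
        for name in ("gc_fraction", "transition_fraction", "truncation_fraction",
                     "solo_ltr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.truncation_fraction + self.solo_ltr_fraction > 1.0:
            raise ValueError("truncation + solo fractions exceed 1")


# ---------------------------------------------------------------------------
# Background and mutation


def simulate_background(length: int, gc_fraction: float, seed: int) -> Genome:
    """Random i.i.d. background sequence with P(G) + P(C) = gc_fraction."""
    if length < 1000:
        raise ValueError("background length must be >= 1000 bp")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(rng.choice(NT, size=length, p=p))
    return Genome(records=[("chr1", seq)])


def mutate_sequence(
    seq: str, subs_per_site: float, transition_fraction: float, rng: np.random.Generator
) -> str:
    """Apply Poisson-many substitutions per site, sequentially per site.

    Each event is a transition with probability ``transition_fraction``,
    otherwise one of the two transversions uniformly.  Sequential
    application models multiple hits, so the observed divergence
    saturates exactly as the Kimura correction assumes.
    """
    if subs_per_site < 0:
        raise ValueError("substitution rate must be >= 0")
    if subs_per_site == 0:
        return seq
    counts = rng.poisson(subs_per_site, size=len(seq))
    out = list(seq)
    for pos in np.nonzero(counts)[0]:
        base = out[pos]
        for _ in range(counts[pos]):
            if base == "N":
                break
            if rng.random() < transition_fraction:
                base = TRANSITION[base]
            else:
                base = TRANSVERSIONS[base][rng.integers(2)]
        out[pos] = base
    return "".join(out)


def age_ltr_pair(
    ltr_sequence: str,
    age_T: float,
    rate_r: float = 1.05e-9,
    transition_fraction: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, str]:
    """Independently mutate two copies of an ancestral LTR for T years."""
    if age_T < 0:
        raise ValueError("age_T must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = rate_r * age_T
    ltr5 = mutate_sequence(ltr_sequence, lam, transition_fraction, rng)
    ltr3 = mutate_sequence(ltr_sequence, lam, transition_fraction, rng)
    return ltr5, ltr3


# ---------------------------------------------------------------------------
# Templates


def _back_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(
        _SYN_CODONS[a][rng.integers(len(_SYN_CODONS[a]))] for a in pep
    )


def _mutate_peptide(pep: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return pep
    out = list(pep)
    for i in range(len(out)):
        if rng.random() < divergence:
            out[i] = _AAS[rng.integers(len(_AAS))]
    return "".join(out)


def make_family_template(
    family_id: str,
    superfamily: str,
    seed: int,
    ltr_len: int = 400,
    chromoviridae: bool = False,
    peptide_divergence: float = 0.0,
    library: Optional[DomainLibrary] = None,
    gc_fraction: float = 0.5,
    reference_peptides: Optional[Dict[str, str]] = None,
) -> FamilyTemplate:
    """Build a template whose interior back-translates library peptides.

    ``peptide_divergence`` mutates the reference peptides (per-residue
    substitution probability) to create family-specific domain variants.
    ``reference_peptides`` overrides the bundled references per domain
    (used to derive families from a common planted ancestor).
    """
    if library is None:
        library = load_default_library()
    rng = np.random.default_rng(seed)
    if chromoviridae and superfamily != "Gypsy":
        raise ValueError("chromodomain layout requires a Gypsy template")
    order = list(GYPSY_ORDER if superfamily == "Gypsy" else COPIA_ORDER)
    if chromoviridae:
        order.append("CHROMO")
    refs = {d: library.references(d)[0][1] for d in order}
    if reference_peptides:
        refs.update({d: p for d, p in reference_peptides.items() if d in refs})
    peptide_parts: List[str] = []
    layout: List[Tuple[str, int, int]] = []
    pos_aa = 0
    for domain in order:
        linker_len = int(rng.integers(10, 30))
        linker = "".join(_AAS[i] for i in rng.integers(len(_AAS), size=linker_len))
        peptide_parts.append(linker)
        pos_aa += linker_len
        pep = _mutate_peptide(refs[domain], peptide_divergence, rng)
        peptide_parts.append(pep)
        layout.append((domain, 3 * pos_aa, 3 * (pos_aa + len(pep))))
        pos_aa += len(pep)
    internal = _back_translate("".join(peptide_parts), rng)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    ltr = "".join(rng.choice(NT, size=ltr_len, p=p))
    return FamilyTemplate(
        family_id=family_id,
        ltr_sequence=ltr,
        internal_sequence=internal,
        domain_layout=layout,
        superfamily_truth=superfamily,
    )


def make_lineage_templates(
    lineage_id: str,
    superfamily: str,
    n_families: int,
    seed: int,
    ancestor_divergence: float = 0.25,
    family_divergence: float = 0.05,
    library: Optional[DomainLibrary] = None,
    **template_kwargs,
) -> List[FamilyTemplate]:
    """Templates sharing a planted ancestor (a phylogenetic clade).

    The lineage ancestor's domain peptides are drawn by mutating the
    library references at ``ancestor_divergence`` per residue; each
    family then diverges a further ``family_divergence`` from that
    ancestor, so families of one lineage are mutually closer than to any
    other lineage and form a recoverable clade.
    """
    if library is None:
        library = load_default_library()
    rng = np.random.default_rng(seed)
    ancestor = {
        d: _mutate_peptide(library.references(d)[0][1], ancestor_divergence, rng)
        for d in CORE_DOMAINS
        if library.references(d)
    }
    return [
        make_family_template(
            f"{lineage_id}_{i + 1}",
            superfamily,
            seed=int(rng.integers(2**31)),
            peptide_divergence=family_divergence,
            library=library,
            reference_peptides=ancestor,
            **template_kwargs,
        )
        for i in range(n_families)
    ]


# ---------------------------------------------------------------------------
# Insertion


def _sample_insertion_points(
    length: int, n: int, min_gap: int, rng: np.random.Generator
) -> List[int]:
    if length < (n + 1) * min_gap:
        raise ValueError(
            f"genome of {length} bp too short to host {n} insertions "
            f"with {min_gap} bp separation"
        )
    for _ in range(1000):
        points = np.sort(rng.integers(min_gap, length - min_gap, size=n))
        if n <= 1 or np.all(np.diff(points) >= min_gap):
            return [int(p) for p in points]
    raise ValueError("could not place insertions without overlap")


def insert_elements(
    genome: Genome,
    templates: Sequence[FamilyTemplate],
    config: SimulationConfig,
) -> Tuple[Genome, List[TruthInsertion]]:
    """Insert ``n_insertions`` aged copies of every template with TSDs.

    A fraction of copies (per config) is 5'/3'-truncated by 20-80% of the
    element length or reduced to a solo LTR.  Ages cycle through
    ``config.ages``.  Returns the expanded genome and truth records with
    exact coordinates in the output genome.
    """
    rng = np.random.default_rng(config.seed)
    n_total = len(templates) * config.n_insertions
    if n_total == 0:
        return genome, []
    seq_id, host = genome.records[0]
    points = _sample_insertion_points(len(host), n_total, min_gap=200, rng=rng)

    jobs = []  # (point, template, age, kind)
    idx = 0
    for template in templates:
        for j in range(config.n_insertions):
            age = float(config.ages[j % len(config.ages)])
            u = rng.random()
            if u < config.solo_ltr_fraction:
                kind = "solo"
            elif u < config.solo_ltr_fraction + config.truncation_fraction:
                kind = "truncated"
            else:
                kind = "full"
            jobs.append((points[idx], template, age, kind))
            idx += 1
    jobs.sort(key=lambda j: j[0])

    parts: List[str] = []
    truths: List[TruthInsertion] = []
    prev = 0
    offset = 0
    for point, template, age, kind in jobs:
        tsd_len = int(rng.integers(4, 7))
        tsd = host[point : point + tsd_len]
        ltr5, ltr3 = age_ltr_pair(
            template.ltr_sequence, age, config.rate_r, config.transition_fraction, rng=rng
        )
        internal = mutate_sequence(
            template.internal_sequence, config.rate_r * age, config.transition_fraction, rng
        )
        if config.indel_rate > 0:
            internal = _apply_indels(internal, config.indel_rate, rng)
        L5, L3 = len(ltr5), len(ltr3)
        if kind == "solo":
            elem = ltr5
            rel5: Optional[Tuple[int, int]] = (0, L5)
            rel3: Optional[Tuple[int, int]] = None
        else:
            elem = ltr5 + internal + ltr3
            rel5 = (0, L5)
            rel3 = (len(elem) - L3, len(elem))
            if kind == "truncated":
                cut = int(round(len(elem) * rng.uniform(0.2, 0.8)))
                cut = min(cut, len(elem) - 1)
                if rng.random() < 0.5:  # 5' truncation
                    elem = elem[cut:]
                    rel5 = None
                    rel3 = (len(elem) - L3, len(elem)) if len(elem) >= L3 else None
                else:  # 3' truncation
                    elem = elem[: len(elem) - cut]
                    rel3 = None
                    rel5 = (0, L5) if len(elem) >= L5 else None
        # host[:point+tsd_len] ends with the left TSD copy; duplicate it right
        parts.append(host[prev : point + tsd_len])
        parts.append(elem)
        parts.append(tsd)
        start = offset + point + tsd_len
        end = start + len(elem)
        offset += len(elem) + tsd_len
        prev = point + tsd_len
        truths.append(
            TruthInsertion(
                family_id=template.family_id,
                sequence_id=seq_id,
                element_interval=(start, end),
                ltr5_interval=None if rel5 is None else (start + rel5[0], start + rel5[1]),
                ltr3_interval=None if rel3 is None else (start + rel3[0], start + rel3[1]),
                tsd=tsd,
                age_T=age,
                truncated=kind == "truncated",
                solo_ltr=kind == "solo",
            )
        )
    parts.append(host[prev:])
    new_genome = Genome(records=[(seq_id, "".join(parts))] + genome.records[1:])
    return new_genome, truths


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out: List[str] = []
    for ch in seq:
        if rng.random() < rate:
            if rng.random() < 0.5:  # deletion
                continue
            ins = "".join(NT[i] for i in rng.integers(4, size=int(rng.integers(1, 4))))
            out.append(ins)
        out.append(ch)
    return "".join(out) or seq[:1]


# ---------------------------------------------------------------------------
# Truth GFF3


def truth_to_annotations(truths: Sequence[TruthInsertion]) -> List[ElementAnnotation]:
    out = []
    for i, t in enumerate(truths):
        out.append(
            ElementAnnotation(
                element_id=f"truth_{i:04d}",
                seq_id=t.sequence_id,
                start=t.element_interval[0],
                end=t.element_interval[1],
                ltr5=t.ltr5_interval,
                ltr3=t.ltr3_interval,
                attributes={
                    "Family": t.family_id,
                    "Age": repr(t.age_T),
                    "TSD": t.tsd,
                    "Truncated": str(t.truncated).lower(),
                    "Solo": str(t.solo_ltr).lower(),
                },
            )
        )
    return out


def write_truth_gff(path, truths: Sequence[TruthInsertion]) -> None:
    write_elements_gff(path, truth_to_annotations(truths))


def read_truth_gff(path) -> List[TruthInsertion]:
    out = []
    for el in read_elements_gff(path):
        out.append(
            TruthInsertion(
                family_id=el.attributes["Family"],
                sequence_id=el.seq_id,
                element_interval=(el.start, el.end),
                ltr5_interval=el.ltr5,
                ltr3_interval=el.ltr3,
                tsd=el.attributes["TSD"],
                age_T=float(el.attributes["Age"]),
                truncated=el.attributes["Truncated"] == "true",
                solo_ltr=el.attributes["Solo"] == "true",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotation tables (gene -> GO, secreted subset)


def gene_universe(n_genes: int) -> List[str]:
    """The full gene id universe used by the annotation-table simulator."""
    return [f"gene_{i:06d}" for i in range(n_genes)]


def simulate_annotation_tables(
    n_genes: int,
    n_secreted: int,
    planted_terms: Sequence[Tuple[str, int, int]],
    seed: int,
    n_background_terms: int = 20,
) -> Tuple[List[Tuple[str, str]], Set[str]]:
    """Gene->GO table plus a secreted-gene set with planted enrichment.

    ``planted_terms`` is ``(term, count_in_secretome, count_in_genome)``;
    the realized counts equal the request exactly.  Background terms are
    assigned to random genes.
    """
    if n_secreted > n_genes:
        raise ValueError("n_secreted cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    secreted = set(rng.choice(genes, size=n_secreted, replace=False))
    non_secreted = [g for g in genes if g not in secreted]
    secreted_list = sorted(secreted)
    table: List[Tuple[str, str]] = []
    for term, k_sec, k_gen in planted_terms:
        if k_sec > k_gen:
            raise ValueError(f"{term}: secretome count exceeds genome count")
        if k_sec > n_secreted or (k_gen - k_sec) > len(non_secreted):
            raise ValueError(f"{term}: counts exceed available genes")
        carriers = list(rng.choice(secreted_list, size=k_sec, replace=False))
        carriers += list(rng.choice(non_secreted, size=k_gen - k_sec, replace=False))
        table.extend((g, term) for g in carriers)
    for i in range(n_background_terms):
        term = f"GO:8{i:06d}"
        k = int(rng.integers(1, 31))
        for g in rng.choice(genes, size=min(k, n_genes), replace=False):
            table.append((g, term))
    table.sort()
    return table, secreted


def write_annotation_tables(prefix, table, secreted, genes=None) -> Tuple[str, ...]:
    ann_path = f"{prefix}.go.tsv"
    sec_path = f"{prefix}.secreted.tsv"
    with open(ann_path, "w") as fh:
        for gene, term in table:
            fh.write(f"{gene}\t{term}\n")
    with open(sec_path, "w") as fh:
        for gene in sorted(secreted):
            fh.write(gene + "\n")
    if genes is None:
        return ann_path, sec_path
    genes_path = f"{prefix}.genes.tsv"
    with open(genes_path, "w") as fh:
        for gene in genes:
            fh.write(gene + "\n")
    return ann_path, sec_path, genes_path
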