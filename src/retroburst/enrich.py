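"""One-sided Fisher exact enrichment of a gene subset, Bonferroni-corrected.

For a term present in ``a`` of the subset's genes and ``a + c`` genes
genome-wide (the genome column includes the subset), the raw p-value is
the upper hypergeometric tail ``P(X >= a)`` with population ``a+b+c+d``,
``a+c`` successes and ``a+b`` draws, summed exactly in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple


@dataclass
class ContingencyTable:
    a: int  # subset genes with term
    b: int  # subset genes without term
    c: int  # non-subset genes with term
    d: int  # non-subset genes without term

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def subset_size(self) -> int:
        return self.a + self.b

    @property
    def term_total(self) -> int:
        return self.a + self.c

    @property
    def population(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentRow:
    term_id: str
    counts: ContingencyTable
    p_raw: float
    p_corrected: float
    tested_terms: int
    significant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= self.p_corrected <= 1.0 + 1e-12:
            raise ValueError("need 0 <= p_raw <= p_corrected <= 1")


def build_contingency(
    term: str,
    gene_terms: Sequence[Tuple[str, str]],
    subset: Set[str],
    genome_genes: Set[str],
) -> ContingencyTable:
    """Count the 2x2 table for one term.

    The genome column includes the subset: ``a + c`` is the genome-wide
    carrier count.  Raises if the subset is not contained in the genome
    gene set.
    """
    missing = subset - genome_genes
    if missing:
        raise ValueError(f"subset genes absent from genome table: {sorted(missing)[:3]}")
    carriers = {g for g, t in gene_terms if t == term}
    a = len(carriers & subset)
    c = len(carriers - subset)
    b = len(subset) - a
    d = len(genome_genes) - len(subset) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail hypergeometric probability ``P(X >= a)``.

    Exact summation in log space.  Zero margins give p = 1 by convention.
    """
    N = table.population
    K = table.term_total
    n = table.subset_size
    a = table.a
    if K == 0 or n == 0 or N == 0:
        return 1.0
    if a <= 0:
        return 1.0  # P(X >= 0) is exactly 1
    denom = _log_comb(N, n)
    hi = min(K, n)
    logs = []
    for x in range(a, hi + 1):
        logs.append(_log_comb(K, x) + _log_comb(N - K, n - x) - denom)
    if not logs:
        return 0.0
    m = max(logs)
    if m == float("-inf"):
        return 0.0
    total = m + math.log(sum(math.exp(v - m) for v in logs))
    return min(1.0, math.exp(total))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> List[float]:
    """``min(1, m * p)`` per value; ``m`` defaults to ``len(p_values)``."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return [min(1.0, m * p) for p in p_values]


def enrich_report(
    gene_terms: Sequence[Tuple[str, str]],
    subset: Iterable[str],
    alpha: float = 0.05,
    min_genome_count: int = 1,
    genome_genes: Iterable[str] | None = None,
) -> List[EnrichmentRow]:
    """Per-term enrichment rows sorted by raw p-value then term id.

    ``genome_genes`` is the full gene universe (the genome denominator);
    when omitted it is inferred as the genes in the table plus the
    subset, which undercounts genes carrying no term — pass it whenever
    the universe is known.
    """
    subset = set(subset)
    if genome_genes is None:
        genome_genes = {g for g, _ in gene_terms} | subset
    else:
        genome_genes = set(genome_genes) | subset
    terms = sorted({t for _, t in gene_terms})
    tables: List[Tuple[str, ContingencyTable]] = []
    for term in terms:
        tab = build_contingency(term, gene_terms, subset, genome_genes)
        if tab.term_total >= min_genome_count:
            tables.append((term, tab))
    m = len(tables)
    rows: List[EnrichmentRow] = []
    if m == 0:
        return rows
    raw = [fisher_one_sided(tab) for _, tab in tables]
    corrected = bonferroni(raw, m)
    for (term, tab), p, pc in zip(tables, raw, corrected):
        rows.append(
            EnrichmentRow(
                term_id=term,
                counts=tab,
                p_raw=p,
                p_corrected=pc,
                tested_terms=m,
                significant=pc <= alpha,
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows
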