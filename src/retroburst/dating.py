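"""LTR-pair dating: align, trim, count substitutions, Kimura 2P, years.

The insertion age of one element is ``T = K / (2 r)`` where ``K`` is the
Kimura two-parameter distance between its two terminal repeats and ``r``
the per-site, per-year substitution rate (default 1.05e-9).  The factor
two reflects both repeats diverging independently since insertion.

Saturated pairs (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``) are flagged
undatable and excluded from burst profiles rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from . import DEFAULT_SUBSTITUTION_RATE
from .align import global_align
from .seqio import ElementAnnotation

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class SaturatedDivergenceError(ValueError):
    """Divergence too high for the Kimura 2P correction."""


class UninformativeAlignmentError(ValueError):
    """No usable columns left after trimming."""


@dataclass
class PairAlignment:
    aligned_ltr5: str
    aligned_ltr3: str
    trimmed: bool = False

    def __post_init__(self) -> None:
        if len(self.aligned_ltr5) != len(self.aligned_ltr3):
            raise ValueError("aligned rows differ in length")
        if not any(a != "-" or b != "-" for a, b in zip(self.aligned_ltr5, self.aligned_ltr3)):
            raise ValueError("alignment has no non-gap column")


@dataclass
class DivergenceEstimate:
    P: float
    Q: float
    usable_sites: int
    K: Optional[float] = None

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("P and Q must be nonnegative with P + Q <= 1")
        if self.usable_sites <= 0:
            raise ValueError("usable_sites must be positive")


@dataclass
class AgeEstimate:
    element_id: str
    K: float
    rate_r: float
    T: float


@dataclass
class BurstProfile:
    bin_width: float
    bin_counts: List[int]
    n_undatable: int = 0

    @property
    def n_dated(self) -> int:
        return sum(self.bin_counts)

    def modal_bin(self) -> Tuple[float, float]:
        """(start, end) in years of the most populated bin."""
        if not self.bin_counts or not any(self.bin_counts):
            raise ValueError("empty profile has no modal bin")
        i = max(range(len(self.bin_counts)), key=lambda j: self.bin_counts[j])
        return (i * self.bin_width, (i + 1) * self.bin_width)


def align_ltr_pair(
    ltr5: str,
    ltr3: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    band: Optional[int] = None,
) -> PairAlignment:
    """Global alignment of the two repeats (diagonal-preferring ties).

    ``band=None`` selects a full DP for short inputs and a 60-column band
    for long ones (exact whenever the true alignment is near-diagonal,
    which holds for LTR pairs of one element).
    """
    if not ltr5 or not ltr3:
        raise ValueError("cannot align empty LTR sequence")
    if band is None and min(len(ltr5), len(ltr3)) > 300:
        band = 60
    aln = global_align(
        ltr5, ltr3, match=match, mismatch=mismatch, gap_open=gap_open,
        gap_extend=gap_extend, band=band,
    )
    return PairAlignment(aln.aligned_a, aln.aligned_b, trimmed=False)


def trim_alignment(pair: PairAlignment) -> PairAlignment:
    """Drop every column containing a gap or an N; set the trimmed flag."""
    cols = [
        (a, b)
        for a, b in zip(pair.aligned_ltr5, pair.aligned_ltr3)
        if a in "ACGT" and b in "ACGT"
    ]
    if not cols:
        raise UninformativeAlignmentError("alignment uninformative: all columns trimmed")
    return PairAlignment(
        "".join(a for a, _ in cols), "".join(b for _, b in cols), trimmed=True
    )


def count_PQ(pair: PairAlignment) -> DivergenceEstimate:
    """Transition (P) and transversion (Q) proportions over usable columns."""
    usable = transitions = transversions = 0
    for a, b in zip(pair.aligned_ltr5, pair.aligned_ltr3):
        if a not in "ACGT" or b not in "ACGT":
            continue
        usable += 1
        if a != b:
            if frozenset((a, b)) in TRANSITION_PAIRS:
                transitions += 1
            else:
                transversions += 1
    if usable == 0:
        raise UninformativeAlignmentError("no usable columns")
    return DivergenceEstimate(
        P=transitions / usable, Q=transversions / usable, usable_sites=usable
    )


def kimura2p(P: float, Q: float) -> float:
    """Kimura 2P distance ``K = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]``."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(
            f"saturated divergence: P={P:.4f}, Q={Q:.4f}"
        )
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def age_from_k(K: float, rate_r: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """Insertion age in years, ``T = K / (2 r)``."""
    if rate_r <= 0:
        raise ValueError("rate_r must be positive")
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * rate_r)


def burst_profile(
    ages: Sequence[float],
    bin_width: float = 5e6,
    max_age: Optional[float] = None,
    n_undatable: int = 0,
) -> BurstProfile:
    """Histogram of ages over half-open bins ``[i*w, (i+1)*w)``.

    Ages at or beyond ``max_age`` are pooled into the last bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_age is not None:
        n_bins = max(1, math.ceil(max_age / bin_width))
    elif ages:
        n_bins = int(max(ages) // bin_width) + 1
    else:
        n_bins = 0
    counts = [0] * n_bins
    for t in ages:
        if t < 0:
            raise ValueError("negative age")
        i = min(int(t // bin_width), n_bins - 1)
        counts[i] += 1
    return BurstProfile(bin_width=bin_width, bin_counts=counts, n_undatable=n_undatable)


@dataclass
class DatingRow:
    """Per-element dating record (status: ok | saturated | no_ltr_pair)."""

    element_id: str
    status: str
    P: Optional[float] = None
    Q: Optional[float] = None
    usable_sites: Optional[int] = None
    K: Optional[float] = None
    T: Optional[float] = None


def date_elements(
    records: Sequence[Tuple[str, str]],
    elements: Sequence[ElementAnnotation],
    rate_r: float = DEFAULT_SUBSTITUTION_RATE,
    **align_kwargs,
) -> List[DatingRow]:
    """Date every element that carries both LTR intervals."""
    seqs = dict(records)
    rows: List[DatingRow] = []
    for el in elements:
        if el.ltr5 is None or el.ltr3 is None:
            rows.append(DatingRow(el.element_id, "no_ltr_pair"))
            continue
        seq = seqs[el.seq_id]
        ltr5 = seq[el.ltr5[0] : el.ltr5[1]]
        ltr3 = seq[el.ltr3[0] : el.ltr3[1]]
        try:
            aln = trim_alignment(align_ltr_pair(ltr5, ltr3, **align_kwargs))
            div = count_PQ(aln)
            K = kimura2p(div.P, div.Q)
        except SaturatedDivergenceError:
            div = count_PQ(trim_alignment(align_ltr_pair(ltr5, ltr3, **align_kwargs)))
            rows.append(
                DatingRow(el.element_id, "saturated", div.P, div.Q, div.usable_sites)
            )
            continue
        except UninformativeAlignmentError:
            rows.append(DatingRow(el.element_id, "saturated"))
            continue
        rows.append(
            DatingRow(
                el.element_id, "ok", div.P, div.Q, div.usable_sites, K,
                age_from_k(K, rate_r),
            )
        )
    return rows


def plot_profile(profile: BurstProfile, path, title: str = "LTR insertion ages") -> None:
    """Write the burst profile as a bar chart (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    my = profile.bin_width / 1e6
    edges = [i * my for i in range(len(profile.bin_counts))]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(edges, profile.bin_counts, width=my * 0.9, align="edge", color="#4472a8")
    ax.set_xlabel("insertion age (MY)")
    ax.set_ylabel("elements")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_from_rows(
    rows: Sequence[DatingRow], bin_width: float = 5e6, max_age: Optional[float] = None
) -> BurstProfile:
    ages = [r.T for r in rows if r.status == "ok" and r.T is not None]
    n_undatable = sum(1 for r in rows if r.status == "saturated")
    return burst_profile(ages, bin_width=bin_width, max_age=max_age, n_undatable=n_undatable)
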