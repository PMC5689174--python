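import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bitmap_union_length
from retroburst.census import (
    CopyAnnotation,
    Family,
    annotate_copies,
    build_consensus,
    cluster_copies,
    interval_union_length,
    quantify,
    run_census,
)
from retroburst.detect import DetectorParams, candidates_to_annotations, detect_elements
from retroburst.seqio import ElementAnnotation
from retroburst.simulate import (
    SimulationConfig,
    insert_elements,
    simulate_background,
)


def _ann(seq_id, start, end, element_id="e"):
    return ElementAnnotation(element_id=element_id, seq_id=seq_id, start=start, end=end)


class TestClustering:
    def test_copies_of_one_template_form_one_family(self, small_simulation, detected_candidates):
        genome, truths = small_simulation
        elements = candidates_to_annotations(detected_candidates)
        families = cluster_copies(elements, genome.records)
        assert len(families) == 2  # the two planted templates
        sizes = sorted(len(f.members) for f in families)
        assert sizes == [3, 3]

    def test_dissimilar_sequences_stay_separate(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=2_000))
        b = "".join(rng.choice(list("ACGT"), size=2_000))
        seq = "T" * 500 + a + "T" * 500 + b + "T" * 500
        elements = [_ann("c", 500, 2_500, "a"), _ann("c", 3_000, 5_000, "b")]
        families = cluster_copies(elements, [("c", seq)])
        assert len(families) == 2

    def test_singleton(self):
        seq = "ACGT" * 1_000
        families = cluster_copies([_ann("c", 0, 400)], [("c", seq)])
        assert len(families) == 1
        assert len(families[0].members) == 1

    def test_numbering_deterministic(self, small_simulation, detected_candidates):
        genome, _ = small_simulation
        elements = candidates_to_annotations(detected_candidates)
        f1 = cluster_copies(elements, genome.records)
        f2 = cluster_copies(list(reversed(elements)), genome.records)
        assert [f.family_id for f in f1] == [f.family_id for f in f2]
        assert [
            sorted(m.element_id for m in f.members) for f in f1
        ] == [sorted(m.element_id for m in f.members) for f in f2]

    def test_no_elements_rejected(self):
        with pytest.raises(ValueError):
            cluster_copies([], [("c", "ACGT")])


class TestConsensus:
    def test_identical_members(self):
        seq = "ACGTACGTAA" * 30
        genome = [("c", seq + "T" * 100 + seq)]
        fam = Family("F", [_ann("c", 0, 300, "m1"), _ann("c", 400, 700, "m2")])
        assert build_consensus(fam, genome) == seq

    def test_majority_recovers_ancestor(self, rng):
        ancestor = "".join(rng.choice(list("ACGT"), size=600))
        # three members, each with a distinct single substitution
        variants = []
        for pos, base in ((50, "A"), (300, "C"), (550, "G")):
            v = list(ancestor)
            v[pos] = {"A": "T", "C": "A", "G": "C", "T": "G"}[v[pos]]
            variants.append("".join(v))
        genome = [("c", ("X" * 0) + variants[0] + variants[1] + variants[2])]
        fam = Family("F", [
            _ann("c", 0, 600, "m1"), _ann("c", 600, 1_200, "m2"),
            _ann("c", 1_200, 1_800, "m3"),
        ])
        assert build_consensus(fam, genome) == ancestor

    def test_singleton_consensus_is_member(self):
        genome = [("c", "ACGTTGCA" * 50)]
        fam = Family("F", [_ann("c", 8, 208)])
        assert build_consensus(fam, genome) == genome[0][1][8:208]


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(21)
    consensus = "".join(rng.choice(list("ACGT"), size=3_000))
    background = "".join(rng.choice(list("ACGT"), size=30_000))
    truncated = consensus[: int(0.6 * len(consensus))]  # 40% 3' truncation
    solo = consensus[:400]
    seq = (
        background[:5_000] + consensus + background[5_000:15_000]
        + truncated + background[15_000:25_000] + solo + background[25_000:]
    )
    fam = Family("F", [_ann("c", 5_000, 8_000)], consensus=consensus)
    return [("c", seq)], fam, consensus


class TestAnnotateCopies:

    def test_full_and_truncated_fractions(self, planted):
        records, fam, consensus = planted
        copies = annotate_copies(records, [fam])
        fracs = sorted(c.fraction_of_consensus for c in copies)
        assert len(copies) == 3
        assert fracs[2] >= 0.99  # full copy
        assert abs(fracs[1] - 0.6) < 0.02  # truncated
        assert abs(fracs[0] - 400 / 3_000) < 0.02  # solo-LTR-sized fragment

    def test_reverse_strand_copy_found(self, planted, rng):
        from Bio.Seq import Seq

        records, fam, consensus = planted
        rc = str(Seq(consensus).reverse_complement())
        seq = records[0][1] + rc + "".join(rng.choice(list("ACGT"), size=1_000))
        copies = annotate_copies([("c", seq)], [fam])
        assert len(copies) == 4

    def test_no_copies_empty(self, rng):
        decoy = "".join(rng.choice(list("ACGT"), size=2_000))
        genome = [("c", "".join(rng.choice(list("ACGT"), size=20_000)))]
        fam = Family("F", [_ann("c", 0, 100)], consensus=decoy)
        assert annotate_copies(genome, [fam]) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_copies([("c", "ACGT")], [])


class TestQuantify:
    def _copies(self, intervals, fraction=1.0):
        return [
            CopyAnnotation("c", s, e, "F", identity=0.99, fraction_of_consensus=fraction)
            for s, e in intervals
        ]

    def _family(self):
        return Family("F", [_ann("c", 0, 5_000)], consensus="A" * 5_000,
                      classification="LTR/Gypsy")

    def test_three_full_copies_exact(self):
        records = [("c", "A" * 100_000)]
        copies = self._copies([(0, 5_000), (10_000, 15_000), (20_000, 25_000)])
        rows = quantify(copies, [self._family()], records)
        fam_row = rows[0]
        assert (fam_row.n_copies, fam_row.n_full_copies) == (3, 3)
        assert fam_row.coverage_percent == pytest.approx(15.0)

    def test_overlapping_copies_counted_once(self):
        records = [("c", "A" * 10_000)]
        copies = self._copies([(0, 1_000), (500, 1_500)])
        rows = quantify(copies, [self._family()], records)
        assert rows[0].coverage_percent == pytest.approx(15.0)

    def test_total_not_more_than_sum(self, small_simulation, detected_candidates):
        genome, _ = small_simulation
        elements = candidates_to_annotations(detected_candidates)
        _, _, rows = run_census(genome.records, elements, two_pass=False)
        per_family = [r for r in rows if r.label.startswith("FAM_")]
        total = [r for r in rows if r.label == "TOTAL"][0]
        assert total.coverage_percent <= sum(r.coverage_percent for r in per_family) + 1e-9
        assert total.n_copies == sum(r.n_copies for r in per_family)

    def test_full_copy_threshold(self):
        records = [("c", "A" * 10_000)]
        copies = self._copies([(0, 4_700)], fraction=0.94)
        rows = quantify(copies, [self._family()], records)
        assert (rows[0].n_copies, rows[0].n_full_copies) == (1, 0)


class TestIntervalUnion:
    def test_basic(self):
        assert interval_union_length([(0, 10), (5, 15), (20, 30)]) == 25

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=20,
        )
    )
    def test_equals_bitmap_oracle(self, intervals):
        assert interval_union_length(intervals) == bitmap_union_length(intervals, 1_000)


class TestEndToEnd:
    def test_census_recovers_planted_truth(self, small_simulation, detected_candidates):
        genome, truths = small_simulation
        elements = candidates_to_annotations(detected_candidates)
        families, copies, rows = run_census(genome.records, elements)
        by_label = {r.label: r for r in rows}
        # two families, three copies each, all full length
        fam_rows = [r for r in rows if r.label.startswith("FAM_")]
        assert len(fam_rows) == 2
        for r in fam_rows:
            assert abs(r.n_copies - 3) <= 1
            assert r.n_full_copies >= 2
        truth_union = sum(
            t.element_interval[1] - t.element_interval[0] for t in truths
        )
        truth_cov = 100.0 * truth_union / genome.total_length
        assert abs(by_label["TOTAL"].coverage_percent - truth_cov) <= 1.0

    def test_determinism(self, small_simulation, detected_candidates):
        genome, _ = small_simulation
        elements = candidates_to_annotations(detected_candidates)
        out1 = run_census(genome.records, elements)
        out2 = run_census(genome.records, elements)
        assert [f.family_id for f in out1[0]] == [f.family_id for f in out2[0]]
        assert out1[1] == out2[1]
        assert out1[2] == out2[2]
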