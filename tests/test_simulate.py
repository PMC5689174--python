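import math

import numpy as np
import pytest

from _oracles import expected_ltr_mismatch
from retroburst.enrich import enrich_report
from retroburst.simulate import (
    Genome,
    SimulationConfig,
    TruthInsertion,
    age_ltr_pair,
    insert_elements,
    make_family_template,
    read_truth_gff,
    simulate_annotation_tables,
    simulate_background,
    write_truth_gff,
)

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class TestBackground:
    def test_length_is_forced(self):
        genome = simulate_background(10_000, 0.5, seed=1)
        assert genome.total_length == 10_000

    def test_gc_fraction_within_three_binomial_sd(self):
        # GC content of the real assembly is 52.82%
        genome = simulate_background(100_000, 0.528, seed=7)
        seq = genome.records[0][1]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sd = math.sqrt(0.528 * (1 - 0.528) / 100_000)
        assert abs(gc - 0.528) <= 3 * sd

    def test_deterministic_given_seed(self):
        a = simulate_background(5_000, 0.4, seed=42)
        b = simulate_background(5_000, 0.4, seed=42)
        assert a.records == b.records

    def test_rejects_short_or_degenerate(self):
        with pytest.raises(ValueError, match="length"):
            simulate_background(10, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_background(10_000, 0.0, seed=0)


class TestAgeLtrPair:
    def test_age_zero_copies_identical(self):
        ltr = "ACGT" * 100
        l5, l3 = age_ltr_pair(ltr, 0.0, seed=1)
        assert l5 == l3 == ltr

    def test_pure_transition_mode(self):
        ltr = "ACGT" * 250
        l5, l3 = age_ltr_pair(ltr, 5e7, transition_fraction=1.0, seed=2)
        diffs = [(a, b) for a, b in zip(l5, l3) if a != b]
        assert diffs  # 50 MY should produce some
        assert all(frozenset(d) in TRANSITIONS for d in diffs)

    @pytest.mark.parametrize("age", [1e7, 2.5e7, 5e7])
    def test_divergence_calibration(self, age):
        # Monte-Carlo mean mismatch vs the closed-form expectation
        ltr = simulate_background(10_000, 0.5, seed=3).records[0][1]
        rng = np.random.default_rng(10)
        props = []
        for _ in range(50):
            l5, l3 = age_ltr_pair(ltr, age, rng=rng)
            props.append(sum(a != b for a, b in zip(l5, l3)) / len(ltr))
        expected = expected_ltr_mismatch(1.05e-9, age)
        se = np.std(props, ddof=1) / math.sqrt(len(props))
        assert abs(np.mean(props) - expected) <= 3 * se

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_ltr_pair("ACGT" * 50, -1.0, seed=0)


class TestInsertElements:
    def test_length_additivity(self, gypsy_template):
        genome = simulate_background(100_000, 0.5, seed=5)
        config = SimulationConfig(n_insertions=3, ages=[0.0], seed=6)
        expanded, truths = insert_elements(genome, [gypsy_template], config)
        added = sum(
            (t.element_interval[1] - t.element_interval[0]) + len(t.tsd) for t in truths
        )
        assert expanded.total_length == 100_000 + added
        for t in truths:
            assert t.element_interval[1] - t.element_interval[0] == gypsy_template.length

    def test_tsd_duplicated_around_element(self, gypsy_template):
        genome = simulate_background(50_000, 0.5, seed=5)
        config = SimulationConfig(n_insertions=2, ages=[0.0], seed=7)
        expanded, truths = insert_elements(genome, [gypsy_template], config)
        seq = expanded.records[0][1]
        for t in truths:
            s, e = t.element_interval
            assert 4 <= len(t.tsd) <= 6
            assert seq[s - len(t.tsd) : s] == t.tsd
            assert seq[e : e + len(t.tsd)] == t.tsd

    def test_truth_gff_roundtrip(self, tmp_path, small_simulation):
        _, truths = small_simulation
        path = tmp_path / "truth.gff3"
        write_truth_gff(path, truths)
        recovered = read_truth_gff(path)
        assert sorted(recovered, key=lambda t: t.element_interval) == sorted(
            truths, key=lambda t: t.element_interval
        )

    def test_full_truncation_leaves_no_complete_ltr_pair(self, gypsy_template):
        genome = simulate_background(100_000, 0.5, seed=8)
        config = SimulationConfig(
            n_insertions=5, ages=[1e6], truncation_fraction=1.0, seed=9
        )
        _, truths = insert_elements(genome, [gypsy_template], config)
        assert all(t.truncated for t in truths)
        assert not any(t.ltr5_interval and t.ltr3_interval for t in truths)

    def test_solo_fraction_one_gives_single_ltrs(self, gypsy_template):
        genome = simulate_background(100_000, 0.5, seed=8)
        config = SimulationConfig(
            n_insertions=4, ages=[1e6], solo_ltr_fraction=1.0, seed=10
        )
        _, truths = insert_elements(genome, [gypsy_template], config)
        ltr_len = len(gypsy_template.ltr_sequence)
        for t in truths:
            assert t.solo_ltr
            assert t.element_interval[1] - t.element_interval[0] == ltr_len
            assert t.ltr3_interval is None

    def test_deterministic_outputs(self, gypsy_template):
        genome = simulate_background(60_000, 0.5, seed=5)
        config = SimulationConfig(n_insertions=2, ages=[2e6], seed=11)
        out1 = insert_elements(genome, [gypsy_template], config)
        out2 = insert_elements(genome, [gypsy_template], config)
        assert out1[0].records == out2[0].records
        assert out1[1] == out2[1]

    def test_genome_too_short_rejected(self, gypsy_template):
        genome = simulate_background(1_000, 0.5, seed=5)
        config = SimulationConfig(n_insertions=50, ages=[0.0], seed=12)
        with pytest.raises(ValueError, match="too short"):
            insert_elements(genome, [gypsy_template], config)

    def test_excised_elements_redate_to_truth(self, small_simulation):
        # truth consistency: the planted LTR pair's divergence is in line
        # with its recorded age (checked loosely; dating tests do better)
        genome, truths = small_simulation
        seq = genome.records[0][1]
        for t in truths:
            if t.ltr5_interval is None or t.ltr3_interval is None:
                continue
            l5 = seq[t.ltr5_interval[0] : t.ltr5_interval[1]]
            l3 = seq[t.ltr3_interval[0] : t.ltr3_interval[1]]
            mismatch = sum(a != b for a, b in zip(l5, l3)) / len(l5)
            expected = expected_ltr_mismatch(1.05e-9, t.age_T)
            assert abs(mismatch - expected) <= 4 * math.sqrt(
                max(expected, 0.001) / len(l5)
            )


class TestTemplates:
    def test_gypsy_orders_rt_before_int(self, gypsy_template):
        order = [name for name, _, _ in gypsy_template.domain_layout]
        assert order.index("RT") < order.index("INT")
        assert order[-1] == "CHROMO"

    def test_copia_orders_int_before_rt(self, copia_template):
        order = [name for name, _, _ in copia_template.domain_layout]
        assert order.index("INT") < order.index("RT")

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError, match="RT before INT"):
            make_family_template("X", "Gypsy", seed=0).__class__(
                family_id="X",
                ltr_sequence="A" * 200,
                internal_sequence="ACGTAC",
                domain_layout=[("INT", 0, 3), ("RT", 3, 6)],
                superfamily_truth="Gypsy",
            )


class TestAnnotationTables:
    def test_planted_counts_realized_exactly(self):
        # Feruloyl esterase: 6 of 470 secreted, 9 of 14,928 genome-wide
        table, secreted = simulate_annotation_tables(
            14_928, 470, [("GO:0030600", 6, 9)], seed=1
        )
        carriers = {g for g, t in table if t == "GO:0030600"}
        assert len(carriers) == 9
        assert len(carriers & secreted) == 6
        assert len(secreted) == 470

    def test_unplanted_secretome_term_not_enriched(self):
        table, secreted = simulate_annotation_tables(
            1_000, 100, [("GO:X", 0, 20)], seed=2, n_background_terms=0
        )
        rows = enrich_report(table, secreted)
        (row,) = [r for r in rows if r.term_id == "GO:X"]
        assert row.p_raw == 1.0

    def test_seeds_change_placement_not_counts(self):
        t1, s1 = simulate_annotation_tables(2_000, 100, [("GO:Y", 5, 8)], seed=1)
        t2, s2 = simulate_annotation_tables(2_000, 100, [("GO:Y", 5, 8)], seed=2)
        c1 = {g for g, t in t1 if t == "GO:Y"}
        c2 = {g for g, t in t2 if t == "GO:Y"}
        assert len(c1) == len(c2) == 8
        assert len(c1 & s1) == len(c2 & s2) == 5
        assert (c1, s1) != (c2, s2)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation_tables(100, 10, [("GO:Z", 5, 3)], seed=0)
        with pytest.raises(ValueError):
            simulate_annotation_tables(100, 150, [], seed=0)


class TestDomainTypes:
    def test_genome_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            Genome(records=[("a", "ACGT"), ("a", "ACGT")])
        with pytest.raises(ValueError, match="illegal"):
            Genome(records=[("a", "ACGX")])

    def test_truth_insertion_invariants(self):
        with pytest.raises(ValueError):
            TruthInsertion("f", "s", (0, 100), (50, 60), (10, 20), "ACGT", 1e6)
        with pytest.raises(ValueError):
            TruthInsertion("f", "s", (0, 100), None, None, "ACGT", -5.0)
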