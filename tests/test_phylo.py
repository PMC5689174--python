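import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from _oracles import random_additive_matrix
from retroburst.classify import scan_domains
from retroburst.phylo import (
    PeptideAlignment,
    SaturatedPairError,
    align_peptides,
    bootstrap_support,
    distance_matrix,
    extract_rt_peptides,
    nj_tree,
    root_with_outgroup,
)
from retroburst.simulate import make_family_template, make_lineage_templates

B62 = substitution_matrices.load("BLOSUM62")


class TestExtract:
    def test_verbatim_template_yields_reference_peptide(self, domain_library, gypsy_template):
        seq = gypsy_template.element_sequence
        hits = {"fam": scan_domains(seq, domain_library)}
        peptides = extract_rt_peptides({"fam": seq}, hits)
        (rt_ref,) = [p for d, _, p in domain_library.entries if d == "RT"]
        assert peptides["fam"] == rt_ref

    def test_taxon_without_rt_skipped(self, domain_library):
        peptides = extract_rt_peptides({"empty": "ACGT" * 100}, {"empty": []})
        assert peptides == {}

    def test_stop_codons_retained(self, domain_library):
        from retroburst.classify import DomainHit

        seq = "ATGTAAATG" * 30  # M * M repeated
        hit = DomainHit("RT", frame=1, start=0, end=27, score=99.0, identity=1.0)
        peptides = extract_rt_peptides({"t": seq}, {"t": [hit]})
        assert "*" in peptides["t"]


def _pairwise_profile_oracle(a, b, gap_open=-11.0, gap_extend=-1.0):
    """Plain affine NW over BLOSUM62 -- the two-sequence special case."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(B62[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open,
                          Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignPeptides:
    def test_identical_sequences_no_gaps(self):
        aln = align_peptides({"a": "MKVLITAG", "b": "MKVLITAG"})
        assert [s for _, s in aln.rows] == ["MKVLITAG", "MKVLITAG"]

    def test_two_sequences_equal_pairwise_optimum(self):
        a, b = "MKVLITAGWQERTA", "MKVITAGWQRTA"
        aln = align_peptides({"a": a, "b": b}, trim_gap_fraction=1.0)
        rows = dict(aln.rows)
        score = 0.0
        prev = ""
        for x, y in zip(rows["a"], rows["b"]):
            if x != "-" and y != "-":
                score += float(B62[x, y])
                prev = "D"
            else:
                cur = "U" if y == "-" else "L"
                score += -1.0 if cur == prev else -11.0
                prev = cur
        assert score == pytest.approx(_pairwise_profile_oracle(a, b))

    def test_gappy_columns_trimmed(self):
        peptides = {
            "a": "MKKKKVLWWWW",
            "b": "MVLWWWW",
            "c": "MVLWWWW",
            "d": "MVLWWWW",
        }
        aln = align_peptides(peptides)
        # the KKKK insertion exists in 1 of 4 rows -> columns dropped
        assert aln.n_columns == 7
        assert all("-" not in s for _, s in aln.rows)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            align_peptides({"a": "MKV"})


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = PeptideAlignment(rows=[("a", "MKVW"), ("b", "MKVW"), ("c", "MKVW")])
        _, D = distance_matrix(aln)
        assert np.allclose(D, 0.0)

    def test_poisson_correction_value(self):
        row = "A" * 9 + "C"  # p = 0.1 against all-A
        aln = PeptideAlignment(rows=[("a", "A" * 10), ("b", row), ("c", "A" * 10)])
        _, D = distance_matrix(aln)
        assert D[0, 1] == pytest.approx(-math.log(0.9), abs=1e-12)
        assert D[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_symmetric_zero_diagonal(self, rng):
        rows = [
            (f"t{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50)))
            for i in range(5)
        ]
        _, D = distance_matrix(PeptideAlignment(rows=rows))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_saturated_pair_is_inf(self):
        aln = PeptideAlignment(rows=[("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA")])
        _, D = distance_matrix(aln)
        assert math.isinf(D[0, 1])


class TestNeighborJoining:
    def test_four_taxon_quartet_recovered(self):
        taxa = ["A", "B", "C", "D"]
        #     A   B   C   D      additive for ((A,B),(C,D))
        D = np.array([
            [0.0, 0.3, 1.0, 1.1],
            [0.3, 0.0, 1.1, 1.2],
            [1.0, 1.1, 0.0, 0.3],
            [1.1, 1.2, 0.3, 0.0],
        ])
        tree = nj_tree(taxa, D)
        assert frozenset({"C", "D"}) in tree.bipartitions()

    def test_three_taxon_branch_lengths(self):
        taxa = ["A", "B", "C"]
        D = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]])
        tree = nj_tree(taxa, D)
        center = next(n for n in tree.adjacency if n not in tree.leaves)
        lengths = {n: l for n, l in tree.adjacency[center]}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.3)
        assert lengths["C"] == pytest.approx(0.5)

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_additive_matrix_recovery(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            taxa, D, splits = random_additive_matrix(n_taxa, rng)
            tree = nj_tree(taxa, D)
            assert tree.bipartitions() == splits

    def test_permutation_invariance(self):
        rng = np.random.default_rng(31)
        taxa, D, _ = random_additive_matrix(7, rng)
        tree1 = nj_tree(taxa, D)
        perm = list(rng.permutation(len(taxa)))
        taxa_p = [taxa[i] for i in perm]
        D_p = D[np.ix_(perm, perm)]
        tree2 = nj_tree(taxa_p, D_p)
        assert tree1.bipartitions() == tree2.bipartitions()
        assert tree1.newick() == tree2.newick()

    def test_saturated_distance_rejected(self):
        D = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(SaturatedPairError):
            nj_tree(["a", "b", "c"], D)


class TestBootstrap:
    @pytest.fixture()
    def clean_alignment(self, rng):
        # long, conflict-free alignment: two groups separated at 40% of
        # the columns (high but unsaturated divergence)
        block_a = "".join(rng.choice(list("ACDEFGHIK"), size=120))
        block_b = "".join(
            ("L" if rng.random() < 0.4 else ch) for ch in block_a
        )
        def variant(block, positions):
            out = list(block)
            for p in positions:
                out[p] = "W"
            return "".join(out)
        return PeptideAlignment(rows=[
            ("a1", variant(block_a, [0])),
            ("a2", variant(block_a, [1])),
            ("b1", variant(block_b, [0])),
            ("b2", variant(block_b, [1])),
        ])

    def test_congruent_signal_full_support(self, clean_alignment):
        tree = bootstrap_support(clean_alignment, n_replicates=50, seed=3)
        assert tree.supports
        assert all(s == 1.0 for s in tree.supports.values())

    def test_single_replicate_support_zero_or_one(self, clean_alignment):
        tree = bootstrap_support(clean_alignment, n_replicates=1, seed=4)
        assert set(tree.supports.values()) <= {0.0, 1.0}

    def test_seed_determinism(self, clean_alignment):
        t1 = bootstrap_support(clean_alignment, n_replicates=25, seed=9)
        t2 = bootstrap_support(clean_alignment, n_replicates=25, seed=9)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_taxon_order_invariance(self, clean_alignment):
        reordered = PeptideAlignment(rows=list(reversed(clean_alignment.rows)))
        t1 = bootstrap_support(clean_alignment, n_replicates=25, seed=9)
        t2 = bootstrap_support(reordered, n_replicates=25, seed=9)
        assert t1.supports == t2.supports


class TestRooting:
    def _quartet_tree(self):
        taxa = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.3, 1.0, 1.1],
            [0.3, 0.0, 1.1, 1.2],
            [1.0, 1.1, 0.0, 0.3],
            [1.1, 1.2, 0.3, 0.0],
        ])
        return nj_tree(taxa, D)

    def test_outgroup_sister_to_rest(self):
        tree = root_with_outgroup(self._quartet_tree(), "D")
        assert tree.root is not None
        children = [n for n, _ in tree.adjacency[tree.root]]
        assert "D" in children
        other = next(n for n in children if n != "D")
        assert tree._side_leaves(other, tree.root) == {"A", "B", "C"}

    def test_idempotent(self):
        once = root_with_outgroup(self._quartet_tree(), "D")
        twice = root_with_outgroup(once, "D")
        assert once.newick() == twice.newick()

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown outgroup"):
            root_with_outgroup(self._quartet_tree(), "Z")

    def test_planted_lineages_are_monophyletic(self, domain_library):
        seqs = {}
        for t in make_lineage_templates("A", "Gypsy", 3, seed=1, library=domain_library):
            seqs[t.family_id] = t.element_sequence
        for t in make_lineage_templates("B", "Gypsy", 3, seed=2, library=domain_library):
            seqs[t.family_id] = t.element_sequence
        out = make_family_template("OUT", "Gypsy", seed=999, peptide_divergence=0.5,
                                   library=domain_library)
        seqs["OUT"] = out.element_sequence
        hits = {k: scan_domains(s, domain_library) for k, s in seqs.items()}
        peptides = extract_rt_peptides(seqs, hits)
        aln = align_peptides(peptides)
        taxa, D = distance_matrix(aln)
        tree = root_with_outgroup(nj_tree(taxa, D), "OUT")
        bps = tree.bipartitions()
        assert frozenset({"A_1", "A_2", "A_3"}) in bps or \
            frozenset({"B_1", "B_2", "B_3", "OUT"}) in bps
        assert frozenset({"B_1", "B_2", "B_3"}) in bps or \
            frozenset({"A_1", "A_2", "A_3", "OUT"}) in bps
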