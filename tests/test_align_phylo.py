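import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import brute_force_global_score, random_additive_case
from srnase.align_phylo import (
    BootstrapConfig,
    DistanceMatrix,
    bootstrap_supports,
    classify_by_clade,
    distance_matrix,
    global_align,
    matrix_extremes,
    nj_build,
    p_distance,
    percent_similarity,
    poisson_distance,
    root_with_outgroup,
    similarity_matrix,
    tree_bipartitions,
)
from srnase.io_formats import SequenceRecord, read_matrix_tsv

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def prot(seq, name="p"):
    return SequenceRecord(name, seq, alphabet="protein")


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align(prot("ACDE", "a"), prot("ACDE", "b"))
        assert aln.a_aligned == aln.b_aligned == "ACDE"
        assert percent_similarity(aln.a_aligned, aln.b_aligned) == 100.0

    def test_single_deletion(self):
        aln = global_align(prot("ACDE", "a"), prot("ACE", "b"))
        assert len(aln.a_aligned) == 4
        assert aln.b_aligned.count("-") == 1
        matched = sum(
            x == y for x, y in zip(aln.a_aligned, aln.b_aligned) if y != "-"
        )
        assert matched == 3

    def test_degapping_recovers_inputs(self):
        aln = global_align(prot("MKWVC", "a"), prot("MWVAC", "b"))
        assert aln.a_aligned.replace("-", "") == "MKWVC"
        assert aln.b_aligned.replace("-", "") == "MWVAC"

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            global_align(prot("-", "a"), prot("ACD", "b"))

    def test_score_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            expected = brute_force_global_score(a, b, BLOSUM62)
            got = global_align(prot(a, "a"), prot(b, "b")).score
            assert got == pytest.approx(expected)


class TestSimilarity:
    def test_identical_pair(self):
        m = similarity_matrix([prot("MKWVC", "a"), prot("MKWVC", "b")])
        assert m.get("a", "b") == 100.0

    def test_one_in_ten_differs(self):
        assert percent_similarity("ACDEFGHIKL", "ACDEFGHIKV") == 90.0

    def test_pairwise_deletion_of_gap_columns(self):
        assert percent_similarity("AC-EF", "ACD-F") == 100.0

    def test_symmetric_and_permutation_equivariant(self, panel):
        sub = panel[:5]
        m = similarity_matrix(sub)
        assert np.allclose(m.values, m.values.T)
        shuffled = [sub[i] for i in (3, 0, 4, 1, 2)]
        m2 = similarity_matrix(shuffled)
        for a in m.row_labels:
            for b in m.row_labels:
                assert m.get(a, b) == pytest.approx(m2.get(a, b))


class TestExtremes:
    def test_published_matrix_extremes(self):
        from srnase.cli_pipeline import _data_path

        m = read_matrix_tsv(_data_path("similarity_16srnases.tsv"),
                            symmetric=True, diagonal_fill=100.0)
        ext = matrix_extremes(m)
        assert (ext.min_value, ext.max_value) == (32.9, 94.5)
        assert ("So1", "So2") in ext.min_pairs
        assert ("Ss3", "Ss10") in ext.max_pairs
        sten = matrix_extremes(m, subset=[
            "Ss1", "Ss2", "Ss3", "Ss4", "Ss5", "Ss6", "Ss7", "Ss8",
            "Ss9p1", "Ss10"])
        assert sten.min_value == 33.1
        assert ("Ss2", "Ss3") in sten.min_pairs

    def test_identity_matrix(self):
        from srnase.io_formats import TabularMatrix

        m = TabularMatrix(["a", "b"], ["a", "b"],
                          np.full((2, 2), 100.0))
        ext = matrix_extremes(m)
        assert (ext.min_value, ext.max_value) == (100.0, 100.0)

    def test_small_subset_error(self, panel):
        m = similarity_matrix(panel[:3])
        with pytest.raises(ValueError):
            matrix_extremes(m, subset=[panel[0].id])


class TestPoisson:
    def test_identical_gives_zero(self):
        assert poisson_distance("ACDE", "ACDE") == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.5])
    def test_closed_form(self, p):
        n = 10
        k = int(p * n)
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        assert poisson_distance(a, b) == pytest.approx(-math.log(1 - p))

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance("AAAA", "CCCC")

    def test_zero_comparable_error(self):
        with pytest.raises(ValueError):
            poisson_distance("A-", "-A")

    def test_correction_inflates(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            a = "".join(rng.choice(list("ACDE"), size=n))
            b = "".join(rng.choice(list("ACDE"), size=n))
            p = p_distance(a, b)
            if p >= 1.0:
                continue
            d = poisson_distance(a, b)
            assert d >= p
            assert (d == p) == (p == 0.0)

    def test_complete_vs_pairwise_deletion(self):
        recs = [prot("ACD-F", "a"), prot("ACDEF", "b"), prot("GCDEF", "c")]
        complete = distance_matrix(recs, deletion="complete")
        pairwise = distance_matrix(recs, deletion="pairwise")
        # b vs c differ at column 1 only: 1/4 after complete deletion
        # (the column gapped in `a` is dropped panel-wide), 1/5 pairwise
        i, j = 1, 2
        assert complete.values[i, j] == pytest.approx(-math.log(1 - 1 / 4))
        assert pairwise.values[i, j] == pytest.approx(-math.log(1 - 1 / 5))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        values = np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc],
                           [d_ac, d_bc, 0]])
        tree = nj_build(DistanceMatrix(labels, values))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_recovers_additive_tree_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            labels, dm, true_splits = random_additive_case(rng, n)
            tree = nj_build(DistanceMatrix(labels, dm))
            assert tree_bipartitions(tree) == true_splits
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                            dm[i, j], abs=1e-9)

    def test_tied_ultrametric_is_deterministic(self):
        values = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        labels = ["a", "b", "c", "d"]
        t1 = nj_build(DistanceMatrix(labels, values))
        t2 = nj_build(DistanceMatrix(labels, values))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert tree_bipartitions(t1) == {frozenset({"a", "b"})}

    def test_asymmetric_input_error(self):
        values = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            nj_build(DistanceMatrix(["a", "b", "c"], values))

    def test_matches_independent_nj_on_random_matrices(self):
        # scikit-bio's neighbour joining as the independent oracle
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            raw = rng.random((n, n))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0)
            labels = [f"T{i}" for i in range(n)]
            mine = tree_bipartitions(
                nj_build(DistanceMatrix(labels, values)))
            sk_tree = sk_nj(SkDM(values, labels))
            theirs = set()
            names = frozenset(labels)
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    comp = names - side
                    theirs.add(min(side, comp,
                                   key=lambda s: (len(s), sorted(s))))
            assert mine == theirs


@pytest.fixture(scope="module")
def clean_alignment(panel):
    # two identical sequences among well-separated taxa
    twin = SequenceRecord("twin", panel[0].residues, alphabet="protein")
    return [panel[0], twin] + panel[1:5]


class TestBootstrap:
    def test_identical_pair_has_full_support(self, clean_alignment):
        tree = bootstrap_supports(clean_alignment,
                                  BootstrapConfig(B=100, seed=3))
        cherry = frozenset({clean_alignment[0].id, "twin"})
        assert tree.bipartition_supports[cherry] == 100.0

    def test_supports_in_range_and_reproducible(self, clean_alignment):
        cfg = BootstrapConfig(B=50, seed=4)
        t1 = bootstrap_supports(clean_alignment, cfg)
        t2 = bootstrap_supports(clean_alignment, cfg)
        assert t1.bipartition_supports == t2.bipartition_supports
        assert all(0 <= v <= 100 for v in t1.bipartition_supports.values())
        t3 = bootstrap_supports(clean_alignment, BootstrapConfig(B=50, seed=5))
        assert set(t3.bipartition_supports) >= {
            frozenset({clean_alignment[0].id, "twin"})}

    def test_unanimous_signal_converges(self, panel, slike_panels):
        # a clean two-group alignment: the group split is near-certain
        recs = panel[:4] + slike_panels[0][:4]
        tree = bootstrap_supports(recs, BootstrapConfig(B=200, seed=6))
        split = frozenset(r.id for r in panel[:4])
        assert tree.bipartition_supports[split] >= 99.0


class TestRooting:
    def test_single_leaf_outgroup(self):
        labels = ["in1", "in2", "in3", "out"]
        values = np.array([
            [0, 0.2, 0.4, 1.0],
            [0.2, 0, 0.4, 1.0],
            [0.4, 0.4, 0, 1.0],
            [1.0, 1.0, 1.0, 0],
        ])
        tree = nj_build(DistanceMatrix(labels, values))
        rooted = root_with_outgroup(tree, ["out"])
        children = rooted.seed_node.child_nodes()
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"out"} in sides

    def test_multi_leaf_outgroup_makes_ingroup_monophyletic(
            self, panel, reference_panels):
        recs = panel[:5] + reference_panels["S_like_I"][:3]
        tree = bootstrap_supports(recs, BootstrapConfig(B=10, seed=1))
        outgroup = [r.id for r in reference_panels["S_like_I"][:3]]
        rooted = root_with_outgroup(tree, outgroup)
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert set(outgroup) in sides

    def test_scattered_outgroup_is_error(self):
        labels = ["a", "b", "c", "d"]
        # additive tree pairing (a,c) and (b,d): {a,b} is not a clade
        values = np.array([
            [0, 1.0, 0.2, 1.0],
            [1.0, 0, 1.0, 0.2],
            [0.2, 1.0, 0, 1.0],
            [1.0, 0.2, 1.0, 0],
        ])
        tree = nj_build(DistanceMatrix(labels, values))
        with pytest.raises(ValueError, match="not cohesive"):
            root_with_outgroup(tree, ["a", "b"])


@pytest.fixture(scope="module")
def labelled_refs(reference_panels):
    return (
        [(r, "S_RNase_III") for r in reference_panels["S_RNase_III"]]
        + [(r, "S_like_I") for r in reference_panels["S_like_I"]]
        + [(r, "S_like_II") for r in reference_panels["S_like_II"]]
    )


class TestCladeClassification:
    def test_class_iii_candidate(self, panel, labelled_refs,
                                 reference_panels):
        cls, support = classify_by_clade(
            panel[0], labelled_refs, BootstrapConfig(B=100, seed=2),
            outgroup=reference_panels["outgroup"])
        assert cls == "S_RNase_III"
        assert support >= 50

    def test_candidate_equal_to_reference_gets_its_class(
            self, labelled_refs, reference_panels):
        ref = reference_panels["S_like_II"][0]
        candidate = SequenceRecord("query", ref.residues, alphabet="protein")
        cls, support = classify_by_clade(
            candidate, labelled_refs, BootstrapConfig(B=100, seed=2),
            outgroup=reference_panels["outgroup"])
        assert cls == "S_like_II"
        assert support == 100.0

    def test_too_few_references_error(self, panel):
        refs = [(panel[1], "S_RNase_III"), (panel[2], "S_like_I"),
                (panel[3], "S_like_I")]
        with pytest.raises(ValueError, match="2 references"):
            classify_by_clade(panel[0], refs)
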