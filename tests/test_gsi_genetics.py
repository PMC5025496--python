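import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from srnase.gsi_genetics import (
    FULLY_COMPATIBLE,
    INCOMPATIBLE,
    SEMI_COMPATIBLE,
    UNKNOWN,
    DiallelObservation,
    SGenotype,
    check_progeny_consistency,
    classify_cross,
    collapse_identical_alleles,
    deduce_genotype_from_clones,
    infer_diallel_relationships,
    predict_progeny_distribution,
    simulate_cross,
    test_segregation_1to1 as segregation_1to1,
)

ALLELES = ["S1", "S2", "S3", "S4", "S5", "S6"]

# strict GSI populations contain only heterozygous diploids: a
# homozygote would require acceptance of self-matching pollen
genotype_st = (
    st.tuples(st.sampled_from(ALLELES), st.sampled_from(ALLELES))
    .filter(lambda ab: ab[0] != ab[1])
    .map(lambda ab: SGenotype(*ab))
)


class TestCrossClassification:
    def test_shared_genotype_is_incompatible(self):
        out = classify_cross(SGenotype("S1", "S2"), SGenotype("S1", "S2"))
        assert out.cross_class == INCOMPATIBLE
        assert out.accepted_pollen == ()
        assert out.progeny_distribution == {}

    def test_one_shared_allele_is_semi_compatible(self):
        out = classify_cross(SGenotype("S1", "S2"), SGenotype("S1", "S5"))
        assert out.cross_class == SEMI_COMPATIBLE
        assert out.progeny_distribution == {
            SGenotype("S1", "S5"): 0.5,
            SGenotype("S2", "S5"): 0.5,
        }

    def test_disjoint_genotypes_are_fully_compatible(self):
        out = classify_cross(SGenotype("S1", "S2"), SGenotype("S3", "S4"))
        assert out.cross_class == FULLY_COMPATIBLE
        assert len(out.progeny_distribution) == 4
        assert all(
            p == 0.25 for p in out.progeny_distribution.values())

    def test_order_independence(self):
        assert predict_progeny_distribution(
            SGenotype("S1", "S2"), SGenotype("S2", "S1")) == {}

    def test_self_cross_is_empty(self):
        assert predict_progeny_distribution(
            SGenotype("S1", "S2"), SGenotype("S1", "S2")) == {}

    def test_unknown_pistil_is_error(self):
        with pytest.raises(ValueError, match="pistil"):
            classify_cross(SGenotype("S1", UNKNOWN), SGenotype("S1", "S2"))

    def test_unknown_pollen_enumerates_alternatives(self):
        out = classify_cross(SGenotype("S1", "S2"), SGenotype("S3", UNKNOWN))
        assert out.uncertain
        assert out.cross_class == FULLY_COMPATIBLE  # unknown matches nothing
        classes = {alt.cross_class for alt in out.alternatives}
        assert classes == {SEMI_COMPATIBLE}  # if unknown were S1 or S2

    @settings(deadline=None, max_examples=100)
    @given(genotype_st, genotype_st)
    def test_incompatibility_is_reciprocal(self, g1, g2):
        c12 = classify_cross(g1, g2).cross_class
        c21 = classify_cross(g2, g1).cross_class
        assert (c12 == INCOMPATIBLE) == (c21 == INCOMPATIBLE)

    @settings(deadline=None, max_examples=100)
    @given(genotype_st, genotype_st)
    def test_progeny_distribution_invariants(self, pistil, pollen):
        out = classify_cross(pistil, pollen)
        dist = out.progeny_distribution
        if dist:
            assert sum(dist.values()) == pytest.approx(1.0)
        rejected = set(pollen.alleles) & set(pistil.alleles)
        for geno in dist:
            # no progeny carries a rejected pollen haplotype as the
            # non-pistil allele
            non_pistil = set(geno.alleles) - set(pistil.alleles)
            assert not (non_pistil & rejected)


class TestSimulation:
    def test_incompatible_cross_sets_nothing(self):
        progeny, obs = simulate_cross(
            SGenotype("S1", "S2"), SGenotype("S1", "S2"), 50, seed=0)
        assert progeny == [] and obs.berry_set is False
        assert obs.seeds_per_berry is None

    def test_semi_cross_frequencies_within_binomial_bound(self):
        n = 10_000
        progeny, _ = simulate_cross(
            SGenotype("S1", "S2"), SGenotype("S1", "S5"), n, seed=123)
        count = sum(1 for g in progeny if g == SGenotype("S1", "S5"))
        sd = math.sqrt(n * 0.25)
        assert abs(count - n / 2) <= 3 * sd

    def test_same_seed_reproduces(self):
        a = simulate_cross(SGenotype("S1", "S2"), SGenotype("S3", "S4"),
                           100, seed=7)
        b = simulate_cross(SGenotype("S1", "S2"), SGenotype("S3", "S4"),
                           100, seed=7)
        assert a == b


def okadae_pattern():
    """The published diallel pattern: selfs fail, one accession pair
    fails reciprocally, everything else sets berries."""
    accs = ["OKA1", "OKA3", "OKA5", "OKA7", "OKA9"]
    same = {("OKA1", "OKA3"), ("OKA3", "OKA1")}
    obs = []
    for f in accs:
        for m in accs:
            fails = f == m or (f, m) in same
            obs.append(DiallelObservation(f, m, not fails,
                                          90.0 if not fails else None))
    return obs


class TestDiallelInference:
    def test_published_pattern_recovers_partition(self):
        inf = infer_diallel_relationships(okadae_pattern())
        assert [sorted(c) for c in inf.classes] == [
            ["OKA1", "OKA3"], ["OKA5"], ["OKA7"], ["OKA9"]]
        assert all(not sc for sc in inf.self_compatible.values())
        assert inf.conflicts == []

    def test_all_successful_crosses_flag_self_compatibility(self):
        obs = [
            DiallelObservation(f, m, True, 50.0)
            for f in ("A", "B") for m in ("A", "B")
        ]
        inf = infer_diallel_relationships(obs)
        assert inf.self_compatible == {"A": True, "B": True}
        assert len(inf.classes) == 2

    def test_one_direction_failure_is_a_conflict(self):
        obs = okadae_pattern()
        # flip one direction of a compatible pair
        for o in obs:
            if (o.female, o.male) == ("OKA5", "OKA9"):
                obs[obs.index(o)] = DiallelObservation(
                    "OKA5", "OKA9", False)
        inf = infer_diallel_relationships(obs)
        assert any("OKA5" in c and "OKA9" in c for c in inf.conflicts)

    def test_missing_self_is_error(self):
        obs = [DiallelObservation("A", "B", True, 10.0)]
        with pytest.raises(ValueError, match="self"):
            infer_diallel_relationships(obs)

    def test_missing_reciprocal_left_unjoined(self):
        obs = [
            DiallelObservation("A", "A", False),
            DiallelObservation("B", "B", False),
            DiallelObservation("A", "B", False),
        ]
        inf = infer_diallel_relationships(obs)
        assert [sorted(c) for c in inf.classes] == [["A"], ["B"]]
        assert ("A", "B") in inf.partial_pairs

    @settings(deadline=None, max_examples=25)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.lists(genotype_st, min_size=2, max_size=8),
    )
    def test_roundtrip_recovers_planted_partition(self, seed, genotypes):
        accessions = {f"A{i}": g for i, g in enumerate(genotypes)}
        obs = []
        for i, (fa, fg) in enumerate(accessions.items()):
            for j, (ma, mg) in enumerate(accessions.items()):
                _, o = simulate_cross(fg, mg, 0,
                                      seed=seed + 31 * i + j)
                obs.append(DiallelObservation(fa, ma, o.berry_set,
                                              o.seeds_per_berry))
        inf = infer_diallel_relationships(obs)
        planted = {}
        for acc, g in accessions.items():
            planted.setdefault(str(g), set()).add(acc)
        assert sorted(map(sorted, inf.classes)) == sorted(
            map(sorted, planted.values()))
        assert all(not sc for sc in inf.self_compatible.values())
        assert inf.conflicts == []


class TestGenotypeDeduction:
    def test_two_alleles(self):
        assert deduce_genotype_from_clones(
            {"So1": 7, "So4": 2}) == SGenotype("So1", "So4")

    def test_one_allele_gives_unknown_partner(self):
        g = deduce_genotype_from_clones({"So3": 10})
        assert g == SGenotype("So3", UNKNOWN) and g.has_unknown

    def test_three_alleles_violate_diploidy(self):
        with pytest.raises(ValueError, match="diploid"):
            deduce_genotype_from_clones({"a": 1, "b": 1, "c": 1})


class TestCollapse:
    def test_declared_identity_among_seventeen_labels(self):
        labels = (
            [f"So{i}" for i in range(1, 6)]
            + [f"Ss{i}" for i in range(1, 11)]
            + ["Sp1", "Sp2"]
        )
        assert len(labels) == 17
        groups = [["Ss9", "Sp1"]] + [
            [lab] for lab in labels if lab not in ("Ss9", "Sp1")]
        uniques, renaming = collapse_identical_alleles(identities=groups)
        assert len(uniques) == 16
        assert renaming["Ss9"] == renaming["Sp1"] == "Sp1/Ss9"

    def test_panel_collapse_by_sequence(self, study_bundle):
        uniques, _ = collapse_identical_alleles(panel=study_bundle.proteins)
        assert len(uniques) == len(study_bundle.proteins) - 1

    def test_three_way_identity(self):
        uniques, renaming = collapse_identical_alleles(
            identities=[["a", "b", "c"]])
        assert uniques == ["a/b/c"]

    def test_no_identities_keeps_count(self):
        uniques, _ = collapse_identical_alleles(identities=[["x"], ["y"]])
        assert uniques == ["x", "y"]


class TestProgenyConsistency:
    def cohort(self, counts):
        out = []
        for (a, b), n in counts.items():
            out += [SGenotype(a, b)] * n
        return out

    def test_semi_compatible_cohort_is_fully_consistent(self):
        seg = check_progeny_consistency(
            SGenotype("S1", "S2"), SGenotype("S1", "S5"),
            self.cohort({("S1", "S5"): 13, ("S2", "S5"): 17}))
        assert sum(seg.observed.values()) == 30
        assert seg.off_class == 0 and seg.non_parental == 0

    def test_rejected_haplotype_is_off_class(self):
        seg = check_progeny_consistency(
            SGenotype("S1", "S2"), SGenotype("S1", "S5"),
            self.cohort({("S1", "S5"): 10, ("S1", "S1"): 1}))
        assert seg.off_class == 1

    def test_foreign_allele_is_non_parental(self):
        seg = check_progeny_consistency(
            SGenotype("S1", "S2"), SGenotype("S1", "S5"),
            self.cohort({("S1", "S5"): 10, ("S9", "S9"): 1}))
        assert seg.non_parental == 1 and seg.off_class == 0

    def test_unknown_parent_is_error(self):
        with pytest.raises(ValueError):
            check_progeny_consistency(
                SGenotype("S1", UNKNOWN), SGenotype("S1", "S5"), [])


class TestSegregation1to1:
    def test_balanced_counts_give_p_one(self):
        assert segregation_1to1(15, 15).p_value == 1.0

    def test_thirteen_seventeen_matches_tail_sum(self):
        expected = min(1.0, 2 * sum(
            math.comb(30, k) for k in range(14)) / 2**30)
        assert segregation_1to1(13, 17).p_value == pytest.approx(
            expected, rel=1e-12)
        # and the scipy tail agrees with the explicit sum
        assert binom.cdf(13, 30, 0.5) == pytest.approx(
            sum(math.comb(30, k) for k in range(14)) / 2**30)

    def test_extreme_counts(self):
        assert segregation_1to1(0, 30).p_value == pytest.approx(
            2.0**-29)

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            segregation_1to1(0, 0)
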