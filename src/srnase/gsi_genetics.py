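"""The gametophytic self-incompatibility (GSI) genetics engine.

Under S-RNase GSI a haploid pollen grain is rejected whenever its S-allele
matches either allele of the diploid pistil. Crosses therefore fall into
three classes by how many pollen haplotypes are accepted: INCOMPATIBLE
(both shared), SEMI_COMPATIBLE (one shared — progeny segregate 1:1 over
two genotype classes) and FULLY_COMPATIBLE (none shared — four classes at
1/4 each). This module classifies crosses, predicts and simulates progeny,
infers genotype-identity partitions from diallel berry-set data, deduces
genotypes from cloned-allele tallies, and tests progeny cohorts for
consistency and 1:1 segregation (exact binomial).

A cross is scored compatible iff it sets berries; seed counts never
separate semi- from full compatibility (the two are not distinguishable
by seed set when pollen is in excess).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

__all__ = [
    "UNKNOWN",
    "SGenotype",
    "CrossOutcome",
    "DiallelObservation",
    "PartitionInference",
    "SegregationTest",
    "classify_cross",
    "predict_progeny_distribution",
    "simulate_cross",
    "infer_diallel_relationships",
    "deduce_genotype_from_clones",
    "collapse_identical_alleles",
    "check_progeny_consistency",
    "test_segregation_1to1",
]

#: Marker for an allele that is known to exist but was never cloned.
UNKNOWN = "?"

INCOMPATIBLE = "INCOMPATIBLE"
SEMI_COMPATIBLE = "SEMI_COMPATIBLE"
FULLY_COMPATIBLE = "FULLY_COMPATIBLE"


@dataclass(frozen=True)
class SGenotype:
    """An unordered diploid S-allele pair; the second member may be the
    Unknown marker (an allele that escaped cloning)."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == UNKNOWN:
            raise ValueError("first allele must be known")
        # canonical order so (a,b) == (b,a); Unknown sorts last
        a, b = self.a, self.b
        if b != UNKNOWN and (a > b):
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def has_unknown(self) -> bool:
        return self.b == UNKNOWN

    def __str__(self) -> str:
        return f"{self.a}/{self.b}"


@dataclass
class CrossOutcome:
    cross_class: str
    accepted_pollen: tuple[str, ...]
    progeny_distribution: dict[SGenotype, float]
    uncertain: bool = False
    alternatives: list["CrossOutcome"] = field(default_factory=list)

    def __post_init__(self) -> None:
        empty = not self.accepted_pollen
        if (self.cross_class == INCOMPATIBLE) != empty:
            raise ValueError("class INCOMPATIBLE iff no pollen accepted")
        if self.progeny_distribution:
            total = sum(self.progeny_distribution.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError("progeny probabilities must sum to 1")


@dataclass
class DiallelObservation:
    female: str
    male: str
    berry_set: bool
    seeds_per_berry: float | None = None

    def __post_init__(self) -> None:
        if self.seeds_per_berry is not None and not self.berry_set:
            raise ValueError("seeds_per_berry present without berry set")


def _accepted(pistil: SGenotype, pollen_allele: str) -> bool:
    # Unknown pollen alleles are handled by the caller; a known pollen
    # allele is rejected iff it matches either pistil allele.
    return pollen_allele not in pistil.alleles


def classify_cross(pistil: SGenotype, pollen: SGenotype) -> CrossOutcome:
    """Classify a cross and derive its progeny genotype distribution.

    A pollen haplotype is accepted iff it differs from both pistil
    alleles; each accepted haplotype combines with each pistil allele at
    equal probability (gametophytic control, no distortion). The pistil
    genotype must be fully known. A pollen genotype containing the
    Unknown marker yields an uncertainty-flagged outcome enumerating both
    possibilities (Unknown matching nothing vs. the worst case of the
    given known alleles).
    """
    if pistil.has_unknown:
        raise ValueError("cannot classify a cross with unknown pistil allele")
    if pollen.has_unknown:
        # Unknown matches nothing known: treat it as a private allele for
        # the primary outcome, and enumerate the alternative where it
        # coincides with each pistil allele.
        primary = _classify_known(pistil, SGenotype(pollen.a, "@unknown@"))
        alternatives = []
        for assumed in pistil.alleles:
            if assumed != pollen.a:
                alternatives.append(
                    _classify_known(pistil, SGenotype(pollen.a, assumed))
                )
        primary.uncertain = True
        primary.alternatives = alternatives
        return primary
    return _classify_known(pistil, pollen)


def _classify_known(pistil: SGenotype, pollen: SGenotype) -> CrossOutcome:
    accepted = tuple(
        al for al in pollen.alleles if _accepted(pistil, al)
    )
    n = len(accepted)
    cross_class = (INCOMPATIBLE, SEMI_COMPATIBLE, FULLY_COMPATIBLE)[n]
    dist: dict[SGenotype, float] = {}
    if n:
        p = 1.0 / (2 * n)
        for pollen_allele in accepted:
            name = (
                pollen_allele if not pollen_allele.startswith("@")
                else UNKNOWN
            )
            for pistil_allele in pistil.alleles:
                if name == UNKNOWN:
                    geno = SGenotype(pistil_allele, UNKNOWN)
                else:
                    geno = SGenotype(pistil_allele, name)
                dist[geno] = dist.get(geno, 0.0) + p
    return CrossOutcome(cross_class, accepted, dist)


def predict_progeny_distribution(pistil: SGenotype, pollen: SGenotype
                                 ) -> dict[SGenotype, float]:
    """Progeny genotype -> probability (empty for an incompatible cross)."""
    return classify_cross(pistil, pollen).progeny_distribution


def simulate_cross(pistil: SGenotype, pollen: SGenotype, n_progeny: int,
                   seed: int, seed_set_mean: float = 90.0
                   ) -> tuple[list[SGenotype], DiallelObservation]:
    """Draw progeny genotypes and a berry/seed observation for one cross.

    Progeny are i.i.d. draws from the predicted distribution; berry_set is
    true iff the cross is not incompatible, and seeds/berry follows a
    Poisson model with the configured mean. Reproducible under *seed*.
    """
    if n_progeny < 0:
        raise ValueError("n_progeny must be >= 0")
    outcome = classify_cross(pistil, pollen)
    rng = np.random.default_rng(seed)
    if outcome.cross_class == INCOMPATIBLE:
        return [], DiallelObservation(str(pistil), str(pollen), False)
    genotypes = sorted(outcome.progeny_distribution, key=str)
    probs = [outcome.progeny_distribution[g] for g in genotypes]
    draws = rng.choice(len(genotypes), size=n_progeny, p=probs)
    progeny = [genotypes[i] for i in draws]
    seeds = float(rng.poisson(seed_set_mean))
    return progeny, DiallelObservation(str(pistil), str(pollen), True, seeds)


# ---------------------------------------------------------------------------
# Diallel inference


@dataclass
class PartitionInference:
    classes: list[set[str]]  # genotype-equivalence classes
    self_compatible: dict[str, bool]
    conflicts: list[str]
    partial_pairs: list[tuple[str, str]] = field(default_factory=list)

    def class_of(self, accession: str) -> set[str]:
        for group in self.classes:
            if accession in group:
                return group
        raise KeyError(accession)


def infer_diallel_relationships(observations: list[DiallelObservation]
                                ) -> PartitionInference:
    """Infer genotype-identity classes and SI status from a diallel.

    Self-pollinations flag self-compatibility. Two accessions share a
    genotype class iff both reciprocal crosses fail; classes are closed
    transitively. A reciprocal disagreement (one direction fails, the
    other sets berries) is recorded as a conflict — GSI incompatibility
    between fully known genotypes is symmetric, so such data violate the
    model. A pair with only one direction observed is left unjoined with
    a partial-data note.
    """
    accessions = sorted(
        {o.female for o in observations} | {o.male for o in observations}
    )
    seen: dict[tuple[str, str], bool] = {}
    self_compat: dict[str, bool] = {}
    conflicts: list[str] = []
    for obs in observations:
        key = (obs.female, obs.male)
        if key in seen and seen[key] != obs.berry_set:
            conflicts.append(
                f"inconsistent repeats for {obs.female} x {obs.male}"
            )
        seen[key] = obs.berry_set
        if obs.female == obs.male:
            self_compat[obs.female] = obs.berry_set
    missing_selfs = [a for a in accessions if a not in self_compat]
    if missing_selfs:
        raise ValueError(f"missing self-pollinations for: {missing_selfs}")

    parent = {a: a for a in accessions}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    partial: list[tuple[str, str]] = []
    for i, a in enumerate(accessions):
        for b in accessions[i + 1:]:
            ab, ba = seen.get((a, b)), seen.get((b, a))
            if ab is None and ba is None:
                continue
            if ab is None or ba is None:
                if (ab is False) or (ba is False):
                    partial.append((a, b))
                continue
            if ab != ba:
                conflicts.append(
                    f"reciprocal disagreement: {a} x {b} "
                    f"{'set' if ab else 'failed'}, {b} x {a} "
                    f"{'set' if ba else 'failed'}"
                )
                continue
            if ab is False:  # both directions incompatible: same genotype
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for a in accessions:
        groups.setdefault(find(a), set()).add(a)
    classes = sorted(groups.values(), key=lambda g: sorted(g)[0])
    return PartitionInference(
        classes=classes, self_compatible=self_compat,
        conflicts=conflicts, partial_pairs=partial,
    )


def deduce_genotype_from_clones(cloned: dict[str, int]) -> SGenotype:
    """Deduce a diploid S-genotype from cloned-allele tallies.

    Two distinct alleles give the full genotype; one gives (allele,
    Unknown); more than two violate diploidy and raise.
    """
    alleles = sorted(a for a, n in cloned.items() if n > 0)
    if not alleles:
        raise ValueError("no cloned alleles")
    if len(alleles) == 1:
        return SGenotype(alleles[0], UNKNOWN)
    if len(alleles) == 2:
        return SGenotype(alleles[0], alleles[1])
    raise ValueError(
        f"{len(alleles)} distinct alleles cloned from a diploid: {alleles}"
    )


def collapse_identical_alleles(panel=None,
                               identities: list[tuple[str, ...]] | None = None
                               ) -> tuple[list[str], dict[str, str]]:
    """Merge alleles with identical deduced amino-acid sequence.

    *panel* is a list of protein SequenceRecords (identity by exact
    residue string), or *identities* declares groups of equivalent labels
    explicitly. Merged alleles get the joint name "a/b" (label-sorted).
    Returns (unique allele names, old-label -> merged-name map).
    """
    groups: list[list[str]] = []
    if panel is not None:
        by_seq: dict[str, list[str]] = {}
        order: list[str] = []
        for rec in panel:
            key = rec.residues.replace("-", "")
            if key not in by_seq:
                order.append(key)
            by_seq.setdefault(key, []).append(rec.id)
        groups = [by_seq[key] for key in order]
    elif identities is not None:
        groups = [sorted(set(g)) for g in identities]
    else:
        raise ValueError("provide a panel or explicit identity groups")
    renaming: dict[str, str] = {}
    uniques: list[str] = []
    for group in groups:
        merged = "/".join(sorted(group)) if len(group) > 1 else group[0]
        uniques.append(merged)
        for label in group:
            renaming[label] = merged
    return uniques, renaming


# ---------------------------------------------------------------------------
# Progeny consistency and segregation


@dataclass
class SegregationTest:
    observed: dict[SGenotype, int]
    off_class: int
    non_parental: int = 0
    method: str = ""
    p_value: float | None = None


def check_progeny_consistency(pistil: SGenotype, pollen: SGenotype,
                              progeny_genotypes: list[SGenotype]
                              ) -> SegregationTest:
    """Classify each progeny genotype as expected, off-class or
    non-parental.

    Off-class progeny contain a rejected pollen haplotype (e.g. S1S1 or
    S1S2 from (S1S2) x (S1S5)); progeny carrying an allele absent from
    both parents are flagged non-parental (a contamination signal), not
    off-class.
    """
    if pistil.has_unknown or pollen.has_unknown:
        raise ValueError("parental genotypes must be fully known")
    expected = set(predict_progeny_distribution(pistil, pollen))
    parental = set(pistil.alleles) | set(pollen.alleles)
    observed = {g: 0 for g in sorted(expected, key=str)}
    off = non_parental = 0
    for geno in progeny_genotypes:
        if not set(geno.alleles) <= parental:
            non_parental += 1
        elif geno in expected:
            observed[geno] += 1
        else:
            off += 1
    return SegregationTest(
        observed=observed, off_class=off, non_parental=non_parental,
        method="classification",
    )


def test_segregation_1to1(count_a: int, count_b: int) -> SegregationTest:
    """Two-sided exact binomial test of a 1:1 segregation ratio.

    p = min(1, 2 * P(X <= min(k, n-k))) under X ~ Binomial(n, 1/2).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    n = count_a + count_b
    if n == 0:
        raise ValueError("1:1 test undefined with zero progeny")
    k = min(count_a, count_b)
    p = min(1.0, 2.0 * float(binom.cdf(k, n, 0.5)))
    return SegregationTest(
        observed={}, off_class=0, method="exact_binomial_1to1", p_value=p,
    )
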