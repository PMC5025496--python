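"""Synthetic S-RNase panels, reference sets and complete study bundles.

The generator emulates the statistical structure the analysis assumes:

* S-RNase alleles share conserved blocks C1–C5 carrying invariant anchors
  (two catalytic His, eight conserved Cys — two of them upstream of C2 and
  one just after C5 — and the C2 N-glycosylation sequon) while the
  hypervariable regions and linkers are deeply divergent between alleles,
  so pairwise amino-acid similarity spans roughly 33–95 %. A few alleles
  are recent relatives of another allele, providing the high end of the
  band; the rest are independent ancient lineages, providing the low end.
* Variable positions are drawn from a lysine/arginine-biased residue pool,
  so every S-RNase allele is a basic protein (pI > 7.5) by construction.
* S-like class I and class II panels descend from their own class
  scaffolds (conserved blocks redrawn away from the S-RNase scaffold,
  anchors kept — they are T2-family-wide) with acidic variable positions,
  so they form separate clades and fail the basic-pI rubric check.
* Nucleotide sequences are back-translated with uniform random synonymous
  codons, carry a 5'/3' UTR and poly(A) tail, and every allele's C2 block
  is encoded by codons that match the degenerate C2 forward primer
  exactly, mirroring how the cloning strategy sees the transcripts.
* Study bundles plant a diploid population with one shared-genotype
  accession pair, a full diallel with selfs, and semi-compatible progeny
  cohorts of ~30, generated through the GSI engine itself.

With ``hv_divergence = 0`` no substitutions are applied anywhere and the
panel collapses to identical copies of the scaffold (a degenerate limit
used in tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from . import gsi_genetics as gsi
from .align_phylo import matrix_extremes, similarity_matrix
from .io_formats import SequenceRecord, write_fasta
from .primer_insilico import (
    SOLC2_F13,
    DegeneratePrimer,
    check_assay_specificity,
)
from .srnase_features import (
    build_domain_profile,
    classify_functional_candidate,
    compute_pI,
    profile_protein,
)

__all__ = [
    "PanelSpec",
    "StudyBundle",
    "SEGMENTS",
    "region_annotations",
    "anchor_positions",
    "make_allele_panel",
    "make_slike_panels",
    "make_outgroup",
    "make_reference_panels",
    "make_study",
    "write_bundle",
    "load_bundle",
]

# ---------------------------------------------------------------------------
# Protein layout
#
# (name, length, kind); kind "cons" blocks are near-invariant within a
# class, "var" segments are resampled between alleles. Anchors (below) are
# invariant across the whole T2 family.

SEGMENTS: tuple[tuple[str, int, str], ...] = (
    ("L0", 5, "var"),
    ("C1", 10, "cons"),
    ("L1", 8, "var"),
    ("C2", 14, "cons"),
    ("HVa", 40, "var"),
    ("L2", 4, "var"),
    ("HVb", 34, "var"),
    ("L3", 4, "var"),
    ("C3", 11, "cons"),
    ("L4", 8, "var"),
    ("C4", 10, "cons"),
    ("L5", 8, "var"),
    ("C5", 9, "cons"),
    ("CT", 10, "var"),
)

#: Codons whose first bases satisfy the degenerate C2 primer
#: TTTACNRTNCATGGNCTNTGGCC; the residues it encodes open every C2 block.
_C2_PRIMER_RESIDUES = "FTVHGLWP"

TOTAL_LENGTH = sum(length for _, length, _ in SEGMENTS)


def _segment_starts() -> dict[str, int]:
    starts, pos = {}, 1
    for name, length, _ in SEGMENTS:
        starts[name] = pos
        pos += length
    return starts


_STARTS = _segment_starts()


def region_annotations() -> dict[str, tuple[int, int]]:
    """1-based (start, end) of C1–C5 and HVa/HVb on the full-length
    protein (equal-length panel sequences share this column space)."""
    out = {}
    for name, length, _ in SEGMENTS:
        if name.startswith(("C", "HV")) and name != "CT":
            out[name] = (_STARTS[name], _STARTS[name] + length - 1)
    return out


def anchor_positions() -> dict[str, object]:
    """Invariant anchors: catalytic His, the eight conserved Cys, and the
    C2 sequon, as 1-based full-length positions."""
    c2, c3 = _STARTS["C2"], _STARTS["C3"]
    cys = [
        _STARTS["L1"] + 2, _STARTS["L1"] + 5,      # between C1 and C2
        c2 + 13,                                    # end of C2
        c3 + 2,                                     # in C3
        _STARTS["C4"] + 1, _STARTS["C4"] + 6,       # in C4
        _STARTS["C5"] + 3,                          # in C5
        _STARTS["CT"] + 1,                          # just after C5
    ]
    return {
        "his": {"C2": c2 + 3, "C3": c3 + 4},
        "cys": cys,
        "sequon": (c2 + 8, c2 + 10),  # N-A-S
    }


_ANCHORS = anchor_positions()
_ANCHOR_SET = (
    set(_ANCHORS["cys"])
    | set(_ANCHORS["his"].values())
    | set(range(_ANCHORS["sequon"][0], _ANCHORS["sequon"][1] + 1))
    | set(range(_STARTS["C2"], _STARTS["C2"] + len(_C2_PRIMER_RESIDUES)))
)

# residue pools -------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _pool(weights: dict[str, float]) -> tuple[list[str], np.ndarray]:
    residues = sorted(weights)
    w = np.array([weights[r] for r in residues], dtype=float)
    return residues, w / w.sum()


def _variable_pool(basic_bias: float, acidic: bool):
    """Residue pool for variable positions. *basic_bias* is the target
    K+R fraction; the acidic variant inverts the bias (S-like panels)."""
    others = [r for r in _AA if r not in "KRDEC"]
    if acidic:
        weights = {"D": 0.18, "E": 0.18, "K": 0.01, "R": 0.01}
        rest = 1.0 - sum(weights.values())
    else:
        weights = {"K": basic_bias / 2, "R": basic_bias / 2, "D": 0.02, "E": 0.02}
        rest = 1.0 - sum(weights.values())
    for r in others:
        weights[r] = rest / len(others)
    return _pool(weights)


_CONSERVED_POOL = _pool({r: 1.0 for r in _AA if r not in "CH"})


# ---------------------------------------------------------------------------
# Specs


@dataclass
class PanelSpec:
    """Conditions for one synthetic allele panel."""

    n_alleles: int = 16
    n_related: int = 4          # alleles derived from an earlier allele
    hv_divergence: float = 0.9  # per-site substitution prob., variable sites
    conserved_jitter: float = 0.02
    related_divergence: float = 0.12
    basic_bias: float = 0.25    # target K+R fraction at variable sites
    similarity_band: tuple[float, float] = (33.0, 95.0)
    retry_limit: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hv_divergence, self.conserved_jitter,
                  self.related_divergence, self.basic_bias):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_alleles < 2:
            raise ValueError("need >= 2 alleles")
        if self.n_related >= self.n_alleles:
            raise ValueError("n_related must leave >= 1 founder")


# ---------------------------------------------------------------------------
# Protein generation


def _make_scaffold(rng: np.random.Generator) -> list[str]:
    residues, probs = _CONSERVED_POOL
    seq = [rng.choice(residues, p=probs) for _ in range(TOTAL_LENGTH)]
    for region, pos in _ANCHORS["his"].items():
        seq[pos - 1] = "H"
    for pos in _ANCHORS["cys"]:
        seq[pos - 1] = "C"
    s0 = _ANCHORS["sequon"][0]
    seq[s0 - 1:s0 + 2] = list("NAS")
    c2 = _STARTS["C2"]
    seq[c2 - 1:c2 - 1 + len(_C2_PRIMER_RESIDUES)] = list(_C2_PRIMER_RESIDUES)
    return seq


def _variable_positions() -> list[int]:
    out = []
    pos = 1
    for name, length, kind in SEGMENTS:
        if kind == "var":
            out.extend(
                p for p in range(pos, pos + length) if p not in _ANCHOR_SET
            )
        pos += length
    return out


def _conserved_jitter_positions() -> list[int]:
    out = []
    pos = 1
    for name, length, kind in SEGMENTS:
        if kind == "cons":
            out.extend(
                p for p in range(pos, pos + length) if p not in _ANCHOR_SET
            )
        pos += length
    return out


_VAR_POS = _variable_positions()
_JITTER_POS = _conserved_jitter_positions()


def _substitute(seq: list[str], positions, prob: float,
                pool, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    residues, probs = pool
    for p in positions:
        if rng.random() < prob:
            out[p - 1] = rng.choice(residues, p=probs)
    return out


def _generate_proteins(spec: PanelSpec, scaffold: list[str],
                       rng: np.random.Generator, acidic: bool = False,
                       prefix: str = "S") -> list[SequenceRecord]:
    pool = _variable_pool(spec.basic_bias, acidic)
    n_founders = spec.n_alleles - spec.n_related
    alleles: list[list[str]] = []
    if spec.hv_divergence == 0.0:
        alleles = [list(scaffold) for _ in range(spec.n_alleles)]
    else:
        for _ in range(n_founders):
            allele = _substitute(scaffold, _VAR_POS, spec.hv_divergence,
                                 pool, rng)
            allele = _substitute(allele, _JITTER_POS, spec.conserved_jitter,
                                 pool, rng)
            alleles.append(allele)
        for i in range(spec.n_related):
            parent = alleles[int(rng.integers(0, n_founders))]
            child = _substitute(parent, _VAR_POS, spec.related_divergence,
                                pool, rng)
            child = _substitute(child, _JITTER_POS, spec.conserved_jitter,
                                pool, rng)
            alleles.append(child)
    return [
        SequenceRecord(f"{prefix}{i + 1:02d}", "".join(a), alphabet="protein")
        for i, a in enumerate(alleles)
    ]


def make_allele_panel(spec: PanelSpec) -> list[SequenceRecord]:
    """Generate a panel of functional-S-RNase proteins.

    Every allele is verified against the structural rubric (domains in
    order, catalytic His, eight conserved Cys, C2 sequon, basic pI) and
    the panel's pairwise-similarity extremes are required to fall in the
    configured band (low extreme <= 40, high extreme >= 85, both inside
    *similarity_band*); failing panels are resampled up to *retry_limit*
    times before erroring with the achieved band.
    """
    root = np.random.SeedSequence(spec.seed)
    scaffold_rng = np.random.default_rng(root.spawn(1)[0])
    scaffold = _make_scaffold(scaffold_rng)
    achieved = None
    for attempt in range(spec.retry_limit):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(attempt + 1,))
        )
        panel = _generate_proteins(spec, scaffold, rng)
        if spec.hv_divergence == 0.0:
            # degenerate limit: scaffold copies, no enforcement
            return panel
        if any(compute_pI(rec) <= 7.5 for rec in panel):
            continue
        lo, hi = spec.similarity_band
        if (lo, hi) == (0.0, 100.0):  # band enforcement disabled
            _verify_rubric(panel)
            return panel
        ext = matrix_extremes(similarity_matrix(panel))
        achieved = (ext.min_value, ext.max_value)
        if lo <= ext.min_value <= 40.0 and 85.0 <= ext.max_value <= hi:
            _verify_rubric(panel)
            return panel
    raise RuntimeError(
        f"similarity band {spec.similarity_band} not met after "
        f"{spec.retry_limit} attempts; achieved {achieved}"
    )


def _verify_rubric(panel: list[SequenceRecord]) -> None:
    profile = build_domain_profile(panel, region_annotations())
    for rec in panel:
        result = classify_functional_candidate(profile_protein(rec, profile))
        if result.verdict != "putative_S_RNase":
            raise RuntimeError(
                f"generated allele {rec.id} fails the rubric: {result.notes}"
            )


def make_slike_panels(spec: PanelSpec, n_per_class: int = 4,
                      class_divergence: float = 1.0
                      ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two S-like panels (class I-like, class II-like).

    Each class descends from its own scaffold whose conserved non-anchor
    positions were redrawn (at *class_divergence*) from the S-RNase
    scaffold; members diverge mildly within the class so the classes form
    tight, separable clades. Variable positions use the acidic pool, so
    every S-like sequence fails the basic-pI rubric check.
    """
    root = np.random.SeedSequence(spec.seed)
    scaffold_rng = np.random.default_rng(root.spawn(1)[0])
    scaffold = _make_scaffold(scaffold_rng)
    panels = []
    for class_idx, prefix in ((1, "SL1_"), (2, "SL2_")):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed,
                                   spawn_key=(100 + class_idx,))
        )
        class_scaffold = _substitute(
            scaffold, _JITTER_POS, class_divergence, _CONSERVED_POOL, rng)
        class_scaffold = _substitute(
            class_scaffold, _VAR_POS, 1.0,
            _variable_pool(spec.basic_bias, acidic=True), rng)
        sub = PanelSpec(
            n_alleles=n_per_class, n_related=0,
            hv_divergence=min(spec.hv_divergence, 0.08),
            conserved_jitter=spec.conserved_jitter,
            basic_bias=spec.basic_bias, seed=spec.seed,
        )
        panels.append(_generate_proteins(sub, class_scaffold, rng,
                                         acidic=True, prefix=prefix))
    return panels[0], panels[1]


def make_outgroup(spec: PanelSpec, n: int = 1) -> list[SequenceRecord]:
    """Deeply diverged T2-like outgroup sequences (anchors kept)."""
    root = np.random.SeedSequence(spec.seed)
    scaffold_rng = np.random.default_rng(root.spawn(1)[0])
    scaffold = _make_scaffold(scaffold_rng)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(200,))
    )
    out_scaffold = _substitute(scaffold, _JITTER_POS, 1.0,
                               _CONSERVED_POOL, rng)
    sub = PanelSpec(n_alleles=max(n, 2), n_related=0,
                    hv_divergence=min(spec.hv_divergence, 0.05),
                    conserved_jitter=spec.conserved_jitter, seed=spec.seed)
    recs = _generate_proteins(sub, out_scaffold, rng, acidic=False,
                              prefix="OUT")
    return recs[:n]


def make_reference_panels(spec: PanelSpec, n_class_iii: int = 6,
                          n_slike: int = 4, n_outgroup: int = 1
                          ) -> dict[str, list[SequenceRecord]]:
    """Labelled reference panels for clade classification."""
    ref_spec = PanelSpec(
        n_alleles=n_class_iii, n_related=0,
        hv_divergence=spec.hv_divergence,
        conserved_jitter=spec.conserved_jitter,
        basic_bias=spec.basic_bias,
        similarity_band=(0.0, 100.0),  # refs need no band enforcement
        seed=spec.seed + 7919,
    )
    scaffold_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(1)[0])
    scaffold = _make_scaffold(scaffold_rng)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(300,))
    )
    refs_iii = _generate_proteins(ref_spec, scaffold, rng, prefix="REF3_")
    slike_i, slike_ii = make_slike_panels(spec, n_per_class=n_slike)
    return {
        "S_RNase_III": refs_iii,
        "S_like_I": slike_i,
        "S_like_II": slike_ii,
        "outgroup": make_outgroup(spec, n_outgroup),
    }


# ---------------------------------------------------------------------------
# Back-translation and transcripts

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

# codon choices whose nucleotides satisfy the degenerate C2 primer
_PRIMER_CODON_TEMPLATES = {
    0: ["TTT"],                      # F
    1: ["ACA", "ACC", "ACG", "ACT"],  # T (ACN)
    2: ["GTA", "GTC", "GTG", "GTT"],  # V (RTN with R=G)
    3: ["CAT"],                      # H
    4: ["GGA", "GGC", "GGG", "GGT"],  # G (GGN)
    5: ["CTA", "CTC", "CTG", "CTT"],  # L (CTN)
    6: ["TGG"],                      # W
    7: ["CCA", "CCC", "CCG", "CCT"],  # P (CC + N)
}


def back_translate(protein: SequenceRecord, rng: np.random.Generator,
                   utr5: int = 30, utr3: int = 80, polya: int = 25
                   ) -> SequenceRecord:
    """Back-translate to a sense-strand transcript.

    Synonymous codons are drawn uniformly at random, except across the C2
    block where codons are constrained to match the degenerate C2 forward
    primer exactly. A 5' UTR, stop codon, A-poor 3' UTR and poly(A) tail
    complete the transcript.
    """
    c2_start = _STARTS["C2"]  # 1-based protein position
    codons = []
    for i, aa in enumerate(protein.residues, start=1):
        offset = i - c2_start
        if 0 <= offset < len(_C2_PRIMER_RESIDUES):
            choices = _PRIMER_CODON_TEMPLATES[offset]
        else:
            choices = _CODONS_BY_AA[aa]
        codons.append(choices[int(rng.integers(0, len(choices)))])
    non_a = list("CGT")
    utr5_seq = "".join(
        "ACGT"[int(rng.integers(0, 4))] if (k % 4) else
        non_a[int(rng.integers(0, 3))]
        for k in range(utr5)
    )
    utr3_seq = "".join(non_a[int(rng.integers(0, 3))] for _ in range(utr3))
    seq = utr5_seq + "".join(codons) + "TAA" + utr3_seq + "A" * polya
    return SequenceRecord(protein.id, seq, protein.description, "nucleotide")


def back_translate_panel(panel: list[SequenceRecord], seed: int
                         ) -> list[SequenceRecord]:
    out = []
    for i, rec in enumerate(panel):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(400 + i,))
        )
        out.append(back_translate(rec, rng))
    return out


def design_assays(nt_panel: list[SequenceRecord],
                  target_alleles: list[str], primer_len: int = 20,
                  max_product: int = 1500
                  ) -> list[tuple[str, DegeneratePrimer, DegeneratePrimer]]:
    """Allele-specific primer pairs taken from the hypervariable regions.

    Forward primers come from HVa, reverse primers from HVb (reverse
    complement); windows are slid until the assay amplifies exactly its
    own allele in the panel.
    """
    from Bio.Seq import Seq

    by_id = {rec.id: rec for rec in nt_panel}
    utr5 = 30
    hva_nt = utr5 + (_STARTS["HVa"] - 1) * 3
    hvb_nt = utr5 + (_STARTS["HVb"] - 1) * 3
    hva_len = dict(
        (name, length) for name, length, _ in SEGMENTS)["HVa"] * 3
    hvb_len = dict(
        (name, length) for name, length, _ in SEGMENTS)["HVb"] * 3
    assays = []
    for allele in target_alleles:
        seq = by_id[allele].residues
        found = None
        for shift in range(0, hva_len - primer_len, 3):
            fwd_seq = seq[hva_nt + shift:hva_nt + shift + primer_len]
            rev_window = seq[hvb_nt + shift:hvb_nt + shift + primer_len]
            rev_seq = str(Seq(rev_window).reverse_complement())
            fwd = DegeneratePrimer(f"{allele}-F", fwd_seq, "forward")
            rev = DegeneratePrimer(f"{allele}-R", rev_seq, "reverse")
            report = check_assay_specificity(
                [(allele, fwd, rev)], nt_panel, max_product)
            if report[allele] == [allele]:
                found = (allele, fwd, rev)
                break
        if found is None:
            raise RuntimeError(
                f"no specific primer pair found for allele {allele}")
        assays.append(found)
    return assays


# ---------------------------------------------------------------------------
# Study bundles


@dataclass
class StudyBundle:
    """A complete synthetic study: sequences, genotypes, diallel,
    progeny cohorts and allele-specific assays."""

    spec: PanelSpec
    proteins: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    genotypes: dict[str, gsi.SGenotype]
    diallel: list[gsi.DiallelObservation]
    progeny: dict[tuple[str, str], list[gsi.SGenotype]]
    assays: list[tuple[str, DegeneratePrimer, DegeneratePrimer]]
    duplicate_pair: tuple[str, str] | None = None
    manifest: dict = field(default_factory=dict)


#: Default population: five accessions over the first six panel alleles,
#: with ACC1/ACC2 sharing a genotype (the study's shared-genotype pair)
#: and ACC4 carrying one allele the degenerate primer never recovers.
DEFAULT_POPULATION = {
    "ACC1": ("S01", "S02"),
    "ACC2": ("S01", "S02"),
    "ACC3": ("S01", "S05"),
    "ACC4": ("S03", "S06"),
    "ACC5": ("S01", "S04"),
}

#: Semi-compatible cohorts mirroring the study design (~30 each).
DEFAULT_COHORTS = (
    ("ACC1", "ACC3", 30),
    ("ACC1", "ACC5", 29),
    ("ACC2", "ACC3", 29),
    ("ACC2", "ACC5", 28),
)


def make_study(spec: PanelSpec | None = None,
               population: dict[str, tuple[str, str]] | None = None,
               cohorts=DEFAULT_COHORTS,
               add_duplicate_allele: bool = True) -> StudyBundle:
    """Generate a complete, internally consistent study bundle.

    The default preset mirrors the study shape: a 16-allele panel (plus
    one relabelled amino-acid-identical duplicate, so 17 labels collapse
    to 16), five diploid accessions of which two share a genotype, the
    full 5x5 diallel with selfs, and four semi-compatible progeny cohorts
    of ~30 generated through the GSI engine.
    """
    spec = spec or PanelSpec()
    population = population or dict(DEFAULT_POPULATION)
    proteins = make_allele_panel(spec)
    duplicate_pair = None
    if add_duplicate_allele:
        twin_of = proteins[-1].id
        twin = SequenceRecord(
            f"S{spec.n_alleles + 1:02d}", proteins[-1].residues,
            "amino-acid-identical to " + twin_of, "protein")
        proteins = proteins + [twin]
        duplicate_pair = (twin_of, twin.id)
    transcripts = back_translate_panel(proteins, spec.seed)

    panel_ids = {rec.id for rec in proteins}
    genotypes = {}
    for acc, pair in population.items():
        missing = set(pair) - panel_ids
        if missing:
            raise ValueError(
                f"accession {acc} references unknown alleles {sorted(missing)}")
        genotypes[acc] = gsi.SGenotype(*pair)

    diallel = []
    accessions = sorted(genotypes)
    for i, female in enumerate(accessions):
        for j, male in enumerate(accessions):
            _, obs = gsi.simulate_cross(
                genotypes[female], genotypes[male], 0,
                seed=spec.seed * 10000 + i * 100 + j)
            diallel.append(gsi.DiallelObservation(
                female, male, obs.berry_set, obs.seeds_per_berry))

    progeny = {}
    for k, (female, male, n) in enumerate(cohorts):
        kids, _ = gsi.simulate_cross(
            genotypes[female], genotypes[male], n,
            seed=spec.seed * 10000 + 5000 + k)
        progeny[(female, male)] = kids

    assay_targets = sorted(
        {al for g in genotypes.values() for al in g.alleles if al != gsi.UNKNOWN}
    )
    assays = design_assays(transcripts, assay_targets)

    manifest = {
        "seed": spec.seed,
        "panel_spec": asdict(spec),
        "population": {a: list(g.alleles) for a, g in
                       sorted(genotypes.items())},
        "cohorts": [list(c) for c in cohorts],
        "duplicate_pair": list(duplicate_pair) if duplicate_pair else None,
    }
    return StudyBundle(
        spec=spec, proteins=proteins, transcripts=transcripts,
        genotypes=genotypes, diallel=diallel, progeny=progeny,
        assays=assays, duplicate_pair=duplicate_pair, manifest=manifest,
    )


def write_bundle(bundle: StudyBundle, out_dir) -> None:
    """Write a bundle directory (FASTA/TSV/JSON; byte-deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, out / "alleles_protein.fasta")
    write_fasta(bundle.transcripts, out / "alleles_cdna.fasta")
    with open(out / "genotypes.tsv", "w") as fh:
        fh.write("accession\tallele_a\tallele_b\n")
        for acc in sorted(bundle.genotypes):
            g = bundle.genotypes[acc]
            fh.write(f"{acc}\t{g.a}\t{g.b}\n")
    with open(out / "diallel.tsv", "w") as fh:
        fh.write("female\tmale\tberry_set\tseeds_per_berry\n")
        for obs in bundle.diallel:
            seeds = "" if obs.seeds_per_berry is None else (
                f"{obs.seeds_per_berry:g}")
            fh.write(f"{obs.female}\t{obs.male}\t"
                     f"{int(obs.berry_set)}\t{seeds}\n")
    with open(out / "progeny.tsv", "w") as fh:
        fh.write("female\tmale\tindividual\tallele_a\tallele_b\n")
        for (female, male), kids in sorted(bundle.progeny.items()):
            for idx, kid in enumerate(kids, start=1):
                fh.write(f"{female}\t{male}\t{female}x{male}-{idx:02d}\t"
                         f"{kid.a}\t{kid.b}\n")
    with open(out / "primers.tsv", "w") as fh:
        fh.write("allele\tname\tsequence\torientation\n")
        for allele, fwd, rev in bundle.assays:
            fh.write(f"{allele}\t{fwd.name}\t{fwd.iupac}\tforward\n")
            fh.write(f"{allele}\t{rev.name}\t{rev.iupac}\treverse\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_bundle(in_dir) -> StudyBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    from .io_formats import read_fasta, read_table_tsv

    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    spec = PanelSpec(**manifest["panel_spec"])
    spec.similarity_band = tuple(spec.similarity_band)
    proteins = read_fasta(src / "alleles_protein.fasta", alphabet="protein")
    transcripts = read_fasta(src / "alleles_cdna.fasta",
                             alphabet="nucleotide")
    genotypes = {}
    for _, row in read_table_tsv(src / "genotypes.tsv").iterrows():
        genotypes[row["accession"]] = gsi.SGenotype(
            row["allele_a"], row["allele_b"])
    diallel = []
    for _, row in read_table_tsv(src / "diallel.tsv").iterrows():
        seeds = row["seeds_per_berry"]
        diallel.append(gsi.DiallelObservation(
            row["female"], row["male"], row["berry_set"] == "1",
            float(seeds) if seeds else None))
    progeny: dict[tuple[str, str], list[gsi.SGenotype]] = {}
    for _, row in read_table_tsv(src / "progeny.tsv").iterrows():
        key = (row["female"], row["male"])
        progeny.setdefault(key, []).append(
            gsi.SGenotype(row["allele_a"], row["allele_b"]))
    assays_rows = read_table_tsv(src / "primers.tsv")
    assays = []
    for allele, group in assays_rows.groupby("allele", sort=True):
        fwd = group[group["orientation"] == "forward"].iloc[0]
        rev = group[group["orientation"] == "reverse"].iloc[0]
        assays.append((
            allele,
            DegeneratePrimer(fwd["name"], fwd["sequence"], "forward"),
            DegeneratePrimer(rev["name"], rev["sequence"], "reverse"),
        ))
    dup = manifest.get("duplicate_pair")
    return StudyBundle(
        spec=spec, proteins=proteins, transcripts=transcripts,
        genotypes=genotypes, diallel=diallel, progeny=progeny,
        assays=assays, duplicate_pair=tuple(dup) if dup else None,
        manifest=manifest,
    )
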