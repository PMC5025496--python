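"""IUPAC degenerate-primer arithmetic and in-silico RT-PCR / 3'RACE.

Models the cloning strategy used to pull partial S-RNase transcripts out of
pistil RNA: a degenerate forward primer anchored in the conserved C2 domain
(SolC2-F1.3, ``TTTACNRTNCATGGNCTNTGGCC``) paired with an oligo-dT/NotI
anchor that converts the poly(A) tail into a fixed reverse priming site.
Also provides allele-specific PCR genotyping with an exhaustive
specificity check against a panel.

Annealing is modelled as positional Hamming matching over IUPAC sets (no
indels, no 3'-end weighting); ``max_mismatch`` defaults to 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io_formats import SequenceRecord

__all__ = [
    "DegeneratePrimer",
    "PrimerMatch",
    "Amplicon",
    "SOLC2_F13",
    "NOTI_ANCHOR",
    "OLIGO_DT_ANCHOR_LENGTH",
    "expand_iupac",
    "iupac_degeneracy",
    "find_primer_sites",
    "predict_3race_products",
    "in_silico_pcr",
    "genotype_by_as_pcr",
    "check_assay_specificity",
]

#: symbol -> set of concrete bases it stands for (the 15 standard codes)
IUPAC_SETS: dict[str, frozenset[str]] = {
    sym: frozenset(bases)
    for sym, bases in ambiguous_dna_values.items()
    if sym in "ACGTRYSWKMBDHVN"
}

#: Length of the sequence the oligo-dT/NotI anchor appends to a 3'RACE
#: product: 18 dT plus the 27-nt NotI anchor of the RT primer.
OLIGO_DT_ANCHOR_LENGTH = 45


@dataclass(frozen=True)
class DegeneratePrimer:
    """A possibly degenerate oligo written 5'->3'."""

    name: str
    iupac: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("primer sequence must be non-empty")
        object.__setattr__(self, "iupac", self.iupac.upper())
        bad = set(self.iupac) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: non-IUPAC symbols {sorted(bad)}"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse")

    def __len__(self) -> int:
        return len(self.iupac)


#: The degenerate C2-domain forward primer used for 3'RACE cloning.
SOLC2_F13 = DegeneratePrimer("SolC2-F1.3", "TTTACNRTNCATGGNCTNTGGCC", "forward")
#: The NotI anchor primer matching the anchor part of the oligo-dT RT primer.
NOTI_ANCHOR = DegeneratePrimer("NotI-anchor", "AACTGGAAGAATTCGCGG", "reverse")


@dataclass(frozen=True)
class PrimerMatch:
    """An annealing site; *start* is 1-based on the reported strand."""

    template_id: str
    start: int
    strand: str
    mismatches: int
    primer_name: str = ""
    # footprint on the + strand, 1-based inclusive, for product arithmetic
    plus_start: int = 0
    plus_end: int = 0


@dataclass(frozen=True)
class Amplicon:
    """A predicted product; coordinates 1-based inclusive on the + strand.

    ``length_nt`` is the template span; ``product_length_nt`` additionally
    counts sequence contributed by an anchored reverse primer (3'RACE).
    """

    template_id: str
    start: int
    end: int
    primers: tuple[str, str]
    product_length_nt: int | None = None

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


def iupac_degeneracy(primer: DegeneratePrimer) -> int:
    """Product of per-symbol set sizes."""
    n = 1
    for sym in primer.iupac:
        n *= len(IUPAC_SETS[sym])
    return n


def expand_iupac(primer: DegeneratePrimer) -> set[str]:
    """All concrete sequences a degenerate primer stands for."""
    pools = [sorted(IUPAC_SETS[sym]) for sym in primer.iupac]
    return {"".join(combo) for combo in itertools.product(*pools)}


def _hamming_iupac(primer_seq: str, window: str) -> int:
    return sum(
        1 for p, b in zip(primer_seq, window) if b not in IUPAC_SETS[p]
    )


def find_primer_sites(template: SequenceRecord, primer: DegeneratePrimer,
                      max_mismatch: int = 0) -> list[PrimerMatch]:
    """Scan a nucleotide template for annealing sites.

    A primer symbol matches a template base iff the base is in the symbol's
    IUPAC set. Forward primers are scanned on the + strand; reverse primers
    on the - strand (i.e. against the reverse complement). ``start`` is the
    1-based position of the primer's 5'-most base on the scanned strand.
    """
    if template.alphabet != "nucleotide":
        raise ValueError("primer search requires a nucleotide template")
    if "-" in template.residues:
        raise ValueError("template must be ungapped")
    seq = template.residues
    n, k = len(seq), len(primer)
    matches: list[PrimerMatch] = []
    if k > n:
        return matches
    if primer.orientation == "forward":
        strand, scan = "+", seq
    else:
        strand, scan = "-", str(Seq(seq).reverse_complement())
    for i in range(n - k + 1):
        mm = _hamming_iupac(primer.iupac, scan[i:i + k])
        if mm <= max_mismatch:
            if strand == "+":
                plus_start, plus_end = i + 1, i + k
            else:
                plus_start, plus_end = n - (i + k) + 1, n - i
            matches.append(PrimerMatch(
                template_id=template.id, start=i + 1, strand=strand,
                mismatches=mm, primer_name=primer.name,
                plus_start=plus_start, plus_end=plus_end,
            ))
    return matches


def _poly_a_start(seq: str, min_polyA: int, not_before: int) -> int | None:
    """1-based start of the first run of >= min_polyA adenines at/after
    position *not_before* (1-based)."""
    run = 0
    for idx in range(not_before - 1, len(seq)):
        if seq[idx] == "A":
            run += 1
            if run >= min_polyA:
                return idx - run + 2  # 1-based start of the run
        else:
            run = 0
    return None


def predict_3race_products(cdna: SequenceRecord, fwd: DegeneratePrimer,
                           min_polyA: int = 10, max_mismatch: int = 0,
                           anchor_length: int = OLIGO_DT_ANCHOR_LENGTH
                           ) -> list[Amplicon]:
    """Predict 3'RACE amplicons from a sense-strand transcript.

    One product per forward-primer site, running from the site's 5' base to
    the last base before the first downstream run of >= *min_polyA*
    adenines; the anchored oligo-dT reverse primer then appends
    *anchor_length* nt, counted in ``product_length_nt``. Transcripts
    lacking a qualifying poly(A) run yield no product.
    """
    products: list[Amplicon] = []
    for site in find_primer_sites(cdna, fwd, max_mismatch):
        if site.strand != "+":
            continue
        tail = _poly_a_start(cdna.residues, min_polyA, site.plus_end + 1)
        if tail is None:
            continue
        start, end = site.plus_start, tail - 1
        products.append(Amplicon(
            template_id=cdna.id, start=start, end=end,
            primers=(fwd.name, "oligo-dT-anchor"),
            product_length_nt=(end - start + 1) + anchor_length,
        ))
    return products


def in_silico_pcr(template: SequenceRecord, fwd: DegeneratePrimer,
                  rev: DegeneratePrimer, max_product: int = 1500,
                  max_mismatch: int = 0) -> list[Amplicon]:
    """Exhaustive convergent-primer PCR on one template.

    Products pair a +-strand forward site with a downstream --strand
    reverse site, bounded by *max_product* nt.
    """
    fwd_sites = [
        m for m in find_primer_sites(template, fwd, max_mismatch)
        if m.strand == "+"
    ]
    rev_primer = rev
    if rev.orientation != "reverse":
        rev_primer = DegeneratePrimer(rev.name, rev.iupac, "reverse")
    rev_sites = find_primer_sites(template, rev_primer, max_mismatch)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.plus_start > f.plus_end:
                length = r.plus_end - f.plus_start + 1
                if length <= max_product:
                    products.append(Amplicon(
                        template_id=template.id,
                        start=f.plus_start, end=r.plus_end,
                        primers=(fwd.name, rev.name),
                    ))
    return products


Assay = tuple[str, DegeneratePrimer, DegeneratePrimer]


def check_assay_specificity(assays: list[Assay], panel, max_product: int = 1500,
                            max_mismatch: int = 0) -> dict[str, list[str]]:
    """In-silico PCR of every assay against every panel allele.

    Returns assay target allele -> list of panel alleles it amplifies.
    An assay amplifying more than one allele is off-target (the caller
    decides whether that is an error).
    """
    report: dict[str, list[str]] = {}
    for allele_id, fwd, rev in assays:
        hits = [
            rec.id for rec in panel
            if in_silico_pcr(rec, fwd, rev, max_product, max_mismatch)
        ]
        report[allele_id] = hits
    return report


def genotype_by_as_pcr(individual_templates, assays: list[Assay],
                       panel=None, max_product: int = 1500,
                       max_mismatch: int = 0) -> set[str]:
    """Call the S-alleles of a diploid from allele-specific PCR assays.

    *individual_templates* are the (up to two) allele cDNA/genomic
    templates carried by the plant. An allele is called present iff its
    assay amplifies from at least one template. When *panel* is given, the
    assays are first validated with :func:`check_assay_specificity`; an
    assay amplifying more than one panel allele is a hard error.
    """
    if panel is not None:
        report = check_assay_specificity(assays, panel, max_product, max_mismatch)
        for allele_id, hits in report.items():
            if len(hits) > 1:
                raise ValueError(
                    f"assay for {allele_id!r} amplifies multiple panel "
                    f"alleles: {hits}"
                )
    detected: set[str] = set()
    for allele_id, fwd, rev in assays:
        for template in individual_templates:
            if in_silico_pcr(template, fwd, rev, max_product, max_mismatch):
                detected.add(allele_id)
                break
    if not detected:
        warnings.warn("no assay amplified from the individual's templates")
    return detected
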