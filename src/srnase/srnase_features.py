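"""Translation, structural-feature annotation and the functional rubric.

Solanaceous S-RNases share a conserved primary structure: five conserved
blocks C1–C5 interleaved with two hypervariable regions (HVa, HVb) in the
order C1 < C2 < HVa < HVb < C3 < C4 < C5; two catalytic histidines (in C2
and C3); eight conserved cysteines (two between C1 and C2, one just after
C5, so a C2-primed 3'RACE fragment can observe at most six); a single
conserved N-glycosylation sequon inside C2; and a basic isoelectric point
(pI > 7.5). This module locates those features against a reference-derived
position-frequency profile and applies the functional-candidate rubric:
a sequence with the domains in order, the catalytic histidine(s), at most
one conserved cysteine missing, the C2 sequon (full length only), a basic
pI and class-III clade membership is a putative S-RNase.

Partial sequences are scored only over what they can show: absence of
C1/C2 in a 3'RACE fragment is not a rubric failure, and the conserved-Cys
check compares against the observable maximum.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io_formats import SequenceRecord

__all__ = [
    "REGION_ORDER",
    "BJELLQVIST_PKA",
    "DomainMap",
    "DomainProfile",
    "ProteinProfile",
    "RubricResult",
    "translate_orf",
    "build_domain_profile",
    "annotate_domains",
    "count_conserved_cysteines",
    "find_nglyc_sites",
    "compute_pI",
    "profile_protein",
    "classify_functional_candidate",
]

#: Canonical left-to-right order of the conserved/hypervariable regions.
REGION_ORDER = ("C1", "C2", "HVa", "HVb", "C3", "C4", "C5")

#: pKa constants (Bjellqvist-style) used by :func:`compute_pI`. Recorded
#: here verbatim so computed pI values are reproducible constants.
BJELLQVIST_PKA = {
    "Nterm": 7.50,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


# ---------------------------------------------------------------------------
# Translation


def translate_orf(nt: SequenceRecord, frame_search: bool = False,
                  min_codons: int = 50) -> SequenceRecord:
    """Translate a cDNA with the standard genetic code.

    Without *frame_search*, frame 1 is translated up to the first stop.
    With it, the longest stop-free codon run among the three forward
    frames is chosen (cDNA orientation is known from oligo-dT priming, so
    reverse frames are never considered). Runs shorter than *min_codons*
    are an error — too short to be an S-RNase fragment.
    """
    if nt.alphabet != "nucleotide":
        raise ValueError("translate_orf requires a nucleotide record")
    seq = nt.ungapped
    frames = range(3) if frame_search else (0,)
    best: tuple[int, int, int] | None = None  # (length, frame, start_codon)
    for frame in frames:
        trimmed = seq[frame:len(seq) - (len(seq) - frame) % 3]
        aa = str(Seq(trimmed).translate())
        run_start = 0
        for piece in aa.split("*"):
            if best is None or len(piece) > best[0]:
                best = (len(piece), frame, run_start)
            run_start += len(piece) + 1
    assert best is not None
    length, frame, start_codon = best
    if length < min_codons:
        raise ValueError(
            f"{nt.id}: longest stop-free reading frame is {length} codons "
            f"(< {min_codons}); too short to be an S-RNase fragment"
        )
    start = frame + 3 * start_codon
    protein = str(Seq(seq[start:start + 3 * length]).translate())
    return SequenceRecord(nt.id, protein, nt.description, "protein")


# ---------------------------------------------------------------------------
# Domain profiles


@dataclass
class RegionProfile:
    name: str
    start_col: int  # 1-based alignment columns, inclusive
    end_col: int
    frequencies: list[dict[str, float]]
    threshold: float
    self_scores: list[float] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1

    def score(self, window: str) -> float:
        assert len(window) == self.length
        return sum(
            freqs.get(res, 0.0)
            for res, freqs in zip(window, self.frequencies)
        ) / self.length


@dataclass
class DomainProfile:
    """Position-frequency profiles for every annotated region, plus the
    conserved-anchor columns (catalytic His, conserved Cys, sequon)."""

    regions: dict[str, RegionProfile]
    alignment_width: int
    his_columns: dict[str, int]  # region ("C2"/"C3") -> column
    cys_columns: list[int]
    conservation_fraction: float


@dataclass
class DomainMap:
    """Located regions on one protein; 1-based inclusive intervals."""

    intervals: dict[str, tuple[int, int]]
    offset: int | None = None  # protein position - alignment column
    warnings: list[str] = field(default_factory=list)

    def __contains__(self, region: str) -> bool:
        return region in self.intervals

    def get(self, region: str):
        return self.intervals.get(region)


def _conserved_columns(records, residue_filter=None, fraction=0.9):
    width = len(records[0].residues)
    cols = []
    for c in range(width):
        counter = Counter(r.residues[c] for r in records)
        res, count = counter.most_common(1)[0]
        if res == "-":
            continue
        if count / len(records) >= fraction:
            if residue_filter is None or res in residue_filter:
                cols.append((c + 1, res))
    return cols


def build_domain_profile(reference_alignment: list[SequenceRecord],
                         region_annotations: dict[str, tuple[int, int]],
                         k: float = 2.0,
                         conservation_fraction: float = 0.9) -> DomainProfile:
    """Build per-region position-frequency profiles from aligned references.

    *region_annotations* maps region name -> (start, end) alignment columns
    (1-based inclusive). Each region's match threshold is the mean
    self-score of the references minus *k* standard deviations.
    """
    if len(reference_alignment) < 2:
        raise ValueError("need >= 2 reference sequences")
    width = len(reference_alignment[0].residues)
    if any(len(r.residues) != width for r in reference_alignment):
        raise ValueError("reference sequences do not share column space")
    regions: dict[str, RegionProfile] = {}
    for name, (start, end) in region_annotations.items():
        if not (1 <= start <= end <= width):
            raise ValueError(
                f"region {name}: columns ({start},{end}) outside alignment "
                f"width {width}"
            )
        if end - start + 1 < 3:
            raise ValueError(f"region {name}: length < 3")
        freqs: list[dict[str, float]] = []
        for c in range(start - 1, end):
            counter = Counter(r.residues[c] for r in reference_alignment)
            counter.pop("-", None)
            total = sum(counter.values())
            freqs.append(
                {res: n / total for res, n in counter.items()} if total else {}
            )
        prof = RegionProfile(name, start, end, freqs, threshold=0.0)
        self_scores = [
            prof.score(r.residues[start - 1:end]) for r in reference_alignment
        ]
        mean = sum(self_scores) / len(self_scores)
        var = sum((s - mean) ** 2 for s in self_scores) / len(self_scores)
        # every reference must match its own profile: the threshold never
        # rises above the weakest reference self-score
        prof.threshold = min(mean - k * math.sqrt(var), min(self_scores))
        prof.self_scores = self_scores
        regions[name] = prof
    his_cols = {}
    for region in ("C2", "C3"):
        if region in region_annotations:
            start, end = region_annotations[region]
            cols = [
                col for col, res in _conserved_columns(
                    reference_alignment, {"H"}, conservation_fraction)
                if start <= col <= end
            ]
            if cols:
                his_cols[region] = cols[0]
    cys_cols = [
        col for col, res in _conserved_columns(
            reference_alignment, {"C"}, conservation_fraction)
    ]
    return DomainProfile(
        regions=regions, alignment_width=width, his_columns=his_cols,
        cys_columns=cys_cols, conservation_fraction=conservation_fraction,
    )


def annotate_domains(protein: SequenceRecord, profile: DomainProfile
                     ) -> DomainMap:
    """Locate the regions of an ungapped protein.

    Conserved blocks (C1–C5) are found by their best profile window,
    searched left to right in canonical order; a block whose best window
    falls below its threshold (partial sequences, unrelated proteins) is
    reported absent, never guessed, and an above-threshold window that
    violates the canonical order is dropped with a warning. The
    hypervariable regions carry no usable profile signal — by definition —
    so HVa/HVb are placed positionally from the conserved-block anchoring
    (the modal block offset applied to their annotated columns), provided
    they fit inside the sequence and respect the canonical order.
    """
    if "-" in protein.residues:
        raise ValueError("annotate_domains requires an ungapped protein")
    seq = protein.residues
    intervals: dict[str, tuple[int, int]] = {}
    warns: list[str] = []
    min_start = 1
    offsets: list[int] = []
    conserved = [
        n for n in REGION_ORDER
        if n in profile.regions and not n.startswith("HV")
    ]
    for name in conserved:
        prof = profile.regions[name]
        L = prof.length
        best_pos, best_score = None, -1.0
        for pos in range(1, len(seq) - L + 2):
            score = prof.score(seq[pos - 1:pos - 1 + L])
            if score > best_score:
                best_pos, best_score = pos, score
        if best_pos is None or best_score < prof.threshold:
            continue
        if best_pos < min_start:
            # above-threshold window conflicts with an earlier region
            warns.append(
                f"{name}: best window at {best_pos} violates canonical "
                f"order (must start >= {min_start}); region dropped"
            )
            continue
        intervals[name] = (best_pos, best_pos + L - 1)
        offsets.append(best_pos - prof.start_col)
        min_start = best_pos + L
    offset = None
    if offsets:
        offset = Counter(offsets).most_common(1)[0][0]
        if len(set(offsets)) > 1:
            warns.append(
                f"inconsistent region offsets {sorted(set(offsets))}; "
                f"using modal offset {offset}"
            )
    if offset is not None:
        for name in ("HVa", "HVb"):
            prof = profile.regions.get(name)
            if prof is None:
                continue
            start = prof.start_col + offset
            end = prof.end_col + offset
            if start < 1 or end > len(seq):
                continue  # outside a partial sequence: absent, not guessed
            clash = any(
                not (end < s or start > e)
                for s, e in intervals.values()
            )
            if clash:
                warns.append(f"{name}: mapped interval overlaps a "
                             f"conserved block; dropped")
                continue
            intervals[name] = (start, end)
    # final canonical-order audit over everything placed
    placed = [(n, intervals[n]) for n in REGION_ORDER if n in intervals]
    for (n1, (_, e1)), (n2, (s2, _)) in zip(placed, placed[1:]):
        if e1 >= s2:
            warns.append(f"order violation between {n1} and {n2}")
    return DomainMap(intervals=intervals, offset=offset, warnings=warns)


def count_conserved_cysteines(protein: SequenceRecord, domain_map: DomainMap,
                              profile: DomainProfile
                              ) -> tuple[int, list[int], int]:
    """Count cysteines at the profile-defined conserved columns.

    Only the conserved-Cys columns are counted, not every C in the
    sequence. Partial sequences are scored over the columns they can show;
    returns (count, positions, observable_maximum).
    """
    if domain_map.offset is None:
        return 0, [], 0
    positions, observable = [], 0
    for col in profile.cys_columns:
        pos = col + domain_map.offset
        if 1 <= pos <= len(protein.residues):
            observable += 1
            if protein.residues[pos - 1] == "C":
                positions.append(pos)
    return len(positions), positions, observable


def find_nglyc_sites(protein: SequenceRecord,
                     region: tuple[int, int]) -> list[int]:
    """Positions of N-glycosylation sequons (N, X != P, S/T) starting in
    *region* (1-based inclusive)."""
    start, end = region
    seq = protein.residues
    sites = []
    for pos in range(start, min(end, len(seq) - 2) + 1):
        i = pos - 1
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            sites.append(pos)
    return sites


# ---------------------------------------------------------------------------
# Isoelectric point


def _net_charge(seq: str, pH: float, pka=BJELLQVIST_PKA,
                include_termini: bool = True) -> float:
    counts = Counter(seq)
    charge = 0.0
    if include_termini:
        charge += 1.0 / (1.0 + 10 ** (pH - pka["Nterm"]))
        charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - pH))
    for res in _POSITIVE:
        charge += counts[res] / (1.0 + 10 ** (pH - pka[res]))
    for res in _NEGATIVE:
        charge -= counts[res] / (1.0 + 10 ** (pka[res] - pH))
    return charge


def compute_pI(protein: SequenceRecord | str, pka=BJELLQVIST_PKA,
               include_termini: bool = True, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the Henderson–Hasselbalch net
    charge over the ionisable groups (termini, D, E, C, Y, H, K, R).

    The net charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; tolerance 1e-4 pH units. A sequence with no ionisable
    groups returns 7.0 with a warning.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    seq = seq.replace("-", "").upper()
    if not seq:
        raise ValueError("empty sequence")
    n_groups = sum(seq.count(r) for r in _POSITIVE + _NEGATIVE)
    if include_termini:
        n_groups += 2
    if n_groups == 0:
        warnings.warn("sequence has no ionisable groups; returning pI = 7.0")
        return 7.0
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(seq, mid, pka, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Rubric


@dataclass
class ProteinProfile:
    """All measured features of one candidate protein."""

    record: SequenceRecord
    domain_map: DomainMap
    catalytic_his: dict[str, int]  # region -> protein position where H found
    conserved_cys_count: int
    cys_positions: list[int]
    cys_observable_max: int
    nglyc_sites_c2: list[int]
    pI: float


@dataclass
class RubricResult:
    checks: dict[str, bool]
    verdict: str  # putative_S_RNase | S_like | indeterminate
    notes: list[str] = field(default_factory=list)


def profile_protein(protein: SequenceRecord, profile: DomainProfile
                    ) -> ProteinProfile:
    """Annotate one candidate against a domain profile."""
    dm = annotate_domains(protein, profile)
    his: dict[str, int] = {}
    if dm.offset is not None:
        for region, col in profile.his_columns.items():
            if region not in dm:
                continue
            pos = col + dm.offset
            start, end = dm.intervals[region]
            if start <= pos <= end and protein.residues[pos - 1] == "H":
                his[region] = pos
    count, positions, observable = count_conserved_cysteines(
        protein, dm, profile)
    nglyc = find_nglyc_sites(protein, dm.intervals["C2"]) if "C2" in dm else []
    return ProteinProfile(
        record=protein, domain_map=dm, catalytic_his=his,
        conserved_cys_count=count, cys_positions=positions,
        cys_observable_max=observable, nglyc_sites_c2=nglyc,
        pI=compute_pI(protein),
    )


def classify_functional_candidate(profile: ProteinProfile,
                                  clade_class: str = "unknown",
                                  pI_threshold: float = 7.5,
                                  cys_tolerance: int = 1) -> RubricResult:
    """Apply the functional-candidate rubric.

    Checks (partial sequences are judged only on what they can show):
    domains present in canonical order; catalytic His in C3 (and C2 when
    full length); conserved Cys >= observable maximum - *cys_tolerance*
    (one missing Cys is tolerated — several functional S-RNases lack the
    post-C5 cysteine); the C2 sequon when C2 is observed; pI >
    *pI_threshold*; class-III clade membership when a clade call is
    available. Verdict is ``putative_S_RNase`` iff every applicable check
    passes; a candidate placed in an S-like clade is ``S_like``;
    otherwise ``indeterminate``.
    """
    dm = profile.domain_map
    full_length = "C1" in dm and "C2" in dm
    checks: dict[str, bool] = {}
    notes: list[str] = list(dm.warnings)

    observed = [n for n in REGION_ORDER if n in dm]
    # partial 3'RACE fragments begin inside C2: C3..C5 (+HV) must be there
    required_tail = {"HVa", "HVb", "C3", "C4", "C5"}
    checks["domains_detected"] = (
        required_tail <= set(observed) and not dm.warnings
    )
    checks["his_c3"] = "C3" in profile.catalytic_his
    if "C2" in dm:
        checks["his_c2"] = "C2" in profile.catalytic_his
    checks["cys_ok"] = (
        profile.cys_observable_max > 0
        and profile.conserved_cys_count
        >= profile.cys_observable_max - cys_tolerance
    )
    if "C2" in dm:
        checks["nglyc_c2"] = bool(profile.nglyc_sites_c2)
    checks["basic_pI"] = profile.pI > pI_threshold
    if clade_class != "unknown":
        checks["class_III_clade"] = clade_class == "S_RNase_III"

    if clade_class.startswith("S_like"):
        verdict = "S_like"
    elif all(checks.values()):
        verdict = "putative_S_RNase"
    else:
        verdict = "indeterminate"
        notes.extend(name for name, ok in checks.items() if not ok)
    return RubricResult(checks=checks, verdict=verdict, notes=notes)
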