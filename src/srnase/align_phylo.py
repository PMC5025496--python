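"""Pairwise alignment, similarity/distance matrices, neighbour-joining
with bootstrap, outgroup rooting, and S-RNase vs S-like clade calls.

Percent similarity uses exact global alignment (Needleman–Wunsch with
BLOSUM62 and affine gaps, open 10 / extend 0.5) with pairwise deletion of
gap columns. Evolutionary distances use the Poisson correction
d = -ln(1 - p) on the proportion p of differing sites, with complete
deletion of gapped columns across the whole alignment. Trees are built by
the canonical Saitou–Nei neighbour-joining algorithm (implemented here,
not delegated), with deterministic tie-breaking by lexicographically
smallest label pair and MEGA-style clamping of negative branch length
estimates to zero. Bootstrap supports are percentages of column-resampled
replicates containing each internal-edge bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord, TabularMatrix

__all__ = [
    "PairwiseAlignment",
    "DistanceMatrix",
    "BootstrapConfig",
    "global_align",
    "percent_similarity",
    "similarity_matrix",
    "matrix_extremes",
    "MatrixExtremes",
    "poisson_distance",
    "p_distance",
    "distance_matrix",
    "nj_build",
    "bootstrap_supports",
    "root_with_outgroup",
    "classify_by_clade",
]


@dataclass
class PairwiseAlignment:
    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings differ in length")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("distance matrix is not square over the labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")


@dataclass
class BootstrapConfig:
    B: int = 1000
    seed: int = 0
    support_display_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("bootstrap replicate count must be >= 1")


# ---------------------------------------------------------------------------
# Pairwise alignment and similarity


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5,
                  matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def global_align(a: SequenceRecord, b: SequenceRecord,
                 open_gap: float = 10.0, extend_gap: float = 0.5,
                 matrix: str = "BLOSUM62") -> PairwiseAlignment:
    """Optimal global alignment of two ungapped proteins (affine gaps)."""
    if not a.ungapped or not b.ungapped:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(open_gap, extend_gap, matrix)
    alignment = aligner.align(a.ungapped, b.ungapped)[0]
    return PairwiseAlignment(
        a_aligned=str(alignment[0]),
        b_aligned=str(alignment[1]),
        score=float(alignment.score),
    )


def percent_similarity(a_aligned: str, b_aligned: str) -> float:
    """100 * identities / positions where both sequences have residues."""
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned strings differ in length")
    comparable = ident = 0
    for x, y in zip(a_aligned, b_aligned):
        if x != "-" and y != "-":
            comparable += 1
            if x == y:
                ident += 1
    if comparable == 0:
        raise ValueError("no comparable positions")
    return 100.0 * ident / comparable


def similarity_matrix(panel: list[SequenceRecord], **align_kwargs
                      ) -> TabularMatrix:
    """Pairwise percent-similarity matrix over a protein panel."""
    if len(panel) < 2:
        raise ValueError("similarity matrix needs >= 2 sequences")
    labels = [r.id for r in panel]
    n = len(panel)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(panel[i], panel[j], **align_kwargs)
            sim = percent_similarity(aln.a_aligned, aln.b_aligned)
            values[i, j] = values[j, i] = sim
    return TabularMatrix(labels, list(labels), values)


@dataclass
class MatrixExtremes:
    min_value: float
    min_pairs: list[tuple[str, str]]
    max_value: float
    max_pairs: list[tuple[str, str]]


def matrix_extremes(m: TabularMatrix, subset: list[str] | None = None,
                    atol: float = 1e-9) -> MatrixExtremes:
    """Off-diagonal (min, max) with all attaining pairs; NaN excluded."""
    if not m.is_square:
        raise ValueError("extremes require a square labelled matrix")
    labels = m.row_labels if subset is None else list(subset)
    missing = set(labels) - set(m.row_labels)
    if missing:
        raise ValueError(f"labels not in matrix: {sorted(missing)}")
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    idx = [m.row_labels.index(lab) for lab in labels]
    cells = [
        (float(m.values[i, j]), (m.row_labels[i], m.row_labels[j]))
        for ii, i in enumerate(idx)
        for j in idx[ii + 1:]
        if not math.isnan(m.values[i, j])
    ]
    if not cells:
        raise ValueError("no non-missing off-diagonal cells")
    lo = min(v for v, _ in cells)
    hi = max(v for v, _ in cells)
    return MatrixExtremes(
        min_value=lo,
        min_pairs=[p for v, p in cells if abs(v - lo) <= atol],
        max_value=hi,
        max_pairs=[p for v, p in cells if abs(v - hi) <= atol],
    )


# ---------------------------------------------------------------------------
# Distances


def p_distance(a_aligned: str, b_aligned: str) -> float:
    """Proportion of differing sites over positions where both have
    residues."""
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned strings differ in length")
    comparable = diff = 0
    for x, y in zip(a_aligned, b_aligned):
        if x != "-" and y != "-":
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        raise ValueError("zero comparable positions")
    return diff / comparable


def poisson_distance(a_aligned: str, b_aligned: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p); p = 0 gives d = 0."""
    p = p_distance(a_aligned, b_aligned)
    if p >= 1.0:
        raise ValueError(f"saturated distance: p = {p} >= 1")
    return -math.log1p(-p)


def distance_matrix(records: list[SequenceRecord],
                    deletion: str = "complete",
                    correction: str = "poisson") -> DistanceMatrix:
    """Distance matrix over an aligned panel.

    *deletion*: "complete" drops every column containing a gap in any
    sequence before computing p (the convention used for tree building);
    "pairwise" compares each pair over their mutually ungapped columns.
    *correction*: "poisson" or "p" (uncorrected).
    """
    if len(records) < 2:
        raise ValueError("need >= 2 sequences")
    width = len(records[0].residues)
    if any(len(r.residues) != width for r in records):
        raise ValueError("sequences do not share column space")
    seqs = [r.residues for r in records]
    if deletion == "complete":
        keep = [c for c in range(width) if all(s[c] != "-" for s in seqs)]
        if not keep:
            raise ValueError("complete deletion removed every column")
        seqs = ["".join(s[c] for c in keep) for s in seqs]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion convention {deletion!r}")
    dist = poisson_distance if correction == "poisson" else p_distance
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist(seqs[i], seqs[j])
    return DistanceMatrix([r.id for r in records], values)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_build(dm: DistanceMatrix,
             taxon_namespace: dendropy.TaxonNamespace | None = None
             ) -> dendropy.Tree:
    """Saitou–Nei neighbour joining on a distance matrix.

    Joins minimise Q(i,j) = (n-2) d(i,j) - r(i) - r(j); branch lengths use
    the standard two-point formulas. Negative length estimates are clamped
    to zero and the total deficit recorded on the returned tree as
    ``negative_length_deficit``. Ties are broken by the lexicographically
    smallest (label, label) pair, where a cluster is labelled by its
    smallest leaf label, so output is deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(sorted(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(label)
        if node.taxon is None:
            raise ValueError(f"label {label!r} missing from taxon namespace")
        nodes[label] = node

    # active clusters: key -> (min-leaf label for tie-breaks)
    active = list(dm.labels)
    d = {
        (a, b): float(dm.values[i, j])
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
        if i != j
    }

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_key = None
        best_pair = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        a, b = best_pair
        dab = dist(a, b)
        la = clamp(0.5 * dab + (r[a] - r[b]) / (2 * (m - 2)))
        lb = clamp(dab - (0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new = min(a, b)  # cluster label: smallest member leaf label
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            dnew = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new, c)] = d[(c, new)] = dnew
        active = [c for c in active if c not in (a, b)]
        active.append(new)
        active.sort()
        nodes[new] = parent
        nodes.pop(other, None)

    a, b, c = sorted(active)
    la = clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))
    lb = clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))
    lc = clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))
    center = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[label])
        nodes[label].edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    tree.negative_length_deficit = deficit
    return tree


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each as the smaller-or-canonical
    side's frozen leaf-label set (complement-normalised)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = _leaf_labels(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        comp = all_leaves - side
        canonical = min(side, comp, key=lambda s: (len(s), sorted(s)))
        splits.add(canonical)
    return splits


def _canonical_split(side: frozenset[str], all_leaves: frozenset[str]
                     ) -> frozenset[str]:
    comp = all_leaves - side
    return min(side, comp, key=lambda s: (len(s), sorted(s)))


def bootstrap_supports(alignment: list[SequenceRecord], cfg: BootstrapConfig,
                       deletion: str = "complete") -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate (seeded);
    each replicate goes through the same distance -> NJ path. The support
    of an internal edge is the percentage of replicates whose tree
    contains the same leaf bipartition. Supports are stored on internal
    node labels and in ``tree.bipartition_supports``.
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    width = len(alignment[0].residues)
    if width < 1 or any(len(r.residues) != width for r in alignment):
        raise ValueError("sequences do not share column space")
    seqs = [r.residues for r in alignment]
    if deletion == "complete":
        keep = [c for c in range(width) if all(s[c] != "-" for s in seqs)]
        if not keep:
            raise ValueError("complete deletion removed every column")
        seqs = ["".join(s[c] for c in keep) for s in seqs]
    labels = [r.id for r in alignment]
    namespace = dendropy.TaxonNamespace(sorted(labels))

    def tree_from_columns(cols) -> dendropy.Tree:
        sub = ["".join(s[c] for c in cols) for s in seqs]
        n = len(sub)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = sum(1 for x, y in zip(sub[i], sub[j]) if x != y) / len(cols)
                if p >= 1.0:
                    p = 1.0 - 1.0 / (2 * len(cols))  # saturated replicate
                values[i, j] = values[j, i] = -math.log1p(-p)
        return nj_build(DistanceMatrix(labels, values), namespace)

    ncols = len(seqs[0])
    reference = tree_from_columns(range(ncols))
    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(cfg.B):
        cols = rng.integers(0, ncols, size=ncols)
        rep = tree_from_columns(cols)
        for split in tree_bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(labels)
    supports: dict[frozenset[str], float] = {}
    for node in reference.preorder_internal_node_iter():
        if node is reference.seed_node:
            continue
        side = _leaf_labels(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        split = _canonical_split(side, all_leaves)
        pct = 100.0 * counts.get(split, 0) / cfg.B
        supports[split] = pct
        node.label = f"{pct:g}"
    reference.bipartition_supports = supports
    return reference


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup must be cohesive (form one side of an existing
    bipartition of the unrooted tree); otherwise an error lists the
    offending label sets.
    """
    outgroup = frozenset(outgroup_labels)
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not outgroup <= all_leaves:
        raise ValueError(
            f"outgroup labels missing from tree: {sorted(outgroup - all_leaves)}"
        )
    if outgroup == all_leaves:
        raise ValueError("outgroup cannot be the whole tree")
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = _leaf_labels(node)
        if side == outgroup or side == all_leaves - outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not cohesive: no edge induces "
            f"the bipartition {sorted(outgroup)} | "
            f"{sorted(all_leaves - outgroup)}"
        )
    edge = target.edge
    length = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    # rerooting reverses nodes on the old root path, so node labels no
    # longer describe their (new) subtrees; bipartition supports are
    # rooting-invariant — re-apply them from the stored table
    supports = getattr(tree, "bipartition_supports", None)
    if supports is not None:
        apply_supports(tree, supports)
    return tree


def apply_supports(tree: dendropy.Tree,
                   supports: dict[frozenset[str], float]) -> None:
    """Write bipartition supports onto internal node labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = _leaf_labels(node)
        if len(side) < 2 or len(all_leaves - side) < 2:
            node.label = None
            continue
        split = _canonical_split(side, all_leaves)
        if split in supports:
            node.label = f"{supports[split]:g}"


def classify_by_clade(candidate: SequenceRecord,
                      labelled_refs: list[tuple[SequenceRecord, str]],
                      cfg: BootstrapConfig | None = None,
                      outgroup: list[SequenceRecord] | None = None,
                      support_threshold: float = 50.0
                      ) -> tuple[str, float]:
    """Place a candidate among class III S-RNase / S-like I / S-like II
    references by clade membership.

    Builds an NJ tree with bootstrap supports over candidate + references
    (+ optional outgroup used to root). The candidate's class is the
    majority class of the references inside the smallest supported
    (>= *support_threshold*) clade containing the candidate and at least
    one reference. Returns ("unclassified", 0.0) when no such clade
    exists.
    """
    cfg = cfg or BootstrapConfig(B=200, seed=0)
    classes = {rec.id: cls for rec, cls in labelled_refs}
    per_class: dict[str, int] = {}
    for cls in classes.values():
        per_class[cls] = per_class.get(cls, 0) + 1
    if any(n < 2 for n in per_class.values()):
        raise ValueError("need >= 2 references per class")
    # a candidate may be one of the references (self-classification):
    # keep a single copy of the leaf, its class stays known via `classes`
    panel = [candidate] + [
        rec for rec, _ in labelled_refs if rec.id != candidate.id
    ]
    outgroup_labels = []
    if outgroup:
        panel += list(outgroup)
        outgroup_labels = [r.id for r in outgroup]
    tree = bootstrap_supports(panel, cfg)
    if outgroup_labels:
        try:
            tree = root_with_outgroup(tree, outgroup_labels)
        except ValueError:
            pass  # outgroup not cohesive on this data: classify unrooted
    leaf = next(
        lf for lf in tree.leaf_node_iter()
        if lf.taxon.label == candidate.id
    )
    node = leaf.parent_node
    while node is not None:
        clade = _leaf_labels(node)
        refs_in = [lab for lab in clade if lab in classes]
        support = math.nan
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = math.nan
        if refs_in and not math.isnan(support) and support >= support_threshold:
            tally: dict[str, int] = {}
            for lab in refs_in:
                tally[classes[lab]] = tally.get(classes[lab], 0) + 1
            best = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            return best, support
        node = node.parent_node
    return "unclassified", 0.0
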