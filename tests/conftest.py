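"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from srnase.cli_pipeline import analyze_okadae_tables
from srnase.srnase_features import build_domain_profile
from srnase.synthetic_data import (
    PanelSpec,
    make_allele_panel,
    make_reference_panels,
    make_slike_panels,
    make_study,
    region_annotations,
)


@pytest.fixture(scope="session")
def panel_spec() -> PanelSpec:
    return PanelSpec(seed=1)


@pytest.fixture(scope="session")
def panel(panel_spec):
    return make_allele_panel(panel_spec)


@pytest.fixture(scope="session")
def slike_panels(panel_spec):
    return make_slike_panels(panel_spec)


@pytest.fixture(scope="session")
def reference_panels(panel_spec):
    return make_reference_panels(panel_spec)


@pytest.fixture(scope="session")
def domain_profile(panel):
    return build_domain_profile(panel, region_annotations())


@pytest.fixture(scope="session")
def study_bundle(panel_spec):
    return make_study(panel_spec)


@pytest.fixture(scope="session")
def okadae_report():
    return analyze_okadae_tables()


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_global_score(a: str, b: str, submat, open_gap: float = 10.0,
                             extend_gap: float = 0.5) -> float:
    """Exhaustive enumeration of all global alignments (affine gaps:
    a gap of length L costs open + (L-1)*extend). Exponential — only for
    short sequences."""
    best = -math.inf

    def rec(i: int, j: int, prev: str | None, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + submat[a[i], b[j]])
        if i < len(a):
            cost = extend_gap if prev == "GA" else open_gap
            rec(i + 1, j, "GA", score - cost)
        if j < len(b):
            cost = extend_gap if prev == "GB" else open_gap
            rec(i, j + 1, "GB", score - cost)

    rec(0, 0, None, 0.0)
    return best


def random_additive_case(rng, n_taxa: int):
    """A random binary tree over *n_taxa* leaves with uniform branch
    lengths, returned as (labels, distance matrix, bipartition set).

    Distances are computed by explicit path summation over the generated
    tree, independently of any neighbour-joining code.
    """
    import numpy as np

    labels = [f"T{i:02d}" for i in range(n_taxa)]
    # adjacency of the growing unrooted tree
    edges: dict[int, dict[int, float]] = {}
    node_id = n_taxa

    def connect(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def blen():
        return float(rng.uniform(0.1, 1.0))

    # start from a 3-leaf star, then attach leaves to random edges
    center = node_id
    node_id += 1
    for leaf in range(3):
        connect(leaf, center, blen())
    for leaf in range(3, n_taxa):
        pairs = [(u, v) for u in edges for v in edges[u] if u < v]
        u, v = pairs[int(rng.integers(0, len(pairs)))]
        w = edges[u][v]
        mid = node_id
        node_id += 1
        split = float(rng.uniform(0.2, 0.8))
        del edges[u][v]
        del edges[v][u]
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        connect(leaf, mid, blen())

    def path_dist(src: int) -> dict[int, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in edges[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    dm = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        dist = path_dist(i)
        for j in range(n_taxa):
            dm[i, j] = dist[j]

    # bipartitions: removing each internal edge splits the leaves
    all_leaves = frozenset(labels)
    splits = set()
    for u in edges:
        for v in edges[u]:
            if u < v:
                # explore from u without crossing (u, v)
                seen = {u, v}
                stack = [u]
                side = set()
                while stack:
                    x = stack.pop()
                    if x < n_taxa:
                        side.add(labels[x])
                    for y in edges[x]:
                        if y == v and x == u:
                            continue
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                fs = frozenset(side)
                if 2 <= len(fs) <= n_taxa - 2:
                    comp = all_leaves - fs
                    splits.add(min(fs, comp, key=lambda s: (len(s), sorted(s))))
    return labels, dm, splits
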