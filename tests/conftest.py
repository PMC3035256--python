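"""Shared fixtures and independent oracles for the test suite."""

import dendropy
import numpy as np
import pytest

from pantree import DistanceMatrix, PanMatrix, SequenceCatalog


@pytest.fixture
def small_catalog() -> SequenceCatalog:
    """Five proteins over two genomes with assorted lengths."""
    return SequenceCatalog(
        lengths={"A": 100, "B": 300, "C": 120, "D": 90, "E": 200},
        genomes={"A": "g1", "B": "g1", "C": "g2", "D": "g2", "E": "g2"},
    )


@pytest.fixture
def small_panmatrix() -> PanMatrix:
    """3 genomes x 4 families with occupancies 1, 2, 2, 3."""
    return PanMatrix(
        genome_ids=["gA", "gB", "gC"],
        family_ids=["F0", "F1", "F2", "F3"],
        M=np.array(
            [
                [1, 1, 0, 1],
                [0, 1, 1, 1],
                [0, 0, 1, 1],
            ]
        ),
    )


def random_panmatrix(rng: np.random.Generator, G: int, n: int) -> PanMatrix:
    """Random binary matrix, resampling any all-zero column."""
    M = (rng.random((G, n)) < rng.uniform(0.2, 0.8)).astype(np.int8)
    for j in range(n):
        if M[:, j].sum() == 0:
            M[rng.integers(G), j] = 1
    return PanMatrix(
        genome_ids=[f"g{i:02d}" for i in range(G)],
        family_ids=[f"f{j:03d}" for j in range(n)],
        M=M,
    )


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with pantree)
# ---------------------------------------------------------------------------

def brute_force_components(nodes, pairs):
    """Transitive closure by repeated sweeping over the pair list."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for pair in pairs:
        a, b = tuple(pair)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return frozenset(frozenset(g) for g in groups.values())


def naive_upgma(dm: DistanceMatrix):
    """From-scratch UPGMA: cluster distance recomputed each step as the
    mean of the original leaf-to-leaf distances across the two clusters.

    Returns (set of bipartition keys, {leafset: height}) for the internal
    nodes, using the same lexicographic tie-break rule as the package
    (smallest-member labels, smallest (a, b) tuple first).
    """
    idx = {g: i for i, g in enumerate(dm.genome_ids)}
    clusters = [frozenset({g}) for g in dm.genome_ids]
    children: dict[frozenset, tuple[frozenset, frozenset]] = {}
    heights: dict[frozenset, float] = {}

    def cluster_dist(c1, c2):
        vals = [dm.D[idx[x], idx[y]] for x in c1 for y in c2]
        return sum(vals) / len(vals)

    tie_tol = 1e-12
    while len(clusters) > 1:
        cand = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_dist(clusters[i], clusters[j])
                key = tuple(sorted((min(clusters[i]), min(clusters[j]))))
                cand.append((d, key, clusters[i], clusters[j]))
        dmin = min(c[0] for c in cand)
        d, _, ca, cb = min(
            (c for c in cand if c[0] <= dmin + tie_tol), key=lambda c: c[1]
        )
        merged = ca | cb
        children[merged] = (ca, cb)
        heights[merged] = d / 2.0
        clusters = [c for c in clusters if c not in (ca, cb)] + [merged]

    bipartitions = {frozenset(children[c]) for c in children}
    return bipartitions, heights


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) via dendropy."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)
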