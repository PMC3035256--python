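"""UPGMA trees, column-resampling bootstrap supports, and Newick output.

UPGMA (average linkage) repeatedly merges the pair of clusters with the
smallest size-weighted mean inter-cluster distance; the merged node is
placed at height = merge distance / 2, giving a rooted ultrametric tree.
Ties are broken deterministically: each cluster is labelled by its
lexicographically smallest genome, and among minimal-distance pairs the
(smaller label, larger label) tuple that sorts first is merged.

Bootstrap supports follow the classic column bootstrap on the pan-matrix:
each replicate draws n family columns uniformly with replacement (each
column carries its weight along), recomputes the weighted distances and
the UPGMA tree, and a reference node is supported by a replicate iff the
replicate tree has an internal node splitting into the *same two leaf
sets*.  Support is the percentage of the B replicates that do.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from .distance import DistanceMatrix, _manhattan_from_arrays, manhattan
from .panmatrix import PanMatrix, WeightVector

__all__ = [
    "TreeNode",
    "ClusterTree",
    "SupportTable",
    "upgma",
    "bootstrap_supports",
    "to_newick",
]

# A node's bipartition key: the unordered pair of its two child leaf sets.
Bipartition = frozenset  # frozenset({frozenset[str], frozenset[str]})


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted binary ultrametric tree.

    Leaves carry a genome label and height 0; internal nodes carry two
    children and the height at which they were merged (merge distance / 2).
    """

    height: float
    label: Optional[str] = None
    children: tuple["TreeNode", ...] = ()
    leaves: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.leaves is None:
            if self.is_leaf:
                object.__setattr__(self, "leaves", frozenset({self.label}))
            else:
                object.__setattr__(
                    self,
                    "leaves",
                    frozenset().union(*(c.leaves for c in self.children)),
                )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def bipartition(self) -> Bipartition:
        """The unordered pair of child leaf-sets (internal nodes only)."""
        if self.is_leaf:
            raise ValueError("leaves have no bipartition")
        return frozenset(c.leaves for c in self.children)


@dataclass(frozen=True)
class ClusterTree:
    """Rooted ultrametric tree over a set of genome labels."""

    root: TreeNode
    genome_ids: list[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome_ids", list(self.genome_ids))
        if self.root.leaves != frozenset(self.genome_ids):
            raise ValueError("tree leaf set does not match genome_ids")

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[Bipartition]:
        return {n.bipartition() for n in self.internal_nodes()}

    def leaf_heights_ok(self, tol: float = 1e-9) -> bool:
        """All leaves at height 0 and heights non-decreasing toward the root."""

        def walk(node: TreeNode) -> bool:
            for c in node.children:
                if c.height > node.height + tol or not walk(c):
                    return False
            return True

        return walk(self.root)


@dataclass(frozen=True)
class SupportTable:
    """Bootstrap supports keyed by internal-node bipartition."""

    supports: Mapping[Bipartition, float]  # percentages in [0, 100]
    B: int
    seed: int

    def __post_init__(self) -> None:
        for key, val in self.supports.items():
            if not 0.0 <= val <= 100.0:
                raise ValueError(f"support {val} outside [0, 100]")

    def support_of(self, node: TreeNode) -> float:
        return float(self.supports[node.bipartition()])


def upgma(D: DistanceMatrix) -> ClusterTree:
    """Build the UPGMA tree from a distance matrix.

    Merge distances under average linkage are monotone (the linkage is
    reducible), so node heights never decrease toward the root and the
    result is ultrametric.
    """
    G = D.n_genomes
    if G < 2:
        raise ValueError("UPGMA needs at least 2 genomes")
    if not np.isfinite(D.D).all():
        raise ValueError("non-finite distances")

    # Cluster label = lexicographically smallest member genome id.
    nodes: dict[str, TreeNode] = {
        g: TreeNode(height=0.0, label=g) for g in D.genome_ids
    }
    sizes: dict[str, int] = {g: 1 for g in D.genome_ids}
    idx = {g: i for i, g in enumerate(D.genome_ids)}
    dist: dict[frozenset[str], float] = {}
    labels = sorted(D.genome_ids)
    for a_i, a in enumerate(labels):
        for b in labels[a_i + 1:]:
            dist[frozenset((a, b))] = float(D.D[idx[a], idx[b]])

    # Ties are detected with a small absolute tolerance so that the
    # size-weighted recursion and a direct mean over leaf pairs (which can
    # differ by float rounding) make the same merge decisions.
    tie_tol = 1e-12
    active = set(labels)
    while len(active) > 1:
        dmin = min(dist.values())
        best = min(
            tuple(sorted(pair))
            for pair, d in dist.items()
            if d <= dmin + tie_tol
        )
        a, b = best
        pair_key = frozenset((a, b))
        d_merge = dist[pair_key]
        merged = TreeNode(
            height=d_merge / 2.0,
            children=(nodes[a], nodes[b]),  # label order: a < b
        )
        new_label = a  # min(a, b)
        new_size = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            d_ac = dist[frozenset((a, c))]
            d_bc = dist[frozenset((b, c))]
            d_new = (sizes[a] * d_ac + sizes[b] * d_bc) / new_size
            del dist[frozenset((a, c))]
            del dist[frozenset((b, c))]
            dist[frozenset((new_label, c))] = d_new
        del dist[pair_key]
        active.discard(b)
        nodes[new_label] = merged
        sizes[new_label] = new_size

    root = nodes[next(iter(active))]
    return ClusterTree(root=root, genome_ids=list(D.genome_ids))


def bootstrap_supports(
    P: PanMatrix,
    w: WeightVector,
    B: int,
    seed: int,
    distance_fn: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
    max_zero_weight_retries: int = 100,
) -> tuple[ClusterTree, SupportTable]:
    """Reference UPGMA tree plus bootstrap supports from column resampling.

    Each of the B replicates draws n column indices uniformly with
    replacement; each sampled column keeps its weight, W is recomputed for
    the replicate, and the replicate's UPGMA tree is built from the
    reweighted Manhattan distances.  A reference internal node's support is
    the percentage of replicates whose tree contains a node with the same
    two child leaf-sets.  Replicate r is a deterministic function of
    (seed, r); a replicate whose resampled total weight is zero is redrawn,
    up to ``max_zero_weight_retries`` times.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if w.W <= 0:
        raise ValueError("total weight W must be positive")
    if distance_fn is None:
        distance_fn = _manhattan_from_arrays

    ref_tree = upgma(manhattan(P, w))
    ref_keys = [n.bipartition() for n in ref_tree.internal_nodes()]
    counts = {key: 0 for key in ref_keys}

    n = P.n_families
    children = np.random.SeedSequence(seed).spawn(B)
    for r in range(B):
        rng = np.random.default_rng(children[r])
        for attempt in range(max_zero_weight_retries + 1):
            cols = rng.integers(0, n, size=n)
            wr = w.w[cols]
            if wr.sum() > 0:
                break
        else:
            raise RuntimeError(
                f"replicate {r}: resampled total weight was zero in "
                f"{max_zero_weight_retries + 1} draws"
            )
        Dr = distance_fn(P.M[:, cols], wr)
        tree_r = upgma(DistanceMatrix(genome_ids=P.genome_ids, D=Dr))
        keys_r = tree_r.bipartitions()
        for key in counts:
            if key in keys_r:
                counts[key] += 1

    supports = {key: 100.0 * c / B for key, c in counts.items()}
    return ref_tree, SupportTable(supports=supports, B=B, seed=seed)


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(
    tree: ClusterTree, supports: Optional[SupportTable] = None
) -> str:
    """Serialize to Newick with branch lengths (parent height - node height).

    Bootstrap supports, if given, are written as internal node labels,
    rounded to integer percentages.  Labels containing Newick-reserved
    characters are single-quoted.  The root carries no branch length.
    """

    def render(node: TreeNode, parent_height: Optional[float]) -> str:
        if node.is_leaf:
            body = _newick_label(node.label)
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            body = f"({inner})"
            if supports is not None:
                body += str(int(round(supports.support_of(node))))
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.12g}"

    return render(tree.root, None) + ";"
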