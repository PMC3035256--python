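"""Synthetic pan-genome data with known ground truth.

Three generators make every pipeline stage testable without downloads:

* :func:`simulate_panmatrix` plants an occupancy spectrum with explicit
  core / shell / cloud structure — core families occur in all G genomes,
  shell and cloud families get occupancies drawn from configurable ranges
  and a uniformly random genome subset of that size.

* :func:`simulate_gainloss` evolves gene content along a known guide tree
  under the simplest independent-events model: along a branch of length t
  each present family is lost with probability 1 - exp(-loss_rate * t) and
  Poisson(gain_rate * t) novel families are gained.  The leaf family sets
  become a pan-matrix whose true tree is known, for topology-recovery and
  bootstrap-stability tests.  The model deliberately ignores sequence
  evolution and correlated gain/loss.

* :func:`simulate_alignment_table` emits a mock all-vs-all hit table whose
  reciprocal-hit structure encodes a planted family partition: every
  within-family pair gets qualifying hits in both directions, and decoy
  cross-family hits fail exactly one clause of the rule (coverage,
  identity, or reciprocity) so each clause is exercised independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import dendropy
import numpy as np

from .families import AlignmentHit, GeneFamilySet, SequenceCatalog
from .panmatrix import PanMatrix

__all__ = [
    "SimulationConfig",
    "GainLossConfig",
    "simulate_panmatrix",
    "simulate_gainloss",
    "simulate_planted_families",
    "simulate_alignment_table",
    "write_blast_tabular",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Planted occupancy-spectrum configuration.

    Core families always have occupancy G; shell and cloud occupancies are
    drawn uniformly from the given inclusive ranges (defaults: shell in the
    upper majority below G, cloud in the lower minority), so the planted
    class structure is recoverable from the spectrum.
    """

    G: int
    n_core: int
    n_shell: int
    n_cloud: int
    shell_occupancy_range: Optional[tuple[int, int]] = None
    cloud_occupancy_range: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("G must be >= 2")
        if min(self.n_core, self.n_shell, self.n_cloud) < 0:
            raise ValueError("family counts must be >= 0")
        if self.shell_occupancy_range is None:
            lo = max(2, (2 * self.G) // 3)
            object.__setattr__(
                self, "shell_occupancy_range", (lo, max(lo, self.G - 1))
            )
        if self.cloud_occupancy_range is None:
            hi = max(1, self.G // 3)
            object.__setattr__(self, "cloud_occupancy_range", (1, hi))
        for name in ("shell_occupancy_range", "cloud_occupancy_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= self.G):
                raise ValueError(f"{name} ({lo}, {hi}) outside [1, {self.G}]")


@dataclass(frozen=True)
class GainLossConfig:
    """Gene gain/loss along a known rooted guide tree.

    ``guide_tree`` is a rooted binary tree with branch lengths (a Newick
    string or a dendropy Tree); rates are events per unit branch length.
    """

    guide_tree: Union[str, dendropy.Tree]
    root_genome_size: int
    gain_rate: float
    loss_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_genome_size < 1:
            raise ValueError("root_genome_size must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")

    def tree(self) -> dendropy.Tree:
        if isinstance(self.guide_tree, dendropy.Tree):
            return self.guide_tree
        return dendropy.Tree.get(data=self.guide_tree, schema="newick")


def simulate_panmatrix(cfg: SimulationConfig) -> PanMatrix:
    """Pan-matrix with a planted core/shell/cloud occupancy spectrum."""
    rng = np.random.default_rng(cfg.seed)
    columns: list[tuple[str, np.ndarray]] = []

    for i in range(cfg.n_core):
        columns.append((f"core{i:04d}", np.ones(cfg.G, dtype=np.int8)))
    for prefix, count, (lo, hi) in (
        ("shell", cfg.n_shell, cfg.shell_occupancy_range),
        ("cloud", cfg.n_cloud, cfg.cloud_occupancy_range),
    ):
        for i in range(count):
            k = int(rng.integers(lo, hi + 1))
            col = np.zeros(cfg.G, dtype=np.int8)
            col[rng.choice(cfg.G, size=k, replace=False)] = 1
            columns.append((f"{prefix}{i:04d}", col))

    if not columns:
        raise ValueError("no families requested")
    family_ids = [fid for fid, _ in columns]
    M = np.column_stack([col for _, col in columns])
    genome_ids = [f"genome{i:03d}" for i in range(cfg.G)]
    return PanMatrix(genome_ids=genome_ids, family_ids=family_ids, M=M)


def simulate_gainloss(cfg: GainLossConfig) -> tuple[PanMatrix, dendropy.Tree]:
    """Evolve family presence/absence along the guide tree.

    Returns the leaf pan-matrix (families present in no leaf are dropped)
    and the guide tree itself as the true tree.  Raises if every family is
    lost from every leaf.
    """
    tree = cfg.tree()
    rng = np.random.default_rng(cfg.seed)
    gain_counter = 0

    root_set = frozenset(f"anc{i:05d}" for i in range(cfg.root_genome_size))
    node_sets: dict[dendropy.Node, frozenset[str]] = {}
    leaf_sets: dict[str, frozenset[str]] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            current = root_set
        else:
            t = node.edge.length or 0.0
            parent = node_sets[node.parent_node]
            p_keep = math.exp(-cfg.loss_rate * t)
            kept = frozenset(
                fid for fid in sorted(parent) if rng.random() < p_keep
            )
            n_gain = int(rng.poisson(cfg.gain_rate * t))
            gained = frozenset(
                f"nov{gain_counter + i:06d}" for i in range(n_gain)
            )
            gain_counter += n_gain
            current = kept | gained
        node_sets[node] = current
        if node.is_leaf():
            label = node.taxon.label if node.taxon else str(id(node))
            leaf_sets[label] = current

    all_families = sorted(set().union(*leaf_sets.values()))
    if not all_families:
        raise ValueError(
            "all families lost from every leaf; lower loss_rate or shorten "
            "the branches"
        )
    genome_ids = sorted(leaf_sets)
    fam_index = {f: j for j, f in enumerate(all_families)}
    M = np.zeros((len(genome_ids), len(all_families)), dtype=np.int8)
    for i, g in enumerate(genome_ids):
        for fid in leaf_sets[g]:
            M[i, fam_index[fid]] = 1
    return PanMatrix(genome_ids=genome_ids, family_ids=all_families, M=M), tree


def simulate_planted_families(
    n_genomes: int,
    family_sizes: list[int],
    seed: int = 0,
    min_length: int = 80,
    max_length: int = 400,
) -> tuple[GeneFamilySet, SequenceCatalog]:
    """A random planted family partition with a matching sequence catalog.

    Sequences get lengths uniform in [min_length, max_length]; genomes are
    assigned so that every genome carries at least one sequence.
    """
    if n_genomes < 1:
        raise ValueError("need at least 1 genome")
    if any(s < 1 for s in family_sizes):
        raise ValueError("family sizes must be >= 1")
    rng = np.random.default_rng(seed)
    genome_ids = [f"genome{i:03d}" for i in range(n_genomes)]

    lengths: dict[str, int] = {}
    genomes: dict[str, str] = {}
    families: dict[str, frozenset[str]] = {}
    counter = 0
    for f, size in enumerate(family_sizes):
        members = []
        for _ in range(size):
            sid = f"seq{counter:05d}"
            # round-robin first so every genome is covered, then random
            if counter < n_genomes:
                g = genome_ids[counter]
            else:
                g = genome_ids[int(rng.integers(n_genomes))]
            lengths[sid] = int(rng.integers(min_length, max_length + 1))
            genomes[sid] = g
            members.append(sid)
            counter += 1
        families[f"planted{f:04d}"] = frozenset(members)
    if counter < n_genomes:
        raise ValueError(
            f"{counter} sequences cannot cover {n_genomes} genomes"
        )
    catalog = SequenceCatalog(lengths=lengths, genomes=genomes)
    return GeneFamilySet(families=families), catalog


def _qualifying_hit(
    rng: np.random.Generator, query: str, subject: str, qlen: int
) -> AlignmentHit:
    aln = max(1, int(math.ceil(0.75 * qlen)))
    identity = float(rng.uniform(60.0, 95.0))
    return AlignmentHit(
        query_id=query,
        subject_id=subject,
        pct_identity=round(identity, 1),
        aln_length=aln,
        evalue=float(10.0 ** -rng.uniform(20, 60)),
    )


def simulate_alignment_table(
    families: GeneFamilySet,
    catalog: SequenceCatalog,
    seed: int = 0,
    n_decoys: int = 30,
) -> list[AlignmentHit]:
    """Mock all-vs-all hits encoding a planted family partition.

    Every within-family ordered pair gets a qualifying hit (coverage 0.75
    of the query, identity 60-95%, tiny E-value) plus self-hits, so
    re-clustering recovers the partition.  ``n_decoys`` cross-family decoy
    hits are added, cycling through the three failure modes: coverage
    below 50%, identity below 50%, and a missing reciprocal direction.
    """
    rng = np.random.default_rng(seed)
    hits: list[AlignmentHit] = []

    for sid in sorted(catalog.lengths):
        hits.append(
            AlignmentHit(
                query_id=sid,
                subject_id=sid,
                pct_identity=100.0,
                aln_length=catalog.length(sid),
                evalue=0.0,
            )
        )

    for fid in families.family_ids:
        members = sorted(families.families[fid])
        for a in members:
            for b in members:
                if a == b:
                    continue
                hits.append(_qualifying_hit(rng, a, b, catalog.length(a)))

    seq_ids = sorted(catalog.lengths)
    fam_of = families.family_of
    used: set[frozenset[str]] = set()
    modes = ("coverage", "identity", "reciprocity")
    attempts = 0
    made = 0
    while made < n_decoys and attempts < 50 * max(n_decoys, 1):
        attempts += 1
        a, b = (seq_ids[int(i)] for i in rng.integers(len(seq_ids), size=2))
        if a == b or fam_of[a] == fam_of[b]:
            continue
        key = frozenset((a, b))
        if key in used:
            continue
        mode = modes[made % 3]
        la, lb = catalog.length(a), catalog.length(b)
        if mode == "coverage":
            aln_a, aln_b = max(1, int(0.3 * la)), max(1, int(0.3 * lb))
            if aln_a / la >= 0.5 or aln_b / lb >= 0.5:
                continue
            hits.append(AlignmentHit(a, b, 85.0, aln_a, 1e-12))
            hits.append(AlignmentHit(b, a, 85.0, aln_b, 1e-12))
        elif mode == "identity":
            hits.append(AlignmentHit(a, b, 30.0, int(0.9 * la), 1e-12))
            hits.append(AlignmentHit(b, a, 30.0, int(0.9 * lb), 1e-12))
        else:  # reciprocity: one qualifying direction only
            hits.append(_qualifying_hit(rng, a, b, la))
        used.add(key)
        made += 1
    return hits


def write_blast_tabular(hits: list[AlignmentHit], path) -> None:
    """Write hits as 12-column BLAST ``-outfmt 6`` lines.

    Columns the family rule does not use (mismatch, gapopen, coordinates,
    bitscore) are filled with consistent placeholder values.
    """
    with open(path, "w") as fh:
        for h in hits:
            mismatch = int(h.aln_length * (1.0 - h.pct_identity / 100.0))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t"
                f"{h.aln_length}\t{mismatch}\t0\t1\t{h.aln_length}\t1\t"
                f"{h.aln_length}\t{h.evalue:.3g}\t{max(30.0, 2.0 * h.aln_length):.1f}\n"
            )
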