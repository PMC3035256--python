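"""Distances between pan-genome profiles.

The primary distance is the weighted relative Manhattan distance

    D(i, k) = (1 / W) * sum_j  w_j * |M_ij - M_kj|,       W = sum_j w_j,

the proportion (by weight) of the pan-genome in which genomes i and k
differ.  With uniform weights it reduces to (b + c) / n, where b and c
count families present in exactly one of the two genomes and n is the
total number of families.  Unlike the Jaccard distance, it treats shared
*absence* of a family as similarity: appending families absent from both
genomes grows the denominator W and lowers the pair's distance, while
Jaccard ignores such columns.

The Jaccard distance 1 - a/(a+b+c) (a = families shared) is provided,
unweighted, for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panmatrix import PanMatrix, WeightVector

__all__ = ["DistanceMatrix", "manhattan", "jaccard", "write_distances_tsv",
           "write_distances_phylip"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric genome x genome distances in [0, 1], zero diagonal."""

    genome_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=np.float64)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "genome_ids", list(self.genome_ids))
        G = len(self.genome_ids)
        if D.shape != (G, G):
            raise ValueError(f"distance matrix shape {D.shape} != ({G}, {G})")
        if not np.isfinite(D).all():
            raise ValueError("non-finite distance")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(D)).max(initial=0.0) > 1e-12:
            raise ValueError("nonzero diagonal")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def get(self, a: str, b: str) -> float:
        i = self.genome_ids.index(a)
        k = self.genome_ids.index(b)
        return float(self.D[i, k])


def _manhattan_from_arrays(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted relative Manhattan distances between the rows of a binary M.

    Uses |M_ij - M_kj| = M_ij + M_kj - 2 M_ij M_kj for binary entries, so
    the whole matrix is one rank-G product instead of a per-pair loop.
    """
    W = float(w.sum())
    if W <= 0:
        raise ValueError("total weight W must be positive")
    Mf = M.astype(np.float64)
    Mw = Mf * w
    s = Mw.sum(axis=1)
    inner = Mw @ Mf.T
    D = (s[:, None] + s[None, :] - 2.0 * inner) / W
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)  # kill rounding asymmetry/negatives
    np.fill_diagonal(D, 0.0)
    return D


def manhattan(P: PanMatrix, w: WeightVector) -> DistanceMatrix:
    """Weighted relative Manhattan distance between all genome profiles."""
    if w.family_ids != P.family_ids:
        if len(w) != P.n_families:
            raise ValueError(
                f"weight vector length {len(w)} != {P.n_families} families"
            )
        raise ValueError("weight vector family_ids do not match pan-matrix columns")
    if w.W <= 0:
        raise ValueError("total weight W must be positive")
    D = _manhattan_from_arrays(P.M, w.w)
    return DistanceMatrix(genome_ids=P.genome_ids, D=D)


def jaccard(P: PanMatrix) -> DistanceMatrix:
    """Jaccard distance 1 - a/(a+b+c) between all genome profiles.

    a counts families present in both genomes, b and c those present in
    exactly one.  Families absent from both are ignored, so the distance is
    blind to shared absence.  Unweighted.
    """
    M = P.M.astype(np.float64)
    inter = M @ M.T
    s = M.sum(axis=1)
    union = s[:, None] + s[None, :] - inter
    off_diag = ~np.eye(P.n_genomes, dtype=bool)
    if (union[off_diag] == 0).any():
        i, k = np.argwhere((union == 0) & off_diag)[0]
        raise ValueError(
            f"genomes {P.genome_ids[i]!r} and {P.genome_ids[k]!r} share no "
            "present family (empty union)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(genome_ids=P.genome_ids, D=D)


def write_distances_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square distance matrix as TSV with genome ids as header and first column."""
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(dm.genome_ids) + "\n")
        for i, g in enumerate(dm.genome_ids):
            row = "\t".join(f"{x:.10g}" for x in dm.D[i])
            fh.write(f"{g}\t{row}\n")


def write_distances_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square-matrix PHYLIP format (relaxed names, whitespace separated)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n_genomes}\n")
        for i, g in enumerate(dm.genome_ids):
            row = "  ".join(f"{x:.6f}" for x in dm.D[i])
            fh.write(f"{g:<12s}{row}\n")
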