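"""The pan-matrix, its occupancy spectrum, and gene-family weight schemes.

The pan-matrix ``M`` is a binary genomes x gene-families matrix: ``M[i, j]``
is 1 iff family *j* occurs in genome *i*.  A family's *occupancy* is the
number of genomes carrying it; the occupancy spectrum counts families at
each occupancy 1..G.  Families present in every genome form the *core*,
families in a majority the *shell*, families in a minority the *cloud*;
families seen in exactly one genome are *ORFans*.

Weight schemes assign a per-family weight from occupancy alone, so families
with equal occupancy always get equal weight:

* ``uniform``      — w_j = 1
* ``drop_orfans``  — w_j = 0 if occupancy is 1, else 1
* ``shell``        — w_j = (k_j - 1) / (G - 1), a linear ramp emphasizing
                     widely conserved families
* ``cloud``        — w_j = (G - k_j) / (G - 1), the opposite ramp
                     emphasizing rare, strain-specific families

Boolean ``drop_orfans`` / ``drop_core`` flags zero the corresponding
columns after any base scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PanMatrix",
    "OccupancySpectrum",
    "WeightVector",
    "ZeroWeightError",
    "occupancy",
    "make_weights",
    "write_weights",
    "WEIGHT_SCHEMES",
]

WEIGHT_SCHEMES = ("uniform", "drop_orfans", "shell", "cloud")


class ZeroWeightError(ValueError):
    """All family weights vanished; distances would be 0/0."""


@dataclass(frozen=True)
class PanMatrix:
    """Binary genomes x gene-families presence/absence matrix."""

    genome_ids: list[str]
    family_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.int8)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "genome_ids", list(self.genome_ids))
        object.__setattr__(self, "family_ids", list(self.family_ids))
        if M.ndim != 2:
            raise ValueError("M must be a 2-D matrix")
        G, n = M.shape
        if G != len(self.genome_ids) or n != len(self.family_ids):
            raise ValueError(
                f"shape {M.shape} does not match {len(self.genome_ids)} genomes "
                f"x {len(self.family_ids)} families"
            )
        if len(set(self.genome_ids)) != G:
            raise ValueError("duplicate genome_ids")
        if len(set(self.family_ids)) != n:
            raise ValueError("duplicate family_ids")
        if not np.isin(M, (0, 1)).all():
            bad = np.argwhere(~np.isin(M, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at genome {self.genome_ids[bad[0]]!r}, "
                f"family {self.family_ids[bad[1]]!r}"
            )
        if n and (M.sum(axis=0) == 0).any():
            j = int(np.argmax(M.sum(axis=0) == 0))
            raise ValueError(
                f"family {self.family_ids[j]!r} is present in no genome"
            )

    @property
    def n_genomes(self) -> int:
        return self.M.shape[0]

    @property
    def n_families(self) -> int:
        return self.M.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanMatrix):
            return NotImplemented
        return (
            self.genome_ids == other.genome_ids
            and self.family_ids == other.family_ids
            and np.array_equal(self.M, other.M)
        )

    def column_occupancy(self) -> np.ndarray:
        """Per-family occupancy k_j: number of genomes carrying family j."""
        return self.M.sum(axis=0).astype(np.int64)

    def write(self, path: str | Path) -> None:
        """Write as TSV: header row of family ids, first column 'genome'."""
        df = pd.DataFrame(self.M, index=self.genome_ids, columns=self.family_ids)
        df.index.name = "genome"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "PanMatrix":
        """Read the TSV layout produced by :meth:`write`.

        Round-trips with write; non-binary entries and duplicated genome or
        family ids are rejected with the offending label in the message.
        """
        # check the raw header before pandas de-duplicates repeated names
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dupe = next(f for f in header if header.count(f) > 1)
            raise ValueError(f"{path}: duplicate family id {dupe!r}")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        family_ids = header
        genome_ids = [str(i) for i in df.index]
        if len(set(genome_ids)) != len(genome_ids):
            dupe = next(g for g in genome_ids if genome_ids.count(g) > 1)
            raise ValueError(f"{path}: duplicate genome id {dupe!r}")
        M = np.zeros(df.shape, dtype=np.int8)
        for i, g in enumerate(genome_ids):
            for j, f in enumerate(family_ids):
                raw = df.iat[i, j]
                if raw not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary entry {raw!r} at genome {g!r}, "
                        f"family {f!r}"
                    )
                M[i, j] = int(raw)
        return cls(genome_ids=genome_ids, family_ids=family_ids, M=M)


@dataclass(frozen=True)
class OccupancySpectrum:
    """count[k] = number of families found in exactly k genomes, k = 1..G."""

    G: int
    counts: np.ndarray  # length G; counts[k-1] is the count at occupancy k

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.G,):
            raise ValueError(f"expected {self.G} counts, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative count in occupancy spectrum")

    def __getitem__(self, k: int) -> int:
        if not 1 <= k <= self.G:
            raise KeyError(f"occupancy {k} outside 1..{self.G}")
        return int(self.counts[k - 1])

    @property
    def n_families(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {k: int(self.counts[k - 1]) for k in range(1, self.G + 1)}


@dataclass(frozen=True)
class WeightVector:
    """Per-family weights aligned to a pan-matrix's family ids."""

    family_ids: list[str]
    w: np.ndarray
    scheme_name: str
    occupancies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "family_ids", list(self.family_ids))
        if w.shape != (len(self.family_ids),):
            raise ValueError("weight vector length does not match family_ids")
        if (w < 0).any():
            raise ValueError("negative weight")
        if self.occupancies is not None:
            occ = np.asarray(self.occupancies, dtype=np.int64)
            object.__setattr__(self, "occupancies", occ)

    @property
    def W(self) -> float:
        """Total weight, the denominator of the relative Manhattan distance."""
        return float(self.w.sum())

    def __len__(self) -> int:
        return len(self.family_ids)


def occupancy(P: PanMatrix) -> OccupancySpectrum:
    """Occupancy spectrum: how many families occur in exactly k genomes."""
    k = P.column_occupancy()
    counts = np.bincount(k, minlength=P.n_genomes + 1)[1:]
    return OccupancySpectrum(G=P.n_genomes, counts=counts)


def make_weights(
    P: PanMatrix,
    scheme: str = "uniform",
    drop_orfans: bool = False,
    drop_core: bool = False,
) -> WeightVector:
    """Per-family weights from occupancy under a named scheme.

    The ``drop_orfans`` and ``drop_core`` flags zero single-genome and
    all-genome families respectively, after the base scheme, so they
    compose with any of the four schemes.  Raises :class:`ZeroWeightError`
    if every weight vanishes (e.g. the cloud scheme on a pure-core matrix).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {WEIGHT_SCHEMES}")
    G = P.n_genomes
    k = P.column_occupancy().astype(np.float64)
    if scheme == "uniform":
        w = np.ones_like(k)
    elif scheme == "drop_orfans":
        w = np.where(k == 1, 0.0, 1.0)
    else:
        if G < 2:
            raise ValueError(f"{scheme} weights need at least 2 genomes")
        if scheme == "shell":
            w = (k - 1.0) / (G - 1.0)
        else:  # cloud
            w = (G - k) / (G - 1.0)
    if drop_orfans:
        w = np.where(k == 1, 0.0, w)
    if drop_core:
        w = np.where(k == G, 0.0, w)
    if w.sum() == 0:
        raise ZeroWeightError(
            f"all weights vanished under scheme {scheme!r} "
            f"(drop_orfans={drop_orfans}, drop_core={drop_core})"
        )
    return WeightVector(
        family_ids=P.family_ids,
        w=w,
        scheme_name=scheme,
        occupancies=P.column_occupancy(),
    )


def write_weights(weights: WeightVector, path: str | Path) -> None:
    """Write weights as TSV: family_id, occupancy, weight."""
    occ = weights.occupancies
    if occ is None:
        occ = np.full(len(weights), -1, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("family_id\toccupancy\tweight\n")
        for fid, k, w in zip(weights.family_ids, occ, weights.w):
            fh.write(f"{fid}\t{int(k)}\t{w:.10g}\n")
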