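"""Gene-family clustering from all-vs-all protein alignment hits.

Proteins are grouped into gene families by a reciprocal coverage/identity
rule: two sequences belong together when, with *either* sequence used as
query, there is a significant alignment (E-value below a cutoff, default
1e-5) that spans at least half of that query's length and has at least 50%
identity over the aligned region.  The pairwise relation is closed
transitively: families are the connected components of the graph whose
edges are the qualifying reciprocal pairs (single linkage).

Input is standard 12-column BLAST tabular output (``-outfmt 6``); sequence
lengths and genome membership come from a catalog built from protein FASTA
files (one per genome) or from a 3-column TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .panmatrix import PanMatrix

__all__ = [
    "AlignmentHit",
    "SequenceCatalog",
    "GeneFamilySet",
    "BlastParseError",
    "parse_blast_tabular",
    "reciprocal_pairs",
    "build_families",
    "families_to_panmatrix",
    "write_family_table",
]

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_MIN_IDENTITY = 0.5


class BlastParseError(ValueError):
    """A BLAST tabular line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a BLAST tabular file (the columns the family rule uses).

    ``pct_identity`` is the percent identity over the aligned region, in
    [0, 100]; ``aln_length`` is the number of aligned columns; ``evalue``
    the alignment's expectation value.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} must be >= 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} must be non-negative")


@dataclass(frozen=True)
class SequenceCatalog:
    """Per-sequence length (residues) and genome membership.

    Maps each protein sequence id to its length and the genome it belongs
    to.  The length is the denominator of the coverage rule — the fraction
    of the *query* sequence an alignment spans.
    """

    lengths: Mapping[str, int]
    genomes: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.lengths) != set(self.genomes):
            raise ValueError("lengths and genomes must cover the same seq_ids")
        for sid, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"sequence {sid!r} has length {length} < 1")

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def seq_ids(self) -> list[str]:
        return sorted(self.lengths)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(set(self.genomes.values()))

    def length(self, seq_id: str) -> int:
        return self.lengths[seq_id]

    def genome(self, seq_id: str) -> str:
        return self.genomes[seq_id]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SequenceCatalog":
        """Read a headerless 3-column TSV: seq_id, length, genome_id."""
        lengths: dict[str, int] = {}
        genomes: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                sid, length_s, genome = parts
                if sid in lengths:
                    raise ValueError(f"{path}: line {lineno}: duplicate seq_id {sid!r}")
                try:
                    length = int(length_s)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-integer length {length_s!r}"
                    ) from exc
                lengths[sid] = length
                genomes[sid] = genome
        return cls(lengths=lengths, genomes=genomes)

    @classmethod
    def from_fastas(cls, paths: Sequence[str | Path]) -> "SequenceCatalog":
        """Build a catalog from protein FASTA files, one per genome.

        The genome id is the file stem; sequence lengths are taken from the
        records themselves.
        """
        from Bio import SeqIO

        lengths: dict[str, int] = {}
        genomes: dict[str, str] = {}
        for path in paths:
            genome_id = Path(path).stem
            for rec in SeqIO.parse(str(path), "fasta"):
                if rec.id in lengths:
                    raise ValueError(f"duplicate seq_id {rec.id!r} (in {path})")
                lengths[rec.id] = len(rec.seq)
                genomes[rec.id] = genome_id
        return cls(lengths=lengths, genomes=genomes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in self.seq_ids:
                fh.write(f"{sid}\t{self.lengths[sid]}\t{self.genomes[sid]}\n")


@dataclass(frozen=True)
class GeneFamilySet:
    """A partition of the sequence catalog into gene families."""

    families: Mapping[str, frozenset[str]]
    family_of: Mapping[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family_of is None:
            inverse = {
                sid: fid for fid, members in self.families.items() for sid in members
            }
            object.__setattr__(self, "family_of", inverse)
        total = sum(len(m) for m in self.families.values())
        if total != len(self.family_of):
            raise ValueError("families must be disjoint (a seq_id appears twice)")
        if any(len(m) == 0 for m in self.families.values()):
            raise ValueError("empty family not allowed")

    def __len__(self) -> int:
        return len(self.families)

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def as_partition(self) -> frozenset[frozenset[str]]:
        """The partition ignoring family labels (for order-invariance checks)."""
        return frozenset(self.families.values())


def parse_blast_tabular(
    path: str | Path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[AlignmentHit]:
    """Parse BLAST ``-outfmt 6`` tabular output, keeping hits with
    E-value <= ``evalue_cutoff``.

    Columns are the standard qseqid, sseqid, pident, length, mismatch,
    gapopen, qstart, qend, sstart, send, evalue, bitscore; extra trailing
    columns are tolerated.  File order is preserved; self-hits are kept
    (they are ignored later when pairs are formed).  Lines starting with
    ``#`` and blank lines are skipped.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastParseError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                aln_length = int(fields[3])
                evalue = float(fields[10])
            except ValueError as exc:
                raise BlastParseError(
                    f"{path}: line {lineno}: non-numeric identity/length/evalue "
                    f"({fields[2]!r}, {fields[3]!r}, {fields[10]!r})"
                ) from exc
            if not math.isfinite(evalue) or evalue < 0:
                raise BlastParseError(
                    f"{path}: line {lineno}: invalid evalue {fields[10]!r}"
                )
            if evalue <= evalue_cutoff:
                hits.append(
                    AlignmentHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=pident,
                        aln_length=aln_length,
                        evalue=evalue,
                    )
                )
    return hits


def reciprocal_pairs(
    hits: Iterable[AlignmentHit],
    catalog: SequenceCatalog,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> set[frozenset[str]]:
    """Unordered pairs {a, b} for which *both* alignment directions qualify.

    A direction query->subject qualifies when some hit for it has
    ``aln_length / length(query) >= min_coverage`` and
    ``pct_identity / 100 >= min_identity``.  Coverage is always relative to
    that direction's query length.  Self-hits are ignored; when several
    hits (HSPs) exist for a direction, any single qualifying hit suffices.
    """
    if not 0 < min_coverage <= 1 or not 0 < min_identity <= 1:
        raise ValueError("min_coverage and min_identity must be in (0, 1]")
    qualifying: set[tuple[str, str]] = set()
    for hit in hits:
        for sid in (hit.query_id, hit.subject_id):
            if sid not in catalog:
                raise KeyError(f"hit references seq_id {sid!r} absent from catalog")
        if hit.query_id == hit.subject_id:
            continue
        coverage = hit.aln_length / catalog.length(hit.query_id)
        if coverage >= min_coverage and hit.pct_identity / 100.0 >= min_identity:
            qualifying.add((hit.query_id, hit.subject_id))
    return {
        frozenset((a, b))
        for (a, b) in qualifying
        if (b, a) in qualifying and a < b  # emit each unordered pair once
    }


def build_families(
    pairs: Iterable[frozenset[str]], catalog: SequenceCatalog
) -> GeneFamilySet:
    """Group sequences into families as connected components.

    Every sequence in the catalog is a node; qualifying reciprocal pairs
    are edges.  Sequences with no edge form singleton families.  Family ids
    are ``F`` + zero-padded index, assigned in order of each component's
    lexicographically smallest member, so labels are reproducible.
    """
    graph = nx.Graph()
    graph.add_nodes_from(catalog.lengths)
    for pair in pairs:
        members = tuple(pair)
        if len(members) != 2:
            raise ValueError(f"pair {set(pair)} does not have exactly 2 members")
        for sid in members:
            if sid not in catalog:
                raise KeyError(f"pair references seq_id {sid!r} absent from catalog")
        graph.add_edge(*members)
    components = sorted(nx.connected_components(graph), key=min)
    pad = max(4, len(str(max(len(components) - 1, 0))))
    families = {
        f"F{idx:0{pad}d}": frozenset(comp) for idx, comp in enumerate(components)
    }
    return GeneFamilySet(families=families)


def families_to_panmatrix(
    families: GeneFamilySet, catalog: SequenceCatalog
) -> PanMatrix:
    """Binary genomes x families presence/absence matrix.

    An entry is 1 iff the family contains at least one sequence from that
    genome — paralogs within a genome still give a single 1.  Rows are
    ordered by genome id, columns by family id.
    """
    genome_ids = catalog.genome_ids
    family_ids = families.family_ids
    genome_index = {g: i for i, g in enumerate(genome_ids)}
    family_index = {f: j for j, f in enumerate(family_ids)}
    M = np.zeros((len(genome_ids), len(family_ids)), dtype=np.int8)
    for fid, members in families.families.items():
        j = family_index[fid]
        for sid in members:
            M[genome_index[catalog.genome(sid)], j] = 1
    return PanMatrix(genome_ids=genome_ids, family_ids=family_ids, M=M)


def write_family_table(
    families: GeneFamilySet, catalog: SequenceCatalog, path: str | Path
) -> None:
    """Write the family assignment as TSV: family_id, seq_id, genome_id."""
    with open(path, "w") as fh:
        fh.write("family_id\tseq_id\tgenome_id\n")
        for fid in families.family_ids:
            for sid in sorted(families.families[fid]):
                fh.write(f"{fid}\t{sid}\t{catalog.genome(sid)}\n")
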