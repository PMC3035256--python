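"""Gene-family clustering: BLAST parsing, the reciprocal 50/50 rule, and
connected-component family construction."""

import numpy as np
import pytest

from pantree import (
    AlignmentHit,
    BlastParseError,
    SequenceCatalog,
    build_families,
    families_to_panmatrix,
    parse_blast_tabular,
    reciprocal_pairs,
)
from .conftest import brute_force_components


def _hit(q, s, ident, aln, evalue=1e-20):
    return AlignmentHit(q, s, ident, aln, evalue)


def _blast_line(q, s, ident, aln, evalue):
    mid = "\t".join(["5", "1", "1", str(aln), "1", str(aln)])
    return f"{q}\t{s}\t{ident}\t{aln}\t{mid}\t{evalue}\t150.0"


class TestParseBlastTabular:
    def test_keeps_hits_passing_cutoff_in_file_order(self, tmp_path):
        lines = [
            _blast_line("A", "B", 80.0, 100, "1e-20"),
            _blast_line("B", "A", 75.0, 90, "1e-3"),   # fails cutoff
            _blast_line("C", "D", 60.0, 50, "1e-6"),
            _blast_line("D", "C", 60.0, 50, "2e-2"),   # fails cutoff
            _blast_line("A", "A", 100.0, 100, "0.0"),
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(lines) + "\n")
        hits = parse_blast_tabular(path, evalue_cutoff=1e-5)
        assert [(h.query_id, h.subject_id) for h in hits] == [
            ("A", "B"), ("C", "D"), ("A", "A"),
        ]
        assert hits[0].pct_identity == 80.0
        assert hits[0].aln_length == 100
        assert hits[0].evalue == 1e-20

    def test_self_hits_are_retained_at_parse_stage(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_line("A", "A", 100.0, 80, "0.0") + "\n")
        hits = parse_blast_tabular(path)
        assert len(hits) == 1 and hits[0].query_id == hits[0].subject_id

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_blast_tabular(path) == []

    @pytest.mark.parametrize(
        "bad_line",
        [
            "A\tB\t80.0\t100",                                  # too few fields
            _blast_line("A", "B", "eighty", 100, "1e-20"),      # bad identity
            _blast_line("A", "B", 80.0, "x", "1e-20"),          # bad length
            _blast_line("A", "B", 80.0, 100, "not-a-number"),   # bad evalue
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, bad_line):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_line("X", "Y", 90.0, 50, "1e-30") + "\n"
                        + bad_line + "\n")
        with pytest.raises(BlastParseError, match="line 2"):
            parse_blast_tabular(path)

    def test_extra_trailing_columns_tolerated(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_blast_line("A", "B", 80.0, 100, "1e-20")
                        + "\textra\tcols\n")
        assert len(parse_blast_tabular(path)) == 1


class TestReciprocalPairs:
    def test_both_directions_qualifying_gives_pair(self, small_catalog):
        hits = [_hit("A", "B", 80.0, 90), _hit("B", "A", 80.0, 270)]
        assert reciprocal_pairs(hits, small_catalog) == {frozenset("AB")}

    def test_single_direction_is_not_enough(self, small_catalog):
        hits = [_hit("A", "B", 80.0, 90)]
        assert reciprocal_pairs(hits, small_catalog) == set()

    def test_coverage_is_relative_to_each_querys_own_length(self, small_catalog):
        # A is 100 aa, B is 300 aa; a 60-residue alignment covers 60% of A
        # but only 20% of B, so the B->A direction fails.
        hits = [_hit("A", "B", 80.0, 60), _hit("B", "A", 80.0, 60)]
        assert reciprocal_pairs(hits, small_catalog) == set()

    def test_identity_below_half_disqualifies(self, small_catalog):
        hits = [_hit("A", "B", 49.9, 90), _hit("B", "A", 80.0, 270)]
        assert reciprocal_pairs(hits, small_catalog) == set()

    def test_any_single_hsp_can_qualify_a_direction(self, small_catalog):
        hits = [
            _hit("A", "B", 30.0, 90),    # fails identity
            _hit("A", "B", 80.0, 20),    # fails coverage
            _hit("A", "B", 80.0, 90),    # qualifies
            _hit("B", "A", 80.0, 270),
        ]
        assert reciprocal_pairs(hits, small_catalog) == {frozenset("AB")}

    def test_self_hits_never_form_pairs(self, small_catalog):
        hits = [_hit("A", "A", 100.0, 100)]
        assert reciprocal_pairs(hits, small_catalog) == set()

    def test_unknown_seq_id_raises_naming_it(self, small_catalog):
        with pytest.raises(KeyError, match="ZZZ"):
            reciprocal_pairs([_hit("A", "ZZZ", 80.0, 90)], small_catalog)

    def test_thresholds_are_inclusive(self, small_catalog):
        # exactly 50% coverage of A (50/100) and exactly 50.0% identity
        hits = [_hit("A", "B", 50.0, 50), _hit("B", "A", 50.0, 150)]
        assert reciprocal_pairs(hits, small_catalog) == {frozenset("AB")}


class TestBuildFamilies:
    def test_one_edge_and_a_singleton(self):
        catalog = SequenceCatalog(
            lengths={"A": 10, "B": 10, "C": 10},
            genomes={"A": "g1", "B": "g1", "C": "g1"},
        )
        fams = build_families({frozenset("AB")}, catalog)
        assert fams.as_partition() == frozenset(
            {frozenset("AB"), frozenset("C")}
        )

    def test_transitive_closure_merges_chained_pairs(self):
        catalog = SequenceCatalog(
            lengths={s: 10 for s in "ABC"}, genomes={s: "g1" for s in "ABC"}
        )
        fams = build_families({frozenset("AB"), frozenset("BC")}, catalog)
        assert fams.as_partition() == frozenset({frozenset("ABC")})

    def test_no_pairs_gives_all_singletons(self, small_catalog):
        fams = build_families(set(), small_catalog)
        assert len(fams) == len(small_catalog)
        assert all(len(m) == 1 for m in fams.families.values())

    def test_family_sizes_partition_the_catalog(self, small_catalog):
        fams = build_families({frozenset("AB"), frozenset("CD")}, small_catalog)
        assert sum(len(m) for m in fams.families.values()) == len(small_catalog)

    def test_family_ids_deterministic_by_smallest_member(self, small_catalog):
        fams = build_families({frozenset("CD")}, small_catalog)
        # components sorted by min member: A < B < {C,D} < E
        assert fams.family_of["A"] < fams.family_of["B"] < fams.family_of["C"]
        assert fams.family_of["C"] == fams.family_of["D"]

    def test_pair_order_invariance(self, small_catalog):
        pairs = [frozenset("AB"), frozenset("BC"), frozenset("DE")]
        f1 = build_families(pairs, small_catalog)
        f2 = build_families(list(reversed(pairs)), small_catalog)
        assert f1.as_partition() == f2.as_partition()
        assert f1.families == f2.families

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        nodes = [f"s{i:02d}" for i in range(n)]
        catalog = SequenceCatalog(
            lengths={s: 100 for s in nodes}, genomes={s: "g1" for s in nodes}
        )
        n_edges = int(rng.integers(0, n))
        pairs = set()
        for _ in range(n_edges):
            a, b = rng.choice(n, size=2, replace=False)
            pairs.add(frozenset((nodes[a], nodes[b])))
        fams = build_families(pairs, catalog)
        assert fams.as_partition() == brute_force_components(nodes, pairs)

    def test_raising_thresholds_never_merges_families(self, small_catalog):
        hits = [
            _hit("A", "B", 60.0, 70), _hit("B", "A", 60.0, 200),
            _hit("C", "D", 90.0, 100), _hit("D", "C", 90.0, 80),
        ]
        loose = build_families(
            reciprocal_pairs(hits, small_catalog, 0.5, 0.5), small_catalog
        )
        strict = build_families(
            reciprocal_pairs(hits, small_catalog, 0.7, 0.7), small_catalog
        )
        # every strict family is contained in some loose family
        for members in strict.families.values():
            assert any(
                members <= loose_members
                for loose_members in loose.families.values()
            )


class TestFamiliesToPanmatrix:
    def test_shared_family_gives_ones_in_both_genomes(self, small_catalog):
        fams = build_families({frozenset(("A", "C"))}, small_catalog)
        P = families_to_panmatrix(fams, small_catalog)
        fid = fams.family_of["A"]
        col = P.M[:, P.family_ids.index(fid)]
        assert col.tolist() == [1, 1]  # rows g1, g2

    def test_paralogs_in_one_genome_still_give_single_one(self, small_catalog):
        # A and B are both in genome g1
        fams = build_families({frozenset(("A", "B"))}, small_catalog)
        P = families_to_panmatrix(fams, small_catalog)
        fid = fams.family_of["A"]
        col = P.M[:, P.family_ids.index(fid)]
        assert col.tolist() == [1, 0]

    def test_cellwise_against_hand_enumeration(self):
        catalog = SequenceCatalog(
            lengths={s: 50 for s in ["a1", "a2", "b1", "b2", "c1"]},
            genomes={"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB", "c1": "gC"},
        )
        fams = build_families(
            {frozenset(("a1", "b1")), frozenset(("b2", "c1"))}, catalog
        )
        P = families_to_panmatrix(fams, catalog)
        assert P.genome_ids == ["gA", "gB", "gC"]
        # families sorted by min member: {a1,b1}, {a2}, {b2,c1}
        expected = {
            fams.family_of["a1"]: [1, 1, 0],
            fams.family_of["a2"]: [1, 0, 0],
            fams.family_of["b2"]: [0, 1, 1],
        }
        for fid, col in expected.items():
            assert P.M[:, P.family_ids.index(fid)].tolist() == col

    def test_rows_and_columns_are_sorted(self, small_catalog):
        fams = build_families(set(), small_catalog)
        P = families_to_panmatrix(fams, small_catalog)
        assert P.genome_ids == sorted(P.genome_ids)
        assert P.family_ids == sorted(P.family_ids)
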