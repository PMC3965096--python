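"""Canonical pair algebra, MITAB parsing, dataset I/O and summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from negset.annotate import NIPRecord
from negset.errors import (
    DatasetFormatError,
    MitabFormatError,
    UndefinedFractionError,
)
from negset.filter_merge import (
    CanonicalPair,
    merge,
    read_dataset,
    read_domain_pairs,
    read_mitab,
    removal_fraction,
    subtract,
    summarize,
    write_dataset,
)

accessions = st.text(
    alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=2, max_size=8
)
pairs = st.tuples(accessions, accessions).map(lambda t: CanonicalPair(*t))
pair_sets = st.sets(pairs, max_size=40)


class TestCanonicalPair:
    def test_order_insensitive_equality(self):
        assert CanonicalPair("Q1", "P1") == CanonicalPair("P1", "Q1")
        assert CanonicalPair("Q1", "P1").first == "P1"

    def test_hashable_and_sortable(self):
        s = {CanonicalPair("B", "A"), CanonicalPair("A", "B")}
        assert len(s) == 1
        assert sorted([CanonicalPair("C", "D"), CanonicalPair("A", "B")])[0] \
            == CanonicalPair("B", "A")

    def test_empty_member_rejected(self):
        with pytest.raises(ValueError):
            CanonicalPair("", "P1")

    @given(a=accessions, b=accessions)
    def test_canonical_order_invariant(self, a, b):
        pair = CanonicalPair(a, b)
        assert pair.first <= pair.second
        assert pair == CanonicalPair(b, a)


class TestMitab:
    def test_uniprot_pair_extracted(self, tmp_path):
        path = tmp_path / "k.mitab"
        path.write_text(
            "uniprotkb:P12345\tuniprotkb:Q67890\tpsi-mi:x\t-\n"
        )
        got = read_mitab(path)
        assert got.pairs == {CanonicalPair("P12345", "Q67890")}

    def test_non_protein_interactor_skipped_leniently(self, tmp_path):
        path = tmp_path / "k.mitab"
        path.write_text(
            "chebi:CHEBI:15422\tuniprotkb:P12345\t-\n"
            "uniprotkb:P00001\tuniprotkb:P00002\t-\n"
        )
        assert read_mitab(path).pairs == {CanonicalPair("P00001", "P00002")}

    def test_strict_mode_reports_line_number(self, tmp_path):
        path = tmp_path / "k.mitab"
        path.write_text(
            "uniprotkb:P00001\tuniprotkb:P00002\t-\n"
            "chebi:CHEBI:15422\tuniprotkb:P12345\t-\n"
        )
        with pytest.raises(MitabFormatError, match=":2"):
            read_mitab(path, strict=True)

    def test_collapse_isoforms(self, tmp_path):
        path = tmp_path / "k.mitab"
        path.write_text("uniprotkb:P12345-2\tuniprotkb:Q67890\t-\n")
        got = read_mitab(path, collapse_isoforms=True)
        assert got.pairs == {CanonicalPair("P12345", "Q67890")}

    def test_alternative_xrefs_searched(self, tmp_path):
        path = tmp_path / "k.mitab"
        path.write_text(
            "intact:EBI-1|uniprotkb:P11111\tuniprotkb:P22222\t-\n"
        )
        assert read_mitab(path).pairs == {CanonicalPair("P11111", "P22222")}


class TestSubtract:
    def test_order_insensitive_removal(self):
        candidates = {CanonicalPair("P1", "P2"), CanonicalPair("P3", "P4")}
        known = {CanonicalPair("P2", "P1")}
        assert subtract(candidates, known) == {CanonicalPair("P3", "P4")}

    @settings(deadline=None, max_examples=100)
    @given(candidates=pair_sets, known=pair_sets)
    def test_subtract_laws(self, candidates, known):
        out = subtract(candidates, known)
        assert out <= candidates
        assert subtract(out, known) == out  # idempotent
        assert subtract(candidates, set()) == candidates
        assert not out & known


class TestMerge:
    def test_disjoint_and_identical(self):
        a = {CanonicalPair("A", "B"), CanonicalPair("C", "D")}
        b = {CanonicalPair("E", "F"), CanonicalPair("G", "H"),
             CanonicalPair("I", "J")}
        union, overlap = merge(a, b)
        assert (len(union), overlap) == (5, 0)
        union, overlap = merge(a, a)
        assert (len(union), overlap) == (2, 2)

    @settings(deadline=None, max_examples=100)
    @given(a=pair_sets, b=pair_sets)
    def test_inclusion_exclusion(self, a, b):
        union, overlap = merge(a, b)
        assert len(union) == len(a) + len(b) - overlap
        union_ba, overlap_ba = merge(b, a)
        assert union_ba == union and overlap_ba == overlap

    @settings(deadline=None, max_examples=50)
    @given(a=pair_sets, b=pair_sets, c=pair_sets)
    def test_union_associative(self, a, b, c):
        left, _ = merge(merge(a, b)[0], c)
        right, _ = merge(a, merge(b, c)[0])
        assert left == right


class TestRemovalFraction:
    @pytest.mark.parametrize(
        "n_before,n_after,expected",
        [(2171, 1991, 8), (4397, 4161, 5), (6532, 6136, 6), (100, 100, 0)],
    )
    def test_reported_integer_percentages(self, n_before, n_after, expected):
        assert removal_fraction(n_before, n_after) == expected

    def test_half_rounds_away_from_zero(self):
        assert removal_fraction(200, 197) == 2  # 1.5% -> 2

    def test_empty_start_undefined(self):
        with pytest.raises(UndefinedFractionError):
            removal_fraction(0, 0)


class TestDatasetIO:
    RECORDS = [
        NIPRecord(
            pair=CanonicalPair("Q00002", "P00001"),
            source="structure",
            structure_evidence=[("1abc", "1", 11.25), ("2xyz", "1", 14.5)],
        ),
        NIPRecord(
            pair=CanonicalPair("P00003", "P00004"),
            source="manual",
            method="MI:0096 pull down",
        ),
    ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "data.tsv"
        write_dataset(self.RECORDS, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + 2 records
        got = read_dataset(path)
        assert [r.pair for r in got] == sorted(r.pair for r in self.RECORDS)
        by_pair = {r.pair: r for r in got}
        manual = by_pair[CanonicalPair("P00003", "P00004")]
        assert manual.source == "manual"
        assert manual.method == "MI:0096 pull down"
        structural = by_pair[CanonicalPair("P00001", "Q00002")]
        assert {sid for sid, _, _ in structural.structure_evidence} == {
            "1abc", "2xyz"
        }

    def test_unordered_pair_normalized_on_read(self, tmp_path):
        path = tmp_path / "data.tsv"
        path.write_text(
            "accession_a\taccession_b\tsource\tstructures\tmin_distance\t"
            "method\nQ99999\tP00001\tmanual\t\t\t\n"
        )
        got = read_dataset(path)
        assert got[0].pair == CanonicalPair("P00001", "Q99999")

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "data.tsv"
        path.write_text(
            "accession_a\taccession_b\tsource\tstructures\tmin_distance\t"
            "method\nonly_one_column\n"
        )
        with pytest.raises(DatasetFormatError, match=":2"):
            read_dataset(path)

    def test_domain_pair_tsv(self, tmp_path):
        path = tmp_path / "known.tsv"
        path.write_text("PF00002\tPF00001\nPF00003\tPF00003\n")
        got = read_domain_pairs(path)
        assert got.pairs == {
            CanonicalPair("PF00001", "PF00002"),
            CanonicalPair("PF00003", "PF00003"),
        }


class TestSummarize:
    def test_lineage_rows(self):
        rows = summarize({"PDB": (40, 36), "merged": (6532, 6136)})
        assert rows[0].removed_fraction_pct == 10
        assert rows[1].removed_fraction_pct == 6
        assert all(r.n_after <= r.n_before for r in rows)

    def test_empty_dataset_reports_zero(self):
        rows = summarize({"empty": (0, 0)})
        assert rows[0].removed_fraction_pct == 0
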