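"""Chain mapping, protein-level consolidation and domain expansion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from negset.annotate import (
    consolidate_protein_pairs,
    expand_domain_pairs,
    load_chain_mapping,
    load_domain_mapping,
)
from negset.contact_core import ChainPairResult
from negset.errors import DatasetFormatError, MappingIntegrityError
from negset.filter_merge import CanonicalPair
from negset.structure_io import BioUnit, ChainModel


def _unit(sid, chain_ids, assembly_id="1"):
    chains = [ChainModel(chain_id=c, copy_index=1) for c in chain_ids]
    return BioUnit(sid, assembly_id, chains)


def _result(a, b, distance, threshold=8.0, copy_a=1, copy_b=1):
    return ChainPairResult(
        chain_a=(a, copy_a),
        chain_b=(b, copy_b),
        min_distance=distance,
        non_interacting=distance > threshold,
    )


class TestChainMapping:
    def test_basic_rows(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "structure_id\tchain_id\taccession\n"
            "1abc\tA\tP11111\n1abc\tB\tP22222\n"
        )
        mapping = load_chain_mapping(path)
        assert mapping == {("1abc", "A"): "P11111", ("1abc", "B"): "P22222"}

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "structure_id\tchain_id\taccession\n"
            "1abc\tA\tP11111\n1abc\tA\tP33333\n"
        )
        with pytest.raises(MappingIntegrityError, match="1abc"):
            load_chain_mapping(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("structure_id\tchain_id\taccession\n")
        assert load_chain_mapping(path) == {}

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("1abc\tA\tP11111\n")
        with pytest.raises(DatasetFormatError):
            load_chain_mapping(path)


class TestConsolidation:
    MAPPING = {
        ("1abc", "A"): "P00001",
        ("1abc", "A2"): "P00001",
        ("1abc", "B"): "Q00001",
        ("2xyz", "A"): "P00001",
        ("2xyz", "B"): "Q00001",
    }

    def test_one_contacting_copy_suppresses_the_pair(self):
        # homodimer of P in contact; Q is distant from one P copy only
        unit = _unit("1abc", ["A", "A2", "B"])
        results = [
            _result("A", "A2", 3.0),
            _result("A", "B", 6.0),
            _result("A2", "B", 20.0),
        ]
        records = consolidate_protein_pairs([(unit, results)], self.MAPPING)
        assert records == []

    def test_distant_pair_emitted_with_evidence(self):
        unit = _unit("1abc", ["A", "B"])
        records = consolidate_protein_pairs(
            [(unit, [_result("A", "B", 12.0)])], self.MAPPING
        )
        assert len(records) == 1
        rec = records[0]
        assert rec.pair == CanonicalPair("P00001", "Q00001")
        assert rec.structure_evidence == (("1abc", "1", 12.0),)

    def test_cross_structure_contact_suppresses_globally(self):
        unit1 = _unit("1abc", ["A", "B"])
        unit2 = _unit("2xyz", ["A", "B"])
        records = consolidate_protein_pairs(
            [
                (unit1, [_result("A", "B", 12.0)]),
                (unit2, [_result("A", "B", 5.0)]),
            ],
            self.MAPPING,
        )
        assert records == []

    def test_self_pairs_excluded(self):
        unit = _unit("1abc", ["A", "A2"])
        records = consolidate_protein_pairs(
            [(unit, [_result("A", "A2", 30.0)])], self.MAPPING
        )
        assert records == []

    def test_unmapped_chains_dropped(self):
        unit = _unit("1abc", ["A", "Z"])
        records = consolidate_protein_pairs(
            [(unit, [_result("A", "Z", 30.0)])], self.MAPPING
        )
        assert records == []

    def test_reapplying_rule_to_own_output_is_stable(self):
        units = [
            (_unit("1abc", ["A", "B"]), [_result("A", "B", 15.0)]),
            (_unit("2xyz", ["A", "B"]), [_result("A", "B", 9.0)]),
        ]
        records = consolidate_protein_pairs(units, self.MAPPING)
        # rebuild synthetic per-evidence units from the output and rerun
        mapping = {}
        rebuilt = []
        for rec in records:
            for sid, aid, distance in rec.structure_evidence:
                mapping[(sid, rec.pair.first)] = rec.pair.first
                mapping[(sid, rec.pair.second)] = rec.pair.second
                rebuilt.append(
                    (
                        _unit(sid, [rec.pair.first, rec.pair.second], aid),
                        [_result(rec.pair.first, rec.pair.second, distance)],
                    )
                )
        again = consolidate_protein_pairs(rebuilt, mapping)
        assert {r.pair for r in again} == {r.pair for r in records}
        assert {r.pair: r.structure_evidence for r in again} == {
            r.pair: r.structure_evidence for r in records
        }

    def test_collapse_isoforms_merges_splice_variants(self):
        mapping = {("1abc", "A"): "P00001-2", ("1abc", "B"): "Q00001"}
        unit = _unit("1abc", ["A", "B"])
        records = consolidate_protein_pairs(
            [(unit, [_result("A", "B", 10.0)])], mapping,
            collapse_isoforms=True,
        )
        assert records[0].pair == CanonicalPair("P00001", "Q00001")


class TestDomainExpansion:
    def test_cross_product(self):
        domains = {"P": ["PF00001", "PF00002"], "Q": ["PF00010"]}
        out = expand_domain_pairs([CanonicalPair("P", "Q")], domains)
        assert out == {
            CanonicalPair("PF00001", "PF00010"),
            CanonicalPair("PF00002", "PF00010"),
        }

    def test_empty_domain_list_contributes_nothing(self):
        domains = {"P": [], "Q": ["PF00010"]}
        assert expand_domain_pairs([CanonicalPair("P", "Q")], domains) == set()

    def test_self_domain_pair_kept(self):
        domains = {"P": ["PF00001"], "Q": ["PF00001"]}
        out = expand_domain_pairs([CanonicalPair("P", "Q")], domains)
        assert out == {CanonicalPair("PF00001", "PF00001")}

    @settings(deadline=None, max_examples=50)
    @given(
        n_a=st.integers(min_value=0, max_value=6),
        n_b=st.integers(min_value=0, max_value=6),
    )
    def test_cardinality_of_single_pair_expansion(self, n_a, n_b):
        # disjoint domain sets: |expansion| is exactly |dA| * |dB|
        domains = {
            "P": [f"PF1{i:04d}" for i in range(n_a)],
            "Q": [f"PF2{i:04d}" for i in range(n_b)],
        }
        out = expand_domain_pairs([CanonicalPair("P", "Q")], domains)
        assert len(out) == n_a * n_b


class TestDomainMapping:
    def test_repeated_rows_dedupe_in_order(self, tmp_path):
        path = tmp_path / "dom.tsv"
        path.write_text(
            "P00001\tPF00002\nP00001\tPF00001\nP00001\tPF00002\n"
            "Q00001\tPF00010\n"
        )
        mapping = load_domain_mapping(path)
        assert mapping == {
            "P00001": ["PF00002", "PF00001"],
            "Q00001": ["PF00010"],
        }

    def test_malformed_pfam_id_rejected(self, tmp_path):
        path = tmp_path / "dom.tsv"
        path.write_text("P00001\tPFAM1\n")
        with pytest.raises(DatasetFormatError, match="PFAM"):
            load_domain_mapping(path)
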