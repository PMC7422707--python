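"""Evidence collation, major-site calling, MALDI merge and totals."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepephos import (
    PeptideEvidence,
    classify_major,
    collate_lcms,
    merge_maldi,
    parse_site_field,
    read_evidence_table,
    totals,
)
from mepephos.site_collation import EvidenceValidationError, site_map_to_frame

ASARM_SERINES = [493, 494, 496, 497, 499, 501, 502, 503, 505]


@pytest.fixture(scope="module")
def table1(evidence_path):
    return read_evidence_table(evidence_path)


class TestParseSiteField:
    def test_resolved_ambiguous_and_double(self):
        assert parse_site_field("42") == (frozenset({42}),)
        assert parse_site_field("103|104") == (frozenset({103, 104}),)
        assert parse_site_field("436;441") == (
            frozenset({436}),
            frozenset({441}),
        )


class TestCollateLcms:
    def test_fixture_yields_22_distinct_sites(self, table1):
        site_map = collate_lcms(table1)
        assert site_map.n_sites == 22

    def test_ser_thr_tally_ranges(self, table1):
        tally = collate_lcms(table1).residue_class_tally()
        assert (tally["ser_min"], tally["ser_max"]) == (20, 21)
        assert (tally["thr_min"], tally["thr_max"]) == (1, 2)

    def test_ambiguous_pairs_count_once(self, table1):
        site_map = collate_lcms(table1)
        assert (103, 104) in site_map.entries
        assert (370, 371) in site_map.entries
        assert site_map.entries[(103, 104)].residues == ("S", "T")

    def test_aggregated_count_is_maximum_not_sum(self, table1):
        site_map = collate_lcms(table1)
        # S436 appears in two rows with counts 5 and 1
        assert site_map.entries[(436,)].spectral_count == 5

    def test_empty_evidence_gives_empty_map(self):
        site_map = collate_lcms([])
        assert site_map.n_sites == 0
        assert totals(site_map)["grand_total"] == 0

    def test_row_order_and_duplication_invariance(self, table1):
        doubled = list(table1) + list(reversed(table1))
        a = collate_lcms(table1)
        b = collate_lcms(doubled)
        assert a.entries == b.entries

    def test_every_site_is_ser_or_thr_in_its_peptide(self, table1):
        site_map = collate_lcms(table1)
        for entry in site_map.entries.values():
            assert set(entry.residues) <= {"S", "T"}

    def test_non_st_position_rejected(self):
        with pytest.raises(EvidenceValidationError, match="not a"):
            collate_lcms(
                [
                    PeptideEvidence(
                        residues="GAGAG",
                        start=1,
                        end=5,
                        site_units=(frozenset({2}),),
                        spectral_count=1,
                    )
                ]
            )

    def test_parent_sequence_mismatch_rejected(self):
        row = PeptideEvidence(
            residues="SAG", start=2, end=4,
            site_units=(frozenset({2}),), spectral_count=1,
        )
        with pytest.raises(EvidenceValidationError, match="parent"):
            collate_lcms([row], parent_sequence="GGGGG")
        # and accepted when the parent really contains the peptide
        collate_lcms([row], parent_sequence="GSAGG")


class TestClassifyMajor:
    def test_threshold_20_reproduces_major_sites(self, table1):
        site_map = collate_lcms(table1)
        assert classify_major(site_map, 20) == {43, 222, 362, 441}

    def test_threshold_one_returns_everything(self, table1):
        site_map = collate_lcms(table1)
        major = classify_major(site_map, 1)
        positions = {p for e in site_map.entries.values() for p in e.positions}
        assert major == positions

    def test_monotone_in_threshold(self, table1):
        site_map = collate_lcms(table1)
        previous = None
        for thr in (1, 5, 20, 31, 40):
            current = classify_major(site_map, thr)
            if previous is not None:
                assert current <= previous
            previous = current

    @given(st.dictionaries(
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=0, max_value=60),
        min_size=1, max_size=20,
    ), st.integers(min_value=1, max_value=60))
    @settings(derandomize=True, max_examples=60)
    def test_matches_direct_filter(self, counts, threshold):
        rows = [
            PeptideEvidence(
                residues="S", start=pos, end=pos,
                site_units=(frozenset({pos}),), spectral_count=c,
            )
            for pos, c in counts.items()
        ]
        site_map = collate_lcms(rows)
        expected = {p for p, c in counts.items() if c >= threshold}
        assert classify_major(site_map, threshold) == expected


class TestMergeMaldi:
    def test_ladder_of_ten_marks_all_nine_asarm_serines(self, table1):
        site_map = collate_lcms(table1)
        merged = merge_maldi(site_map, ASARM_SERINES, ladder_max=10, tag_serine_count=1)
        for pos in ASARM_SERINES:
            entry = merged.entries[(pos,)]
            assert entry.status == "assumed"
            assert entry.source == "MALDI"
        assert merged.n_sites == 31
        assert not merged.partial_regions

    def test_ladder_zero_changes_nothing(self, table1):
        site_map = collate_lcms(table1)
        merged = merge_maldi(site_map, ASARM_SERINES, ladder_max=0)
        assert merged.entries == site_map.entries

    def test_insufficient_ladder_leaves_region_partial(self, table1):
        site_map = collate_lcms(table1)
        merged = merge_maldi(site_map, ASARM_SERINES, ladder_max=5, tag_serine_count=1)
        assert merged.n_sites == site_map.n_sites
        assert merged.partial_regions
        assert merged.partial_regions[0]["ladder_max"] == 5

    def test_existing_lcms_site_becomes_both_sources(self):
        row = PeptideEvidence(
            residues="ASA", start=492, end=494,
            site_units=(frozenset({493}),), spectral_count=3,
        )
        site_map = collate_lcms([row])
        merged = merge_maldi(site_map, [493, 494], ladder_max=2)
        assert merged.entries[(493,)].source == "both"
        assert merged.entries[(494,)].source == "MALDI"
        assert merged.n_sites == 2


class TestTotals:
    def test_paper_fixture_pipeline_totals(self, table1):
        site_map = merge_maldi(
            collate_lcms(table1), ASARM_SERINES, ladder_max=10, tag_serine_count=1
        )
        t = totals(site_map)
        assert t["lcms_sites"] == 22
        assert t["maldi_region_sites"] == 9
        assert t["grand_total"] == 31
        assert t["tag_sites"] == 1

    def test_site_map_frame_has_one_row_per_site(self, table1):
        site_map = collate_lcms(table1)
        frame = site_map_to_frame(site_map)
        assert len(frame) == 22
        assert frame["spectral_count"].max() == 39
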