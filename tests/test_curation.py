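"""Curated-table parsing, verification and BED export."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfbsevol.curation import (
    CoordinateError,
    CuratedSiteRecord,
    CuratedTableError,
    ReferenceSequence,
    Verification,
    count_distinct_references,
    curated_to_bed,
    parse_curated_table,
    render_curated_table,
    verify_site_sequence,
)
from tfbsevol.tracks import parse_bed_track

HEADER = (
    "gene_region\tfactor_name\tsite_class\tidentifier\tabbrev_ref\tref_id"
    "\tchrom\tstart\tend\tmarker"
)


def table(*rows):
    return HEADER + "\n" + "\n".join(rows) + "\n"


def rec(**kw):
    base = dict(
        gene_region="Oct4",
        factor_name="OctSox",
        site_class="",
        identifier="",
        abbrev_ref="Chew05",
        ref_id="B101",
        chrom="chr17",
        start=35640993,
        end=35641008,
        verified=Verification.CONFIRMED,
    )
    base.update(kw)
    return CuratedSiteRecord(**base)


class TestParse:
    def test_composite_factor_row_parses_with_confirmed_marker(self):
        row = (
            "Oct4\tNr1b*/2b*; Rar*/Rxr*\tHRE\t\tNordhoff01; Sylvester94"
            "\tB59;B90\tchr17\t35642936\t35642955\t+"
        )
        (r,) = parse_curated_table(table(row))
        assert (r.chrom, r.start, r.end) == ("chr17", 35642936, 35642955)
        assert r.verified is Verification.CONFIRMED
        assert r.factor_name == "Nr1b*/2b*; Rar*/Rxr*"

    def test_header_only_gives_empty_list(self):
        assert parse_curated_table(HEADER + "\n") == []

    def test_inverted_interval_names_the_row(self):
        rows = [
            "Oct4\tTcf3\t\tM1\tTam08\tB98\tchr17\t100\t120\t+",
            "Oct4\tTcf3\t\tM3\tTam08\tB98\tchr17\t10\t5\t+",
        ]
        with pytest.raises(CuratedTableError, match="row 2"):
            parse_curated_table(table(*rows))

    def test_malformed_coordinate_is_a_parse_error(self):
        with pytest.raises(CuratedTableError, match="row 1"):
            parse_curated_table(
                table("Oct4\tTcf3\t\t\tTam08\tB98\tchr17\txx\t120\t+")
            )

    def test_unknown_marker_is_a_parse_error(self):
        with pytest.raises(CuratedTableError, match="marker"):
            parse_curated_table(
                table("Oct4\tTcf3\t\t\tTam08\tB98\tchr17\t100\t120\t??")
            )

    def test_marker_mapping_to_verification_enum(self):
        rows = [
            "Oct4\tRonin\tR()\t\tDejosez08\tB89\tchr17\t100\t200",
            "Oct4\tCR1\t\t\tNordhoff01\tB59\tchr17\t100\t200",
            "Nanog\tZfp143\trevcom\t\tChen08\tB118\tchr6\t100\t114\t+",
            "Sox2\tGli\t\t2\tTakanaga09\tB104\tchr3\t100\t111\tdna_not_matching",
            "Oct4\tTcf3\t\t\tTam08\tB98\tchr17\t100\t106",
        ]
        got = [r.verified for r in parse_curated_table(table(*rows))]
        assert got == [
            Verification.REGION_ONLY,
            Verification.REGION_ONLY,
            Verification.REVCOM_CONFIRMED,
            Verification.MISMATCH,
            Verification.UNCHECKED,
        ]


ref_keys = st.sampled_from(["Chew05", "Gu05", "Tam08", "Nordhoff01; Sylvester94"])
factors = st.sampled_from(["OctSox", "Tcf3", "Nr1b*/2b*; Rar*/Rxr*", "Stat3"])


@st.composite
def curated_records(draw):
    start = draw(st.integers(min_value=1, max_value=10**8))
    verified = draw(
        st.sampled_from(
            [Verification.CONFIRMED, Verification.UNCHECKED, Verification.MISMATCH]
        )
    )
    return rec(
        factor_name=draw(factors),
        abbrev_ref=draw(ref_keys),
        identifier=draw(st.sampled_from(["", "P1", "M3", "RE1"])),
        chrom=draw(st.sampled_from(["chr3", "chr6", "chr17"])),
        start=start,
        end=start + draw(st.integers(min_value=0, max_value=300)),
        verified=verified,
    )


@settings(max_examples=60, derandomize=True)
@given(st.lists(curated_records(), max_size=8))
def test_render_parse_round_trip(records):
    assert parse_curated_table(render_curated_table(records)) == records


class TestDistinctReferences:
    def test_multi_reference_cells_split_on_semicolon(self):
        records = [
            rec(abbrev_ref="Nordhoff01; Sylvester94"),
            rec(abbrev_ref="Nordhoff01"),
            rec(abbrev_ref="Gu05"),
        ]
        assert count_distinct_references(records) == 3

    def test_empty_and_duplicates(self):
        assert count_distinct_references([]) == 0
        assert count_distinct_references([rec(abbrev_ref="Gu05")] * 2) == 1


class TestVerify:
    REF = ReferenceSequence("chr17:100", "AAGCACGTAAAA", 100)

    def test_exact_match_is_confirmed(self):
        r = rec(chrom="chr17", start=104, end=107)
        assert verify_site_sequence(r, self.REF, "ACGT") is Verification.CONFIRMED

    def test_reverse_complement_match(self):
        # slice at 100..103 is AAGC; reported GCTT only matches after revcom
        r = rec(chrom="chr17", start=100, end=103)
        assert (
            verify_site_sequence(r, self.REF, "GCTT")
            is Verification.REVCOM_CONFIRMED
        )

    def test_disagreement_is_mismatch(self):
        r = rec(chrom="chr17", start=108, end=111)  # AAAA
        assert verify_site_sequence(r, self.REF, "CCCC") is Verification.MISMATCH

    def test_interval_outside_reference_is_coordinate_error(self):
        r = rec(chrom="chr17", start=95, end=98)
        with pytest.raises(CoordinateError):
            verify_site_sequence(r, self.REF, "ACGT")

    def test_length_mismatch_is_input_error(self):
        r = rec(chrom="chr17", start=104, end=107)
        with pytest.raises(ValueError, match="length"):
            verify_site_sequence(r, self.REF, "ACGTA")


class TestBedExport:
    def test_coordinates_shift_to_zero_based_half_open(self):
        text = curated_to_bed([rec()], "t", "d")
        line = text.splitlines()[1]
        assert line == "chr17\t35640992\t35641008\tChew05_OctSox"

    def test_empty_records_give_track_line_only(self):
        text = curated_to_bed([], "t", "d")
        assert text.startswith("track name=")
        assert len(text.strip().splitlines()) == 1

    def test_output_sorted_by_chrom_then_start(self):
        records = [
            rec(start=500, end=520),
            rec(start=100, end=130),
            rec(chrom="chr3", start=900, end=950),
        ]
        feats = parse_bed_track(curated_to_bed(records, "t", "d"))
        assert [(f[0], f[1]) for f in feats] == sorted((f[0], f[1]) for f in feats)

    def test_bed_round_trip_restores_one_based_coordinates(self):
        records = [rec(start=7, end=31), rec(start=1, end=1)]
        feats = parse_bed_track(curated_to_bed(records, "t", "d"))
        assert {(f[1] + 1, f[2]) for f in feats} == {(7, 31), (1, 1)}

    def test_identifier_appended_and_whitespace_replaced(self):
        text = curated_to_bed(
            [rec(factor_name="demethylation site", identifier="P 1")], "t", "d"
        )
        assert text.splitlines()[1].split("\t")[3] == "Chew05_demethylation_site_P_1"
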