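"""Tests for the variant-extract and VEP-annotation readers and the join."""

import io
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finemav.variant_table_io import (
    AnnotationRecord,
    PopulationPanel,
    TableLayout,
    VariantRecord,
    merge_annotations,
    parse_variant_table,
    parse_vep_annotation,
    write_variant_table,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestPopulationPanel:
    def test_requires_two_distinct_named_populations(self):
        with pytest.raises(ValueError):
            PopulationPanel(("ONLY",))
        with pytest.raises(ValueError):
            PopulationPanel(("A", "A"))
        with pytest.raises(ValueError):
            PopulationPanel(("A", ""))
        assert PopulationPanel(("A", "B", "C")).n == 3


class TestParseVariantTable:
    def test_published_style_row(self, tmp_path, panel3):
        path = _write(
            tmp_path, "v.tsv", "2:109513601\trs3827760\tA\tG\t0.922\t0.029\t0.490\n"
        )
        (rec,) = parse_variant_table(path, panel3)
        assert rec == VariantRecord(
            chrom="2", pos=109513601, id="rs3827760", ref="A", alt="G",
            af_alt=(0.922, 0.029, 0.490),
        )

    def test_optional_columns_and_header(self, tmp_path, panel2):
        path = _write(
            tmp_path, "v.tsv",
            "LOC\tID\tREF\tALT\tAA\tCADD\tAF1\tAF2\n"
            "1:100\trs1\tC\tT\tc\t23.1\t0.5\t0.25\n"
            "1:200\trs2\tG\tA\t.\t.\t0.1\t0.9\n",
        )
        layout = TableLayout(has_aa=True, has_cadd=True, has_header=True)
        recs = list(parse_variant_table(path, panel2, layout))
        assert recs[0].aa == "c" and recs[0].cadd_phred == 23.1
        assert recs[1].aa is None and recs[1].cadd_phred is None

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("1:100\trs1\tA\tG\t1.5\t0.2", "AF_OUT_OF_RANGE"),
            ("1:100\trs1\tA\tG\t-0.1\t0.2", "AF_OUT_OF_RANGE"),
            ("1:100\trs1\tA\tG\tfoo\t0.2", "AF_UNPARSABLE"),
            ("1:100\trs1\tA\tG\t0.2", "BAD_COLUMN_COUNT"),
            ("1:100\trs1\tA\tA\t0.1\t0.2", "NOT_SNP"),
            ("1:100\trs1\tAT\tG\t0.1\t0.2", "NOT_SNP"),
            ("nonsense\trs1\tA\tG\t0.1\t0.2", "BAD_LOCATION"),
            ("1:0\trs1\tA\tG\t0.1\t0.2", "BAD_LOCATION"),
        ],
    )
    def test_malformed_rows_rejected_with_reason(self, tmp_path, panel2, row, reason):
        path = _write(tmp_path, "v.tsv", row + "\n")
        counters = Counter()
        assert list(parse_variant_table(path, panel2, counters=counters)) == []
        assert counters[reason] == 1

    def test_empty_file_yields_empty_stream(self, tmp_path, panel2):
        path = _write(tmp_path, "v.tsv", "")
        counters = Counter()
        assert list(parse_variant_table(path, panel2, counters=counters)) == []
        assert counters["rows_read"] == 0

    def test_missing_file_is_fatal(self, tmp_path, panel2):
        with pytest.raises(FileNotFoundError):
            list(parse_variant_table(tmp_path / "absent.tsv", panel2))

    def test_record_count_conservation(self, tmp_path, panel2):
        """rows_read = rows_yielded + per-reason rejections."""
        path = _write(
            tmp_path, "v.tsv",
            "1:100\trs1\tA\tG\t0.1\t0.2\n"
            "1:101\trs2\tA\tG\t1.5\t0.2\n"
            "1:102\trs3\tA\tG\t0.2\n"
            "1:103\trs4\tC\tT\t0.9\t0.3\n",
        )
        counters = Counter()
        recs = list(parse_variant_table(path, panel2, counters=counters))
        rejected = counters["AF_OUT_OF_RANGE"] + counters["BAD_COLUMN_COUNT"]
        assert counters["rows_read"] == len(recs) + rejected == 4

    @given(
        recs=st.lists(
            st.builds(
                VariantRecord,
                chrom=st.sampled_from(["1", "X", "chr7"]),
                pos=st.integers(min_value=1, max_value=10**9),
                id=st.text(
                    alphabet=st.characters(whitelist_categories=("L", "N")),
                    min_size=1, max_size=8,
                ),
                ref=st.just("A"),
                alt=st.just("G"),
                af_alt=st.tuples(
                    st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
                ),
                aa=st.sampled_from(["A", "G", None]),
                cadd_phred=st.one_of(st.none(), st.floats(0, 99, allow_nan=False)),
            ),
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip_preserves_records(self, tmp_path_factory, recs):
        layout = TableLayout(has_aa=True, has_cadd=True)
        buffer = io.StringIO()
        write_variant_table(recs, buffer, layout)
        path = tmp_path_factory.mktemp("rt") / "v.tsv"
        path.write_text(buffer.getvalue())
        panel = PopulationPanel(("P1", "P2"))
        assert list(parse_variant_table(path, panel, layout)) == recs


class TestParseVepAnnotation:
    HEADER = "Location\tAA\tCADD_PHRED\n"

    def test_plain_and_range_locations(self, tmp_path):
        path = _write(
            tmp_path, "a.tsv",
            self.HEADER
            + "16:31099000\tA\t23.1\n"
            + "2:109513601-109513601\tG\t12.0\n",
        )
        ann = parse_vep_annotation(path)
        assert ann["16:31099000"] == AnnotationRecord("16:31099000", "A", 23.1)
        assert ann["2:109513601"].aa == "G"

    def test_duplicate_keys_first_wins(self, tmp_path):
        path = _write(
            tmp_path, "a.tsv", self.HEADER + "1:5\tA\t1.0\n1:5\tG\t2.0\n"
        )
        counters = Counter()
        ann = parse_vep_annotation(path, counters)
        assert ann["1:5"].aa == "A"
        assert counters["ann_duplicate_key"] == 1

    def test_multi_base_range_rejected(self, tmp_path):
        path = _write(tmp_path, "a.tsv", self.HEADER + "1:5-9\tA\t1.0\n")
        counters = Counter()
        assert parse_vep_annotation(path, counters) == {}
        assert counters["ann_BAD_LOCATION"] == 1

    def test_missing_tokens_map_to_none(self, tmp_path):
        path = _write(tmp_path, "a.tsv", self.HEADER + "1:5\t.\t-\n")
        ann = parse_vep_annotation(path)
        assert ann["1:5"].aa is None and ann["1:5"].cadd_phred is None

    def test_header_without_known_columns_is_fatal(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "Location\tSIFT\n1:5\t0.2\n")
        with pytest.raises(ValueError, match="neither"):
            parse_vep_annotation(path)


class TestMergeAnnotations:
    REC = VariantRecord(
        chrom="1", pos=100, id="rs1", ref="A", alt="G", af_alt=(0.5, 0.5)
    )

    def test_fills_missing_fields_only(self):
        ann = {"1:100": AnnotationRecord("1:100", aa="A", cadd_phred=9.0)}
        (merged,) = merge_annotations([self.REC], ann)
        assert merged.aa == "A" and merged.cadd_phred == 9.0

    def test_never_overwrites_table_values(self):
        rec = VariantRecord(
            chrom="1", pos=100, id="rs1", ref="A", alt="G",
            af_alt=(0.5, 0.5), aa="G", cadd_phred=1.0,
        )
        ann = {"1:100": AnnotationRecord("1:100", aa="A", cadd_phred=9.0)}
        (merged,) = merge_annotations([rec], ann)
        assert merged is rec

    def test_no_matching_key_passes_through(self):
        (merged,) = merge_annotations([self.REC], {})
        assert merged is self.REC

    def test_merge_is_idempotent(self):
        ann = {"1:100": AnnotationRecord("1:100", aa="A", cadd_phred=9.0)}
        once = list(merge_annotations([self.REC], ann))
        twice = list(merge_annotations(once, ann))
        assert once == twice
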