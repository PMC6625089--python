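"""Header parsing, typed coercion, parse levels, round trips, exporters."""

import gzip

import pytest

from vcfstack import (
    FieldDef,
    ParseLevel,
    VariantRecord,
    coerce_value,
    parse_header,
    parse_record,
    read_vcf,
    write_table,
    write_vcf,
)
from vcfstack.errors import (
    CoercionWarning,
    ConsistencyError,
    DuplicateDefinitionError,
    InputError,
    MalformedHeaderError,
    MalformedRecordError,
    UnknownColumnError,
)
from vcfstack.vcfio import render_record

from conftest import TINY_VCF

HEADER_LINES = [ln for ln in TINY_VCF.splitlines() if ln.startswith("#")]


class TestParseHeader:
    def test_info_defs_transcribed(self):
        header = parse_header(HEADER_LINES)
        af = header.info_defs["AF"]
        assert (af.id, af.number, af.type) == ("AF", "A", "Float")
        assert af.description == "Allele Frequency"
        db = header.info_defs["DB"]
        assert (db.number, db.type) == (0, "Flag")

    def test_sample_names_from_chrom_line(self):
        header = parse_header(HEADER_LINES)
        assert header.sample_names == ["FATHER", "MOTHER", "CHILD"]

    def test_sites_only_header_has_no_samples(self):
        lines = ["##fileformat=VCFv4.2",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        assert parse_header(lines).sample_names == []

    def test_unrecognized_lines_kept_verbatim_in_order(self):
        header = parse_header(HEADER_LINES)
        assert header.other_lines == [
            "##contig=<ID=1>", "##contig=<ID=2>", "##contig=<ID=X>"]

    def test_missing_chrom_line_rejected(self):
        with pytest.raises(MalformedHeaderError, match="#CHROM"):
            parse_header(["##fileformat=VCFv4.2"])

    def test_duplicate_definition_rejected(self):
        dup = '##INFO=<ID=AF,Number=1,Type=Float,Description="again">'
        with pytest.raises(DuplicateDefinitionError, match="AF"):
            parse_header(HEADER_LINES[:2] + [dup] + HEADER_LINES[2:])

    def test_description_with_commas_and_quotes(self):
        line = ('##INFO=<ID=NOTE,Number=1,Type=String,'
                'Description="benign, likely \\"hot\\"">')
        header = parse_header(["##fileformat=VCFv4.2", line,
                               "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"])
        assert header.info_defs["NOTE"].description == 'benign, likely "hot"'

    def test_write_then_reparse_is_identity(self):
        header = parse_header(HEADER_LINES)
        again = parse_header(header.render_lines())
        assert again.info_defs == header.info_defs
        assert again.format_defs == header.format_defs
        assert again.sample_names == header.sample_names


class TestCoerceValue:
    @pytest.mark.parametrize("raw,fdef,expected", [
        ("0.0134", FieldDef("X", "INFO", 1, "Float"), 0.0134),
        ("12,3", FieldDef("X", "INFO", "A", "Integer"), [12, 3]),
        (".", FieldDef("X", "INFO", 1, "Float"), None),
        (".", FieldDef("X", "INFO", 1, "String"), None),
        ("7", FieldDef("X", "INFO", 1, "Integer"), 7),
        ("a,.", FieldDef("X", "INFO", ".", "String"), ["a", None]),
    ])
    def test_typed_coercion(self, raw, fdef, expected):
        assert coerce_value(raw, fdef) == expected

    def test_flag_maps_to_presence(self):
        assert coerce_value("", FieldDef("DB", "INFO", 0, "Flag")) is True

    def test_uncoercible_value_warns_and_is_kept_as_text(self):
        fdef = FieldDef("X", "INFO", 1, "Float")
        with pytest.warns(CoercionWarning):
            assert coerce_value("NaNope", fdef) == "NaNope"


class TestParseRecord:
    def setup_method(self):
        self.header = parse_header(HEADER_LINES)

    def test_l0_keeps_info_not_samples(self):
        line = "1\t101\trs1\tA\tG\t50\tPASS\tAF=0.01\tGT\t0/1\t0/1\t1/1"
        rec = parse_record(line, self.header, ParseLevel.L0)
        assert rec.info == {"AF": [0.01]}
        assert rec.samples == {} and rec.format_keys == []

    def test_filter_retained_at_every_level(self):
        line = "1\t101\t.\tA\tG\t50\tq10;s50\tDP=9"
        for level in ParseLevel:
            assert parse_record(line, self.header, level).filter == ["q10", "s50"]

    def test_l1_adds_format_keys_only(self):
        line = "1\t101\t.\tA\tG\t50\tPASS\tDP=9\tGT:DP\t0/1:30\t0/1:2\t1/1:3"
        rec = parse_record(line, self.header, ParseLevel.L1)
        assert rec.format_keys == ["GT", "DP"]
        assert rec.samples == {}

    def test_l2_types_sample_values(self):
        line = "1\t101\t.\tA\tG\t50\tPASS\tDP=9\tGT:DP\t0/1:30\t0/1:2\t1/1:3"
        rec = parse_record(line, self.header, ParseLevel.L2)
        assert rec.samples["FATHER"] == {"GT": "0/1", "DP": 30}

    def test_alt_split_on_commas(self):
        line = "1\t101\t.\tA\tG,T\t50\tPASS\tDP=9"
        assert parse_record(line, self.header).alt == ["G", "T"]

    def test_too_few_columns_rejected_with_line_number(self):
        with pytest.raises(MalformedRecordError, match="line 12"):
            parse_record("1\t101\t.\tA", self.header, lineno=12)

    def test_nonpositive_pos_rejected(self):
        with pytest.raises(MalformedRecordError, match="POS"):
            parse_record("1\t0\t.\tA\tG\t50\tPASS\tDP=9", self.header)
        with pytest.raises(MalformedRecordError, match="POS"):
            parse_record("1\tabc\t.\tA\tG\t50\tPASS\tDP=9", self.header)

    def test_missing_qual_and_trailing_dropped_sample_field(self):
        line = "X\t500\t.\tG\tA\t.\tPASS\tAF=0.001\tGT:DP\t0\t0/1:20\t1"
        rec = parse_record(line, self.header)
        assert rec.qual is None
        assert rec.samples["FATHER"] == {"GT": "0", "DP": None}


class TestReadVcf:
    def test_record_count_conservation(self, tiny_vcf_path):
        _, records = read_vcf(tiny_vcf_path)
        assert len(list(records)) == 5

    def test_gzip_detected_by_magic_bytes_not_extension(self, tmp_path):
        plain = tmp_path / "a.vcf"
        plain.write_text(TINY_VCF)
        disguised = tmp_path / "b.vcf"  # gzipped despite the .vcf name
        disguised.write_bytes(gzip.compress(TINY_VCF.encode()))
        _, r1 = read_vcf(plain)
        _, r2 = read_vcf(disguised)
        assert list(r1) == list(r2)

    def test_crlf_line_endings_accepted(self, tmp_path):
        path = tmp_path / "crlf.vcf"
        path.write_bytes(TINY_VCF.replace("\n", "\r\n").encode())
        _, records = read_vcf(path)
        base_header, base = read_vcf_text(tmp_path, TINY_VCF)
        assert list(records) == base

    def test_undeclared_key_auto_registered_as_string(self, tiny_store):
        fdef = tiny_store.header.info_defs["XYZ"]
        assert (fdef.type, fdef.number) == ("String", ".")
        rec = tiny_store.records[2]
        assert rec.info["XYZ"] == ["foo"]  # Number='.' values are lists

    def test_empty_file_is_an_input_error(self, tmp_path):
        empty = tmp_path / "empty.vcf"
        empty.write_text("")
        with pytest.raises(InputError):
            read_vcf(empty)

    def test_missing_file_is_an_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_vcf(tmp_path / "nope.vcf")


def read_vcf_text(tmp_path, text, level=ParseLevel.L2):
    path = tmp_path / "scratch_read.vcf"
    path.write_text(text)
    header, records = read_vcf(path, level)
    return header, list(records)


class TestWriteVcf:
    def test_round_trip_identity(self, tmp_path, tiny_vcf_path):
        header, records = read_vcf(tiny_vcf_path)
        records = list(records)
        out = tmp_path / "out.vcf"
        assert write_vcf(header, records, out) == len(records)
        header2, records2 = read_vcf(out)
        assert list(records2) == records
        assert header2.info_defs == header.info_defs

    def test_round_trip_on_generated_fixture(self, tmp_path, small_store):
        subset = small_store.records[:500]
        out = tmp_path / "subset.vcf.gz"
        assert write_vcf(small_store.header, subset, out) == 500
        _, again = read_vcf(out)
        assert list(again) == subset

    def test_empty_survivor_set_yields_header_only_vcf(self, tmp_path, tiny_vcf_path):
        header, _ = read_vcf(tiny_vcf_path)
        out = tmp_path / "empty.vcf"
        assert write_vcf(header, [], out) == 0
        header2, records2 = read_vcf(out)
        assert list(records2) == []
        assert header2.sample_names == header.sample_names

    def test_provenance_lines_emitted_verbatim(self, tmp_path, tiny_vcf_path):
        header, _ = read_vcf(tiny_vcf_path)
        out = tmp_path / "prov.vcf"
        write_vcf(header, [], out, provenance=["##vcfstack_filter=QUAL>30"])
        text = out.read_text()
        assert "##vcfstack_filter=QUAL>30\n" in text
        assert text.index("##vcfstack_filter") < text.index("#CHROM")

    def test_unknown_sample_in_record_rejected(self, tmp_path, tiny_vcf_path):
        header, records = read_vcf(tiny_vcf_path)
        rec = next(iter(records))
        rec.samples["GHOST"] = {"GT": "0/1", "DP": 1}
        with pytest.raises(ConsistencyError, match="GHOST"):
            write_vcf(header, [rec], tmp_path / "bad.vcf")


class TestWriteTable:
    def test_header_plus_one_row_per_record(self, tmp_path, tiny_store):
        out = tmp_path / "t.csv"
        n = write_table(tiny_store.header, tiny_store.records[:3],
                        ["CHROM", "POS", "REF", "ALT", "AF"], out)
        assert n == 3
        lines = out.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == "CHROM,POS,REF,ALT,AF"
        assert lines[3].startswith("chr1,200,G,") and '"C,T"' in lines[3]

    def test_csv_value_with_comma_is_quoted(self, tmp_path, tiny_store):
        rec = tiny_store.records[0]
        rec.info["CLASS"] = "benign,likely"
        out = tmp_path / "q.csv"
        write_table(tiny_store.header, [rec], ["CLASS"], out)
        assert out.read_text().splitlines()[1] == '"benign,likely"'

    def test_sample_format_column_and_missing_dot(self, tmp_path, tiny_store):
        out = tmp_path / "gt.tsv"
        write_table(tiny_store.header, tiny_store.records,
                    ["POS", "CHILD.GT", "QUAL"], out, dialect="TSV")
        lines = out.read_text().splitlines()
        assert lines[1].split("\t") == ["101", "1/1", "50"]
        assert lines[2].split("\t") == ["150", "0/1", "."]

    def test_unknown_column_error_lists_valid_names(self, tmp_path, tiny_store):
        with pytest.raises(UnknownColumnError, match="AF"):
            write_table(tiny_store.header, [], ["NOPE"], tmp_path / "x.csv")


def test_render_record_is_reparsable_for_constructed_record():
    header = parse_header(HEADER_LINES)
    rec = VariantRecord("1", 42, None, "A", ["T"], None, None,
                        {"DB": True, "AF": [0.25, None]}, [], {})
    line = render_record(rec, header)
    assert parse_record(line, header) == rec
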