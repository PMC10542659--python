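"""Association-database parsing, indexing, and store persistence."""

import gzip
import io
import json

import pytest

from varhits import (
    SchemaError,
    StoreIntegrityError,
    StoreVersionError,
    ValidationError,
    build_index,
    load_store,
    normalize_chrom,
    parse_database_tsv,
    save_store,
    write_database_tsv,
)
from varhits.db import DbMeta, parse_p_value


def tsv_of(records):
    buf = io.StringIO()
    write_database_tsv(records, buf)
    return buf.getvalue()


class TestNormalizeChrom:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("X", "X"),
            ("chr6", "6"),
            ("chrM", "MT"),
            ("m", "MT"),
            ("ChrX", "X"),
            ("22", "22"),
            ("HLA-A", "HLA-A"),  # unknown contig: upper-cased, unchanged
            (" chr10 ", "10"),
        ],
    )
    def test_canonical_forms(self, raw, expected):
        assert normalize_chrom(raw) == expected

    @pytest.mark.parametrize("raw", ["", "   ", "chr"])
    def test_empty_rejected(self, raw):
        with pytest.raises(ValidationError):
            normalize_chrom(raw)

    def test_idempotent(self):
        for raw in ["chr6", "X", "chrM", "weird_contig"]:
            once = normalize_chrom(raw)
            assert normalize_chrom(once) == once


class TestParsePValue:
    def test_unicode_minus_accepted(self):
        assert parse_p_value("2.00E−12") == pytest.approx(2e-12)
        assert parse_p_value("2E-170") == pytest.approx(2e-170)

    @pytest.mark.parametrize("bad", ["not_a_number", "0", "-0.5", "1.5", ""])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_p_value(bad)


class TestParseDatabaseTsv:
    def test_fixture_table_parses_to_four_records(self, fixture_data):
        records, summary = parse_database_tsv(io.StringIO(tsv_of(fixture_data.records)))
        assert len(records) == 4
        assert summary.rows_dropped == 0
        shared = [r for r in records if r.key == ("10", 121577821)]
        assert len(shared) == 2
        assert {r.p_text for r in records} == {
            "2.00E−12", "8.00E−08", "2E-170", "2.00E−10",
        }

    def test_header_only_gives_empty_with_warning(self):
        records, summary = parse_database_tsv(
            io.StringIO("chrom\tpos\trsid\tref\talt\tgene\tconsequence\tp_value\tdisease\tsource_db\n")
        )
        assert records == []
        assert summary.empty_input

    def test_bad_rows_dropped_and_counted(self, fixture_data):
        text = tsv_of(fixture_data.records[:3])
        text += "6\t100\trsX\tA\tG\tGENE\t\tnot_a_number\tSome disease\tGWASdb\n"
        records, summary = parse_database_tsv(io.StringIO(text))
        assert len(records) == 3
        assert summary.rows_dropped == 1

    def test_missing_mandatory_column_names_it(self):
        with pytest.raises(SchemaError) as excinfo:
            parse_database_tsv(io.StringIO("chrom\tpos\tp_value\tsource_db\nx\ty\tz\tw\n"))
        assert "disease" in str(excinfo.value)

    def test_custom_schema_and_extra_columns(self):
        text = (
            "CHR\tBP\tSNP\tPVAL\tTRAIT\tSOURCE\tIGNORED\n"
            "chr7\t123\trs1\t5e-9\tGout\tGRASP\tjunk\n"
        )
        schema = {
            "chrom": "CHR", "pos": "BP", "rsid": "SNP",
            "p_value": "PVAL", "disease": "TRAIT", "source_db": "SOURCE",
        }
        records, _ = parse_database_tsv(io.StringIO(text), schema)
        assert len(records) == 1
        rec = records[0]
        assert rec.chrom == "7" and rec.pos == 123 and rec.p_text == "5e-9"
        assert rec.gene == "" and rec.ref_allele == ""


class TestBuildIndex:
    def test_every_record_reachable_at_its_own_key(self, fixture_db, fixture_data):
        for rec in fixture_data.records:
            assert rec in fixture_db.lookup(rec.chrom, rec.pos)
        assert fixture_db.lookup("10", 121577821) == fixture_data.records[2:4]
        assert fixture_db.lookup("6", 1) == []
        assert fixture_db.meta.record_count == 4

    def test_exact_duplicates_collapse(self, fixture_data):
        rec = fixture_data.records[0]
        db = build_index([rec, rec])
        assert db.meta.record_count == 1
        assert db.meta.dedup_count == 1

    def test_near_duplicates_all_kept(self, fixture_data):
        # same locus+disease+source, different p: both survive
        both = fixture_data.records[2:4]
        db = build_index(both)
        assert db.meta.record_count == 2
        assert len(db.lookup("10", 121577821)) == 2

    def test_empty_input_is_a_valid_database(self):
        db = build_index([])
        assert len(db) == 0
        assert db.lookup("1", 1) == []


class TestStore:
    def test_round_trip_preserves_everything(self, tmp_path, fixture_data):
        db = build_index(
            fixture_data.records, DbMeta(build_tag="GRCh38", source_name="fixture")
        )
        path = tmp_path / "fixture.store"
        save_store(db, path)
        loaded = load_store(path)
        assert loaded == db
        assert loaded.lookup("10", 121577821) == db.lookup("10", 121577821)
        assert loaded.meta.build_tag == "GRCh38"

    def test_empty_database_round_trips(self, tmp_path):
        path = tmp_path / "empty.store"
        save_store(build_index([]), path)
        assert len(load_store(path)) == 0

    def test_reindex_after_round_trip_is_idempotent(self, tmp_path, fixture_data):
        db = build_index(fixture_data.records)
        path = tmp_path / "a.store"
        save_store(db, path)
        again = build_index(load_store(path).records, DbMeta())
        assert again.records == db.records

    def test_major_version_bump_rejected(self, tmp_path, fixture_data):
        db = build_index(fixture_data.records)
        path = tmp_path / "v2.store"
        save_store(db, path)
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["version"] = "2.0"
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh)
        with pytest.raises(StoreVersionError) as excinfo:
            load_store(path)
        assert "2.0" in str(excinfo.value) and "1.0" in str(excinfo.value)

    def test_truncated_file_rejected(self, tmp_path, fixture_data):
        path = tmp_path / "trunc.store"
        save_store(build_index(fixture_data.records), path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(StoreIntegrityError):
            load_store(path)

    def test_record_count_mismatch_rejected(self, tmp_path, fixture_data):
        path = tmp_path / "bad.store"
        save_store(build_index(fixture_data.records), path)
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["meta"]["record_count"] = 99
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh)
        with pytest.raises(StoreIntegrityError):
            load_store(path)
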