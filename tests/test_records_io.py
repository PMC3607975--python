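"""Registry record types, CSV round-trip, schema dialects, age derivation."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traumalink import (
    Registry,
    SchemaConfig,
    SchemaError,
    derive_age,
    read_registry_csv,
    write_registry_csv,
)
from traumalink.records import validate_record

from conftest import make_pir, make_tr, pir_table, tr_table


class TestReadValidation:
    def test_well_formed_file_round_trips_identically(self, tmp_path):
        table = pir_table(
            [
                make_pir("P1"),
                make_pir("P2", age=63),
                make_pir("P3", hb=None, sbp=None, payload={"prbc": "4"}),
            ]
        )
        path = tmp_path / "pir.csv"
        write_registry_csv(table, path)
        result = read_registry_csv(path, Registry.PIR)
        assert result.n_rejected == 0
        assert result.table.records == table.records

    def test_tr_round_trip_preserves_ais_codes_and_missing(self, tmp_path):
        table = tr_table(
            [
                make_tr("T1", ais=("856100.2", "850802.3")),
                make_tr("T2", ais=(), hb=None),
            ]
        )
        path = tmp_path / "tr.csv"
        write_registry_csv(table, path)
        result = read_registry_csv(path, Registry.TR)
        assert result.n_rejected == 0
        assert result.table.records[0].ais_codes == ["856100.2", "850802.3"]
        assert result.table.records == table.records

    def test_date_order_violation_rejected_with_reason(self, tmp_path):
        table = pir_table([make_pir("P1"), make_pir("P2"), make_pir("P3")])
        path = tmp_path / "pir.csv"
        write_registry_csv(table, path)
        text = path.read_text().replace("P2,H01,2005-03-02,2005-03-20", "P2,H01,2005-03-02,2005-02-20")
        path.write_text(text)
        result = read_registry_csv(path, Registry.PIR)
        assert len(result.table) == 2
        assert result.n_rejected == 1
        assert "date order" in result.rejects[0].reason
        # validation is total: accepted + rejected = input rows
        assert len(result.table) + result.n_rejected == 3

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,admission_date\nP1,2005-03-02\n")
        with pytest.raises(SchemaError, match="hospital_code"):
            read_registry_csv(path, Registry.PIR)

    def test_missing_hb_reads_back_as_missing_not_zero(self, tmp_path):
        table = pir_table([make_pir("P1", hb=None)])
        path = tmp_path / "pir.csv"
        write_registry_csv(table, path)
        rec = read_registry_csv(path, Registry.PIR).table.records[0]
        assert rec.initial_hb is None

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_registry_csv(pir_table([]), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        result = read_registry_csv(path, Registry.PIR)
        assert len(result.table) == 0 and result.n_rejected == 0

    def test_german_date_dialect_and_column_mapping(self, tmp_path):
        path = tmp_path / "export.csv"
        path.write_text(
            "FallNr,Klinik,Aufnahme,Entlassung,Geschlecht\n"
            "P1,H01,02.03.2005,20.03.2005,männlich\n"
        )
        schema = SchemaConfig(
            columns={
                "record_id": "FallNr",
                "hospital_code": "Klinik",
                "admission_date": "Aufnahme",
                "discharge_date": "Entlassung",
                "sex": "Geschlecht",
            },
            date_format="dmy",
        )
        result = read_registry_csv(path, Registry.PIR, schema)
        rec = result.table.records[0]
        assert result.n_rejected == 0
        assert rec.admission_date == date(2005, 3, 2)
        assert rec.sex.value == "male"

    def test_malformed_ais_code_rejected(self, tmp_path):
        table = tr_table([make_tr("T1")])
        path = tmp_path / "tr.csv"
        write_registry_csv(table, path)
        path.write_text(path.read_text().replace("856100.2", "856"))
        result = read_registry_csv(path, Registry.TR)
        assert result.n_rejected == 1
        assert "AIS" in result.rejects[0].reason


class TestDeriveAge:
    @pytest.mark.parametrize(
        "age, birthdate, adm, expected",
        [
            (41, None, "2005-03-02", 41),  # stored age passes through
            (None, "1970-06-15", "2005-06-14", 34),  # day before anniversary
            (None, "1970-06-15", "2005-06-15", 35),  # on the anniversary
            (None, None, "2005-03-02", None),
        ],
    )
    def test_completed_years_at_admission(self, age, birthdate, adm, expected):
        rec = make_pir(age=age, birthdate=birthdate, adm=adm)
        assert derive_age(rec) == expected

    def test_birthdate_after_reference_raises(self):
        rec = make_pir(age=None, birthdate="2006-01-01", adm="2005-03-02")
        with pytest.raises(ValueError):
            derive_age(rec)

    @given(
        birth=st.dates(date(1910, 1, 1), date(2000, 12, 31)),
        ref1=st.dates(date(2004, 1, 1), date(2009, 12, 31)),
        ref2=st.dates(date(2004, 1, 1), date(2009, 12, 31)),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_reference_date(self, birth, ref1, ref2):
        rec = make_pir(age=None, birthdate=birth.isoformat(), adm="2009-12-31")
        lo, hi = sorted([ref1, ref2])
        assert derive_age(rec, lo) <= derive_age(rec, hi)


def test_validate_record_flags_iss_out_of_range():
    rec = make_pir(iss=76)
    assert any("iss" in p for p in validate_record(rec))
    assert validate_record(make_pir(iss=75)) == []
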