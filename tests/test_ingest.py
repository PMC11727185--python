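"""Reading, scope filtering and duplicate-notification removal."""

import math
from datetime import date

import pytest

from vetregqa.ingest import (
    ScopeConfig,
    filter_scope,
    read_prescriptions,
    read_wholesale,
    remove_practitioner_duplicates,
    write_prescriptions,
    write_wholesale,
)
from vetregqa.model import PrescriptionRecord, ReportType, WholesaleRecord
from vetregqa.synthetic import generate, simple_config, write_dataset

HEADER = (
    "report_id,registration_date,delivery_date,report_type,product_id,atc_code,"
    "product_name,quantity,quantity_unit,species,n_animals,weight,owner_location,pharmacy_id"
)


def make_record(**kw) -> PrescriptionRecord:
    defaults = dict(
        report_id="R1",
        registration_date=date(2020, 2, 1),
        delivery_date=date(2020, 1, 15),
        report_type=ReportType.PHARMACY_DELIVERY,
        product_id="027475",
        atc_code="QI10AL02",
        product_name="Alpha Ject Micro 6",
        quantity=10_000.0,
        quantity_unit="stk",
        species="Atlantic salmon",
        n_animals=10_000,
        pharmacy_id="PHA",
    )
    defaults.update(kw)
    return PrescriptionRecord(**defaults)


class TestReadPrescriptions:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            HEADER + "\n"
            "R1,2020-02-01,2020-01-15,pharmacy_delivery,027475,QI10AL02,AJM6,"
            "500,ml,Atlantic salmon,10000,25.0,12345,PHA\n"
            "R2,2020-02-02,2020-01-16,pharmacy_delivery,130772,QI10AB02,AJ3000,"
            "100,stk,Rainbow trout,,,,PHB\n"
            "R3,2020-02-03,2020-01-17,practitioner_use,560340,QI10AL02,AQ6,"
            "50,dose,Brown trout,50,,54321,PHB\n"
        )
        records, rejects = read_prescriptions(path)
        assert len(records) == 3 and not rejects
        assert records[0].quantity == 500.0
        assert records[1].n_animals is None
        assert records[2].quantity_unit == "stk"  # "dose" folded
        assert records[2].report_type is ReportType.PRACTITIONER_USE

    def test_unparseable_date_goes_to_reject_log(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            HEADER + "\n"
            "R1,not-a-date,2020-01-15,pharmacy_delivery,027475,QI10AL02,x,"
            "500,ml,Atlantic salmon,,,,PHA\n"
        )
        records, rejects = read_prescriptions(path)
        assert records == []
        assert len(rejects) == 1
        assert rejects[0].row_number == 2

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text("report_id,quantity\nR1,5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_prescriptions(path)

    def test_generator_round_trip(self, tmp_path):
        config = simple_config(seed=42, n_records=100)
        dataset = generate(config)
        paths = write_dataset(dataset, tmp_path)
        records, rejects = read_prescriptions(paths["records"])
        assert len(records) == 100 and not rejects
        for orig, back in zip(dataset.records, records):
            assert back.report_id == orig.report_id
            assert back.delivery_date == orig.delivery_date
            assert back.registration_date == orig.registration_date
            assert back.product_id == orig.product_id
            assert back.quantity_unit == orig.quantity_unit
            assert back.n_animals == orig.n_animals
            assert back.owner_location == orig.owner_location
            assert math.isclose(back.quantity, orig.quantity, rel_tol=1e-12)

    def test_unrecognized_unit_carried_on_record(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            HEADER + "\n"
            "R1,2020-02-01,2020-01-15,pharmacy_delivery,027475,QI10AL02,x,"
            "3,bottles,Atlantic salmon,,,,PHA\n"
        )
        records, rejects = read_prescriptions(path)
        assert not rejects
        assert records[0].quantity_unit == "bottles"
        assert records[0].unit_recognized is False


class TestFilterScope:
    def test_atc_and_window_drops_with_conservation(self):
        records = [
            make_record(report_id="in"),
            make_record(report_id="atc", atc_code="QI01AD02"),
            make_record(
                report_id="window",
                delivery_date=date(2015, 12, 31),
                registration_date=date(2016, 1, 5),
            ),
        ]
        result = filter_scope(records, ScopeConfig(2016, 2022))
        assert [r.report_id for r in result.kept] == ["in"]
        assert result.drop_counts == {"out_of_window": 1, "non_matching_atc": 1}
        n = len(result.kept) + sum(result.drop_counts.values())
        assert n == len(records)

    def test_window_boundaries_inclusive(self):
        first = make_record(
            delivery_date=date(2016, 1, 1), registration_date=date(2016, 1, 2)
        )
        last = make_record(
            delivery_date=date(2022, 12, 31), registration_date=date(2023, 1, 4)
        )
        result = filter_scope([first, last], ScopeConfig(2016, 2022))
        assert len(result.kept) == 2

    def test_invalid_scope_rejected(self):
        with pytest.raises(ValueError):
            ScopeConfig(2022, 2016)
        with pytest.raises(ValueError):
            ScopeConfig(2016, 2022, atc_prefixes=())


class TestPractitionerRemoval:
    def test_partition(self):
        pharm = [make_record(report_id=f"p{i}") for i in range(5)]
        pract = [
            make_record(report_id=f"v{i}", report_type=ReportType.PRACTITIONER_USE)
            for i in range(2)
        ]
        kept, removed = remove_practitioner_duplicates(pharm + pract)
        assert len(kept) == 5 and len(removed) == 2
        assert {r.report_id for r in kept} | {r.report_id for r in removed} == {
            r.report_id for r in pharm + pract
        }

    def test_no_practitioners(self):
        kept, removed = remove_practitioner_duplicates([make_record()])
        assert len(kept) == 1 and removed == []


class TestReadWholesale:
    def make_sales_file(self, tmp_path, rows):
        path = tmp_path / "sales.csv"
        write_wholesale(rows, path)
        return path

    def test_name_exclusion_and_scope(self, tmp_path):
        rows = [
            WholesaleRecord(2020, "QI10AL02", "027475", "Alpha Ject Micro 6", 500, 10),
            WholesaleRecord(2020, "QI10AB04", "999999", "IZOVAC ENCEPHALOMYELITS", 1000, 2),
            WholesaleRecord(2015, "QI10AL02", "027475", "Alpha Ject Micro 6", 500, 1),
            WholesaleRecord(2020, "QI01AD02", "888888", "Other vaccine", 500, 1),
        ]
        path = self.make_sales_file(tmp_path, rows)
        kept, log = read_wholesale(path, ScopeConfig(2016, 2022))
        assert len(kept) == 1
        assert log.n_excluded_name == 1
        assert log.n_dropped_year == 1
        assert log.n_dropped_atc == 1
        assert log.n_read == 4

    def test_same_product_year_rows_both_kept(self, tmp_path):
        rows = [
            WholesaleRecord(2020, "QI10AL02", "027475", "Alpha Ject Micro 6", 500, 3),
            WholesaleRecord(2020, "QI10AL02", "027475", "Alpha Ject Micro 6", 500, 2),
        ]
        kept, _ = read_wholesale(self.make_sales_file(tmp_path, rows))
        assert len(kept) == 2  # summation happens later, never implicit dedup

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "sales.csv"
        path.write_text("year,product_id\n2020,027475\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_wholesale(path)


def test_prescription_write_read_round_trip(tmp_path):
    records = [make_record(), make_record(report_id="R2", quantity=234.5, quantity_unit="ml")]
    path = tmp_path / "r.csv"
    write_prescriptions(records, path)
    back, rejects = read_prescriptions(path)
    assert not rejects
    assert [r.report_id for r in back] == ["R1", "R2"]
    assert back[1].quantity == 234.5
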