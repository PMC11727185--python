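"""Readers and writers for register extracts, scope filtering, deduplication.

Row-level parsing uses the stdlib csv module so that malformed rows can be
collected in a reject log with their row number and reason instead of being
silently dropped (or aborting the whole read, as a vectorized parser would).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    PrescriptionRecord,
    ReportType,
    WholesaleRecord,
    canonical_product_id,
    fold_unit,
    normalize_vaccine_name,
    _fmt,
)

#: Register-extract report-type labels; canonical tokens are accepted too.
DEFAULT_REPORT_TYPE_LABELS: dict[str, ReportType] = {
    "pharmacy_delivery": ReportType.PHARMACY_DELIVERY,
    "practitioner_use": ReportType.PRACTITIONER_USE,
    "delivery from pharmacies to animal owners/husbandry": ReportType.PHARMACY_DELIVERY,
    "notification of animal health professional's use of medicinal products": (
        ReportType.PRACTITIONER_USE
    ),
    "notification of animal health personnel's use of medicinal products": (
        ReportType.PRACTITIONER_USE
    ),
}

RECORD_COLUMNS = [
    "report_id",
    "registration_date",
    "delivery_date",
    "report_type",
    "product_id",
    "atc_code",
    "product_name",
    "quantity",
    "quantity_unit",
    "species",
    "n_animals",
    "weight",
    "owner_location",
    "pharmacy_id",
]

SALES_COLUMNS = [
    "year",
    "atc_code",
    "product_id",
    "vaccine_name",
    "pack_size_ml",
    "n_packs",
    "marketed",
]


@dataclass
class ReaderConfig:
    """Dialect and column binding for register extracts.

    Nordic exports commonly use semicolon delimiters and decimal commas;
    both are configurable because the extract format varies by source.
    ``column_map`` maps the canonical column names to the file's headers.
    """

    delimiter: str = ","
    decimal: str = "."
    column_map: dict[str, str] = field(default_factory=dict)
    report_type_labels: dict[str, ReportType] = field(
        default_factory=lambda: dict(DEFAULT_REPORT_TYPE_LABELS)
    )

    def source_column(self, name: str) -> str:
        return self.column_map.get(name, name)

    def parse_number(self, text: str) -> float:
        if self.decimal != ".":
            text = text.replace(self.decimal, ".")
        return float(text)


@dataclass(frozen=True)
class ScopeConfig:
    """Study window and ATC scope for the fish-vaccine record stream."""

    year_start: int = 2016
    year_end: int = 2022
    atc_prefixes: tuple[str, ...] = ("QI10A", "QI10B")
    wholesale_exclusions: tuple[str, ...] = ("IZOVAC ENCEPHALOMYELITS",)

    def __post_init__(self) -> None:
        if self.year_start > self.year_end:
            raise ValueError("year_start must not exceed year_end")
        if not self.atc_prefixes:
            raise ValueError("at least one ATC prefix required")

    def atc_in_scope(self, atc: str) -> bool:
        return any(atc.startswith(p) for p in self.atc_prefixes)

    def year_in_scope(self, year: int) -> bool:
        return self.year_start <= year <= self.year_end


@dataclass(frozen=True)
class Reject:
    row_number: int
    reason: str
    raw_line: str


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def read_prescriptions(
    path: str | Path, config: ReaderConfig | None = None
) -> tuple[list[PrescriptionRecord], list[Reject]]:
    """Parse a prescription extract; malformed rows go to the reject log.

    Raises ``ValueError`` if a required column is missing from the header.
    """
    cfg = config or ReaderConfig()
    records: list[PrescriptionRecord] = []
    rejects: list[Reject] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=cfg.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in RECORD_COLUMNS if cfg.source_column(c) not in header]
        if missing:
            raise ValueError(f"prescription file missing columns: {missing}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                records.append(_parse_record(row, cfg, record_id=len(records)))
            except (ValueError, KeyError, TypeError) as exc:
                raw = cfg.delimiter.join("" if v is None else str(v) for v in row.values())
                rejects.append(Reject(row_number=i, reason=str(exc), raw_line=raw))
    return records, rejects


def _parse_record(row: dict, cfg: ReaderConfig, record_id: int) -> PrescriptionRecord:
    def get(name: str) -> str:
        value = row.get(cfg.source_column(name))
        return "" if value is None else str(value).strip()

    label = get("report_type").strip().lower()
    if label not in cfg.report_type_labels:
        raise ValueError(f"unknown report type label: {get('report_type')!r}")
    raw_unit = get("quantity_unit")
    folded = fold_unit(raw_unit)
    n_animals = get("n_animals")
    weight = get("weight")
    location = get("owner_location") or None
    return PrescriptionRecord(
        report_id=get("report_id"),
        registration_date=_parse_date(get("registration_date")),
        delivery_date=_parse_date(get("delivery_date")),
        report_type=cfg.report_type_labels[label],
        product_id=canonical_product_id(get("product_id")),
        atc_code=get("atc_code"),
        product_name=get("product_name"),
        quantity=cfg.parse_number(get("quantity")),
        quantity_unit=folded if folded is not None else raw_unit,
        unit_recognized=folded is not None,
        species=get("species"),
        n_animals=int(float(n_animals)) if n_animals else None,
        weight=cfg.parse_number(weight) if weight else None,
        owner_location=location,
        pharmacy_id=get("pharmacy_id"),
        record_id=record_id,
    )


def write_prescriptions(records: Iterable[PrescriptionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.report_id,
                    r.registration_date.isoformat(),
                    r.delivery_date.isoformat(),
                    r.report_type.value,
                    r.product_id,
                    r.atc_code,
                    r.product_name,
                    _fmt(r.quantity),
                    r.quantity_unit,
                    r.species,
                    "" if r.n_animals is None else r.n_animals,
                    "" if r.weight is None else _fmt(r.weight),
                    "" if r.owner_location is None else r.owner_location,
                    r.pharmacy_id,
                ]
            )


def write_rejects(rejects: Iterable[Reject], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row_number", "reason", "raw_line"])
        for r in rejects:
            w.writerow([r.row_number, r.reason, r.raw_line])


# ---------------------------------------------------------------------------
# Scope filtering and duplicate-notification removal


@dataclass
class ScopeResult:
    kept: list[PrescriptionRecord]
    dropped_out_of_window: list[PrescriptionRecord]
    dropped_atc: list[PrescriptionRecord]

    @property
    def drop_counts(self) -> dict[str, int]:
        return {
            "out_of_window": len(self.dropped_out_of_window),
            "non_matching_atc": len(self.dropped_atc),
        }


def filter_scope(
    records: Sequence[PrescriptionRecord], scope: ScopeConfig | None = None
) -> ScopeResult:
    """Keep records whose delivery year and ATC code fall inside the scope.

    Dropped records are partitioned by reason (window first, then ATC) so
    that |kept| + sum of drops = |input|.
    """
    scope = scope or ScopeConfig()
    result = ScopeResult([], [], [])
    for r in records:
        if not scope.year_in_scope(r.year):
            result.dropped_out_of_window.append(r)
        elif not scope.atc_in_scope(r.atc_code):
            result.dropped_atc.append(r)
        else:
            result.kept.append(r)
    return result


def remove_practitioner_duplicates(
    records: Sequence[PrescriptionRecord],
) -> tuple[list[PrescriptionRecord], list[PrescriptionRecord]]:
    """Partition out practitioner-use notifications.

    Practitioner notifications duplicate pharmacy dispensations already in
    the register, so all of them are removed uniformly before cleansing.
    """
    kept = [r for r in records if r.report_type is not ReportType.PRACTITIONER_USE]
    removed = [r for r in records if r.report_type is ReportType.PRACTITIONER_USE]
    return kept, removed


# ---------------------------------------------------------------------------
# Wholesaler sales


@dataclass
class WholesaleLog:
    n_read: int = 0
    n_excluded_name: int = 0
    n_dropped_atc: int = 0
    n_dropped_year: int = 0


def read_wholesale(
    path: str | Path,
    scope: ScopeConfig | None = None,
    config: ReaderConfig | None = None,
) -> tuple[list[WholesaleRecord], WholesaleLog]:
    """Parse wholesaler sales rows, applying name exclusions and scope.

    The default exclusion list drops the one product known to carry a
    miscoded ATC in the sales extract. Rows sharing a product and year are
    all kept; summation happens later in the completeness module.
    """
    scope = scope or ScopeConfig()
    cfg = config or ReaderConfig()
    excluded_names = {normalize_vaccine_name(n) for n in scope.wholesale_exclusions}
    kept: list[WholesaleRecord] = []
    log = WholesaleLog()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=cfg.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in SALES_COLUMNS if cfg.source_column(c) not in header]
        if missing:
            raise ValueError(f"sales file missing columns: {missing}")
        for row in reader:
            log.n_read += 1
            name = str(row[cfg.source_column("vaccine_name")]).strip()
            year = int(row[cfg.source_column("year")])
            atc = str(row[cfg.source_column("atc_code")]).strip()
            if normalize_vaccine_name(name) in excluded_names:
                log.n_excluded_name += 1
                continue
            if not scope.year_in_scope(year):
                log.n_dropped_year += 1
                continue
            if not scope.atc_in_scope(atc):
                log.n_dropped_atc += 1
                continue
            kept.append(
                WholesaleRecord(
                    year=year,
                    atc_code=atc,
                    product_id=canonical_product_id(row[cfg.source_column("product_id")]),
                    vaccine_name=name,
                    pack_size_ml=cfg.parse_number(str(row[cfg.source_column("pack_size_ml")])),
                    n_packs=int(float(row[cfg.source_column("n_packs")])),
                    marketed=str(row[cfg.source_column("marketed")]).strip().lower()
                    in ("true", "1", "yes"),
                )
            )
    return kept, log


def write_wholesale(records: Iterable[WholesaleRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SALES_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.year,
                    r.atc_code,
                    r.product_id,
                    r.vaccine_name,
                    _fmt(r.pack_size_ml),
                    r.n_packs,
                    str(r.marketed).lower(),
                ]
            )
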