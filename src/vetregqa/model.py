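"""Domain model for prescription-register quality assessment.

This module defines the core record types shared by the whole pipeline:
vaccine product metadata keyed by the six-character national product ID,
prescription (dispensing) records as reported to the register, yearly
wholesaler sales records, the hatchery location registry, and the
harmonized record produced by the unit-cleansing cascade.

Product IDs are always handled as zero-padded six-character strings.
Numeric coercion is deliberately forbidden: IDs such as "027475" lose
their leading zero under integer round-trips (a classic spreadsheet
failure mode) and then no longer join between registers.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class AdminType(str, Enum):
    """Route of administration; bath vaccines have no fixed per-fish dose."""

    INJECTION = "injection"
    BATH = "bath"


class ReportType(str, Enum):
    PHARMACY_DELIVERY = "pharmacy_delivery"
    PRACTITIONER_USE = "practitioner_use"


class Disposition(str, Enum):
    KEPT = "kept"
    CORRECTED = "corrected"
    EXCLUDED = "excluded"


class Correction(str, Enum):
    NONE = "none"
    STK_TO_ML = "stk_to_ml"          # routine dose->volume conversion
    G_TO_ML = "g_to_ml"              # mass unit was actually ml
    KG_TO_L = "kg_to_l"              # mass unit was actually litres
    ML_TO_STK = "ml_to_stk"          # volume unit was actually doses
    STK_TO_ML_SWAP = "stk_to_ml_swap"  # dose unit was actually ml (swap heuristic)
    MASS_TO_STK = "mass_to_stk"      # g/kg quantity was actually a dose count


class ExclusionReason(str, Enum):
    NONE = "none"
    PRACTITIONER_DUPLICATE = "practitioner_duplicate"
    BATH_DOSE_UNIT = "bath_dose_unit"
    UNCORRECTABLE_UNIT = "uncorrectable_unit"


class UnitFlag(str, Enum):
    OK = "ok"
    CORRECTED = "corrected"
    UNCORRECTABLE = "uncorrectable"
    UNRECOGNIZED = "unrecognized"


class AnimalConsistency(str, Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    NOT_EVALUABLE = "not_evaluable"


class SpeciesFlag(str, Enum):
    TARGET = "target"
    OFF_TARGET = "off_target"
    PROBABLE_ENTRY_ERROR = "probable_entry_error"


class LocationFlag(str, Enum):
    VALID = "valid"
    UNKNOWN_LOCATION = "unknown_location"
    MISSING = "missing"


class AuthorizationFlag(str, Enum):
    WITHIN = "within"
    OUTSIDE = "outside"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Controlled unit vocabulary

CANONICAL_UNITS = ("stk", "ml", "l", "g", "kg")

_UNIT_SYNONYMS: Mapping[str, str] = {
    "stk": "stk",
    "stykk": "stk",
    "dose": "stk",
    "doser": "stk",
    "doses": "stk",
    "ml": "ml",
    "milliliter": "ml",
    "millilitre": "ml",
    "l": "l",
    "liter": "l",
    "litre": "l",
    "g": "g",
    "gram": "g",
    "kg": "kg",
    "kilo": "kg",
    "kilogram": "kg",
}


def fold_unit(raw: str) -> str | None:
    """Fold a raw quantity-unit spelling onto the controlled vocabulary.

    Case-insensitive; "dose"/"doser" map to the register's "stk" (piece)
    label. Returns ``None`` for out-of-vocabulary spellings — unrecognized
    units are carried on the record and become a validity flag downstream,
    never an exception.
    """
    folded = _UNIT_SYNONYMS.get(str(raw).strip().lower())
    return folded


def canonical_product_id(raw: str) -> str:
    """Zero-pad purely numeric product IDs to the six-character form."""
    s = str(raw).strip()
    if s.isdigit() and len(s) < 6:
        s = s.zfill(6)
    return s


# ---------------------------------------------------------------------------
# Product registry


@dataclass(frozen=True)
class ProductInfo:
    """Metadata for one nationally registered vaccine product.

    ``dose_ml`` is the per-fish dose volume from the Summary of Product
    Characteristics and is present exactly for injectable products; bath
    vaccines are diluted in water, so a dose has no fixed volume.
    ``auth_end_year`` of ``None`` means the authorization is open-ended.
    """

    product_id: str
    atc_code: str
    vaccine_name: str
    pack_size_ml: float
    dose_ml: float | None
    admin_type: AdminType
    auth_start_year: int
    auth_end_year: int | None = None

    def __post_init__(self) -> None:
        if len(self.product_id) != 6:
            raise ValueError(f"product_id must be 6 characters: {self.product_id!r}")
        if self.pack_size_ml <= 0:
            raise ValueError(f"non-positive pack size for {self.product_id}")
        if self.admin_type is AdminType.INJECTION:
            if self.dose_ml is None:
                raise ValueError(f"missing dose for injection product {self.product_id}")
            if not 0 < self.dose_ml <= self.pack_size_ml:
                raise ValueError(f"dose outside (0, pack size] for {self.product_id}")
        elif self.dose_ml is not None:
            raise ValueError(f"bath product {self.product_id} must not carry a dose")
        end = self.auth_end_year
        if end is not None and self.auth_start_year > end:
            raise ValueError(f"authorization interval reversed for {self.product_id}")

    def authorized_in(self, year: int) -> bool:
        end = self.auth_end_year if self.auth_end_year is not None else math.inf
        return self.auth_start_year <= year <= end


class ProductRegistry:
    """Collection of :class:`ProductInfo`, unique by product ID."""

    def __init__(self, products: Iterable[ProductInfo]):
        self._by_id: dict[str, ProductInfo] = {}
        for p in products:
            if p.product_id in self._by_id:
                raise ValueError(f"duplicate product_id {p.product_id}")
            self._by_id[p.product_id] = p

    def get(self, product_id: str) -> ProductInfo | None:
        return self._by_id.get(canonical_product_id(product_id))

    def __contains__(self, product_id: str) -> bool:
        return canonical_product_id(product_id) in self._by_id

    def __iter__(self) -> Iterator[ProductInfo]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def product_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def vaccine_names(self) -> set[str]:
        return {p.vaccine_name for p in self}

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "product_id",
                    "atc_code",
                    "vaccine_name",
                    "pack_size_ml",
                    "dose_ml",
                    "admin_type",
                    "auth_start_year",
                    "auth_end_year",
                ]
            )
            for p in self:
                w.writerow(
                    [
                        p.product_id,
                        p.atc_code,
                        p.vaccine_name,
                        _fmt(p.pack_size_ml),
                        "" if p.dose_ml is None else _fmt(p.dose_ml),
                        p.admin_type.value,
                        p.auth_start_year,
                        "" if p.auth_end_year is None else p.auth_end_year,
                    ]
                )


def _fmt(x: float) -> str:
    """Compact numeric formatting: integers without a decimal point."""
    if x == int(x):
        return str(int(x))
    return f"{x:.6f}".rstrip("0").rstrip(".")


def _data_path(name: str):
    return resources.files("vetregqa.data").joinpath(name)


def load_product_registry(path: str | Path | None = None) -> ProductRegistry:
    """Load a product registry from CSV, or the packaged default.

    The packaged default holds the 23 national product IDs (18 vaccine
    names) observed for salmonid vaccines in 2016–2022, with pack size,
    per-dose volume, administration type and authorization interval.
    """
    if path is None:
        with resources.as_file(_data_path("products.csv")) as p:
            return load_product_registry(p)
    products = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ProductRegistry([])
        required = {"product_id", "atc_code", "vaccine_name", "pack_size_ml", "admin_type"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"product file missing columns: {sorted(missing)}")
        for row in reader:
            dose = row.get("dose_ml", "").strip()
            end = row.get("auth_end_year", "").strip()
            products.append(
                ProductInfo(
                    product_id=canonical_product_id(row["product_id"]),
                    atc_code=row["atc_code"].strip(),
                    vaccine_name=row["vaccine_name"].strip(),
                    pack_size_ml=float(row["pack_size_ml"]),
                    dose_ml=float(dose) if dose else None,
                    admin_type=AdminType(row["admin_type"].strip().lower()),
                    auth_start_year=int(row.get("auth_start_year", 0) or 0),
                    auth_end_year=int(end) if end else None,
                )
            )
    return ProductRegistry(products)


# ---------------------------------------------------------------------------
# Location registry


@dataclass(frozen=True)
class LocationRegistry:
    """Set of five-digit site numbers for juvenile-producing hatcheries."""

    valid_locations: frozenset[str]

    def __post_init__(self) -> None:
        for loc in self.valid_locations:
            if not (len(loc) == 5 and loc.isdigit()):
                raise ValueError(f"location numbers must be 5 digits: {loc!r}")

    def __contains__(self, loc: str) -> bool:
        return loc in self.valid_locations

    def __len__(self) -> int:
        return len(self.valid_locations)


def load_locations(path: str | Path | None = None) -> LocationRegistry:
    """Load hatchery location numbers (one per line; ``#`` comments allowed).

    The packaged default is a synthetic stand-in list; the authoritative
    national register of aquaculture sites is not redistributable.
    """
    if path is None:
        with resources.as_file(_data_path("locations_synthetic.txt")) as p:
            return load_locations(p)
    locs = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                locs.add(line)
    return LocationRegistry(frozenset(locs))


# ---------------------------------------------------------------------------
# Vaccine-name normalization (used for name-level coverage keys)

_NAME_SUFFIXES = (" vet inj", " vet", " inj")


def load_name_aliases(path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        with resources.as_file(_data_path("vaccine_name_aliases.csv")) as p:
            return load_name_aliases(p)
    aliases: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            aliases[_basic_name_key(row["alias"])] = row["canonical"]
    return aliases


def _basic_name_key(name: str) -> str:
    key = " ".join(str(name).split()).lower()
    for suffix in _NAME_SUFFIXES:
        if key.endswith(suffix):
            key = key[: -len(suffix)]
            break
    return key


def normalize_vaccine_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a vaccine-name key: case, whitespace, trailing "vet"/"inj".

    The "Bath" suffix is significant (it distinguishes immersion products
    from injectable products of the same trade name) and is preserved.
    An explicit alias table can override the mechanical normalization.
    """
    key = _basic_name_key(name)
    if aliases and key in aliases:
        return _basic_name_key(aliases[key])
    return key


# ---------------------------------------------------------------------------
# Record types


@dataclass(slots=True)
class PrescriptionRecord:
    """One dispensing/use report row as received from the register.

    ``quantity_unit`` holds the canonical unit when the raw spelling folded
    onto the controlled vocabulary, otherwise the raw token with
    ``unit_recognized`` False. ``weight`` is carried but never used in
    computation: the register does not state its unit.
    """

    report_id: str
    registration_date: date
    delivery_date: date
    report_type: ReportType
    product_id: str
    atc_code: str
    product_name: str
    quantity: float
    quantity_unit: str
    species: str
    pharmacy_id: str
    n_animals: int | None = None
    weight: float | None = None
    owner_location: str | None = None
    unit_recognized: bool = True
    record_id: int = -1

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("quantity must be nonnegative")

    @property
    def year(self) -> int:
        """Record year is defined by the date of delivery."""
        return self.delivery_date.year


@dataclass(slots=True, frozen=True)
class WholesaleRecord:
    """Yearly sales of one product from wholesalers to pharmacies."""

    year: int
    atc_code: str
    product_id: str
    vaccine_name: str
    pack_size_ml: float
    n_packs: int
    marketed: bool = True

    def __post_init__(self) -> None:
        if self.n_packs < 0:
            raise ValueError("n_packs must be nonnegative")


@dataclass(slots=True)
class HarmonizedRecord:
    """A prescription record after the unit-harmonization cascade.

    ``volume_ml`` is the canonical volume; for injectable products with a
    disposition other than excluded, ``n_doses == volume_ml / dose_ml``.
    Corrections and exclusions are mutually exclusive and a record receives
    at most one correction.
    """

    record: PrescriptionRecord
    volume_ml: float | None
    n_doses: float | None
    disposition: Disposition
    correction: Correction = Correction.NONE
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    unit_flag: UnitFlag = UnitFlag.OK

    def __post_init__(self) -> None:
        excluded = self.disposition is Disposition.EXCLUDED
        if excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("disposition excluded iff exclusion_reason set")
        if excluded and self.correction is not Correction.NONE:
            raise ValueError("corrections and exclusions are mutually exclusive")
        if (self.disposition is Disposition.CORRECTED) != (
            self.correction is not Correction.NONE
        ):
            raise ValueError("disposition corrected iff a correction applied")
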