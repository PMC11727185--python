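"""Seeded generator of prescription and sales files with planted defects.

The generator first draws *clean* records — internally consistent
dispensings where the dose count equals the number of animals exactly —
and then plants each quality-defect class by transforming clean records
(relabelling the report type, rewriting the unit to g with the quantity
set to the true volume, swapping ml/dose labels, corrupting the animal
count, ...). Ground truth is therefore the pre-corruption state, every
planted defect is detectable by exactly its intended cleansing rule, and
the per-class totals are exact bookkeeping, not expectations.

Randomness comes from one root seed split into independent substreams
(record structure, defect content, dates/delays, sales), so enabling one
defect class does not perturb unrelated draws. Output files are
byte-stable for a fixed seed.

``table3_profile`` returns the packaged replication profile: per-year
record totals and per-class defect counts matching the published
2016–2022 cleansing census of the Norwegian prescription register
(7,443 in-scope records; 12 practitioner notifications; 684 bath-dose
exclusions; 3 uncorrectable mass-unit records; 2 g→ml and 3 kg→L
corrections; 32 ml→stk and 3 stk→ml swap corrections; 3,129 routine
dose→ml conversions; 6,744 survivors over 22 product IDs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import write_prescriptions, write_wholesale
from .model import (
    AdminType,
    LocationRegistry,
    PrescriptionRecord,
    ProductRegistry,
    ReportType,
    WholesaleRecord,
    load_locations,
    load_product_registry,
)

TARGET_SPECIES = ("Atlantic salmon", "Rainbow trout", "Brown trout")
OFF_TARGET_SPECIES = ("Cyclopterus", "Ornamental fish", "Turbot fish", "Other farmed fish")
OUT_OF_SCOPE_ATC = "QI01AD02"

BATH_KEPT_PRODUCT = "061902"      # immersion vaccine reported in ml (kept)
BATH_EXCLUDED_PRODUCT = "480101"  # immersion vaccine reported in doses (excluded)

#: Years each injectable product appears in the register stream; mirrors the
#: observed reporting pattern so yearly product mixes are plausible and the
#: survivor stream spans 21 injectable IDs (+ one bath product kept in ml).
PRODUCT_YEARS: dict[str, tuple[int, ...]] = {
    "130772": tuple(range(2016, 2023)),
    "101148": tuple(range(2016, 2023)),
    "101159": tuple(range(2016, 2023)),
    "027475": tuple(range(2016, 2023)),
    "027464": tuple(range(2016, 2023)),
    "560340": tuple(range(2016, 2023)),
    "193107": tuple(range(2016, 2022)),
    "130519": tuple(range(2016, 2022)),
    "515591": tuple(range(2016, 2022)),
    "169401": (2016, 2017),
    "130420": (2016,),
    "099126": (2017,),
    "034501": tuple(range(2017, 2023)),
    "034490": (2017, 2018, 2019, 2021, 2022),
    "189864": (2018, 2020, 2021),
    "556139": tuple(range(2020, 2023)),
    "465067": tuple(range(2020, 2023)),
    "090235": tuple(range(2020, 2023)),
    "472689": tuple(range(2020, 2023)),
    "429437": (2021, 2022),
    "167812": (2022,),
}

SEPARATE_RECORD_CLASSES = (
    "practitioner_notification",
    "bath_dose_unit",
    "g_mass_correctable",
    "kg_mass_correctable",
    "mass_uncorrectable",
    "ml_to_stk_swap",
    "stk_to_ml_swap",
    "out_of_scope_atc",
    "out_of_window_year",
)
CORRUPTION_CLASSES = ("animal_count_inconsistent", "off_target_species", "unknown_location")
ALL_CLASSES = SEPARATE_RECORD_CLASSES + CORRUPTION_CLASSES


@dataclass
class DefectCounts:
    """Planted defect counts for one simulated year."""

    practitioner_notification: int = 0
    bath_dose_unit: int = 0
    g_mass_correctable: int = 0
    kg_mass_correctable: int = 0
    mass_uncorrectable: int = 0
    ml_to_stk_swap: int = 0
    stk_to_ml_swap: int = 0
    animal_count_inconsistent: int = 0
    off_target_species: int = 0
    unknown_location: int = 0
    out_of_scope_atc: int = 0
    out_of_window_year: int = 0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"negative defect count for {name}")


@dataclass
class YearPlan:
    """Record composition of one simulated delivery year.

    ``n_stk``/``n_ml`` are the clean injectable records reported in doses
    and in ml; ``n_bath_ml`` are clean bath-vaccine records reported in ml
    (kept through cleansing). ``bath_excluded_061902`` routes that many of
    the bath-dose defects to the second bath product.
    """

    year: int
    n_stk: int
    n_ml: int
    n_bath_ml: int = 0
    bath_excluded_061902: int = 0
    defects: DefectCounts = field(default_factory=DefectCounts)

    @property
    def n_plain(self) -> int:
        return self.n_stk + self.n_ml


@dataclass
class GeneratorConfig:
    seed: int
    plans: list[YearPlan]
    multi_vaccine_rate: float = 0.25
    multi_inconsistency_weight: float = 2.2
    sales_policy: str = "equal_to_use"  # equal_to_use | scaled | independent
    sales_scale: float = 1.0
    izovac_decoys: bool = True
    pharmacy_ids: tuple[str, ...] = ("PHA", "PHB", "PHC", "PHD")
    pharmacy_weights: tuple[float, ...] = (0.531, 0.462, 0.004, 0.003)
    #: geometric success probabilities per pharmacy; medians ~10 and ~3 days
    #: for the two dominant reporters, echoing the observed two-pharmacy
    #: asymmetry without claiming its values.
    pharmacy_delay_p: tuple[float, ...] = (0.065, 0.20, 0.065, 0.20)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        if not self.plans:
            raise ValueError("at least one year plan required")
        if self.sales_policy not in ("equal_to_use", "scaled", "independent"):
            raise ValueError(f"unknown sales policy {self.sales_policy!r}")
        if not 0 <= self.multi_vaccine_rate <= 1:
            raise ValueError("multi_vaccine_rate must be in [0, 1]")
        for plan in self.plans:
            d = plan.defects
            if plan.n_stk < 0 or plan.n_ml < 0 or plan.n_bath_ml < 0:
                raise ValueError(f"negative record count in year {plan.year}")
            if plan.bath_excluded_061902 > d.bath_dose_unit:
                raise ValueError("bath_excluded_061902 exceeds bath_dose_unit count")
            n_corrupt = (
                d.animal_count_inconsistent + d.off_target_species + d.unknown_location
            )
            if n_corrupt > plan.n_plain:
                raise ValueError(
                    f"year {plan.year}: planted defects exceed available records"
                )


@dataclass
class GroundTruth:
    """Planted bookkeeping: per-class totals, per-record labels, true volumes."""

    totals: dict[str, int]
    per_year: dict[int, dict[str, int]]
    labels: dict[int, str]
    use_ml: dict[tuple[str, int], float]
    n_records: int
    stk_clean_conversions: int  # clean dose-unit records (routine stk->ml)


@dataclass
class SyntheticDataset:
    records: list[PrescriptionRecord]
    sales: list[WholesaleRecord]
    truth: GroundTruth
    config: GeneratorConfig


def injection_products_for_year(year: int) -> list[str]:
    avail = [pid for pid, years in PRODUCT_YEARS.items() if year in years]
    if not avail:  # out-of-window years fall back to the ever-available mix
        avail = [pid for pid, years in PRODUCT_YEARS.items() if len(years) == 7]
    return sorted(avail)


@dataclass
class _Spec:
    """Internal pre-record: everything but dates and pharmacy."""

    label: str
    year: int
    product_id: str
    atc_code: str
    product_name: str
    quantity: float
    unit: str
    species: str
    n_animals: int | None
    location: str | None
    report_type: ReportType = ReportType.PHARMACY_DELIVERY
    report_group: int | None = None  # shared prescription grouping
    weight: float | None = None
    delivery_year: int | None = None  # override (out-of-window plants)


def generate(
    config: GeneratorConfig,
    products: ProductRegistry | None = None,
    locations: LocationRegistry | None = None,
) -> SyntheticDataset:
    """Generate prescription records, sales records and ground truth."""
    config.validate()
    registry = products if products is not None else load_product_registry()
    locreg = locations if locations is not None else load_locations()
    loc_pool = sorted(locreg.valid_locations)
    unknown_loc = next(c for c in ("99999", "99998", "00001") if c not in locreg)

    ss = np.random.SeedSequence(config.seed)
    r_rec, r_def, r_delay, r_sales = (np.random.default_rng(c) for c in ss.spawn(4))

    specs: list[_Spec] = []
    group_counter = 0
    # out-of-window plants are delivered the year before the earliest plan
    # year, which lies outside any window that starts at that year
    pre_window_year = min(p.year for p in config.plans) - 1

    for plan in sorted(config.plans, key=lambda p: p.year):
        year = plan.year
        avail = injection_products_for_year(year)
        d = plan.defects

        def clean_spec(rng: np.random.Generator, product_id: str | None = None) -> _Spec:
            pid = product_id if product_id is not None else str(rng.choice(avail))
            prod = registry.get(pid)
            n = int(rng.integers(2_000, 90_001))
            return _Spec(
                label="clean",
                year=year,
                product_id=pid,
                atc_code=prod.atc_code,
                product_name=prod.vaccine_name,
                quantity=float(n),  # provisional; unit assigned below
                unit="stk",
                species=str(rng.choice(TARGET_SPECIES, p=(0.80, 0.15, 0.05))),
                n_animals=n,
                location=str(rng.choice(loc_pool)),
                weight=round(float(rng.uniform(10.0, 60.0)), 1)
                if rng.random() < 0.7
                else None,
            )

        # -- plain clean injectable records; cycle the availability list so
        #    every product of the year appears among the survivors.
        plain: list[_Spec] = []
        for i in range(plan.n_plain):
            pid = avail[i % len(avail)] if i < len(avail) else None
            plain.append(clean_spec(r_rec, pid))
        units = np.array(["stk"] * plan.n_stk + ["ml"] * plan.n_ml)
        r_rec.shuffle(units)
        for spec, unit in zip(plain, units):
            if unit == "ml":
                dose = registry.get(spec.product_id).dose_ml
                spec.unit = "ml"
                spec.quantity = spec.n_animals * dose

        # -- multi-vaccine prescriptions: pair distinct-product records.
        n_pairs = int(config.multi_vaccine_rate * plan.n_plain / 2)
        order = r_rec.permutation(plan.n_plain)
        paired = np.zeros(plan.n_plain, dtype=bool)
        made = 0
        i = 0
        while made < n_pairs and i + 1 < plan.n_plain:
            first, second = order[i], order[i + 1]
            if plain[first].product_id != plain[second].product_id:
                group_counter += 1
                plain[first].report_group = group_counter
                plain[second].report_group = group_counter
                paired[[first, second]] = True
                made += 1
                i += 2
            else:
                i += 1

        # -- corruption classes: disjoint subsets of the plain records,
        #    inconsistency preferentially on multi-vaccine prescriptions.
        n_corrupt = d.animal_count_inconsistent + d.off_target_species + d.unknown_location
        if n_corrupt:
            weights = np.where(paired, config.multi_inconsistency_weight, 1.0)
            chosen = r_def.choice(
                plan.n_plain, size=n_corrupt, replace=False, p=weights / weights.sum()
            )
            split1 = d.animal_count_inconsistent
            split2 = split1 + d.off_target_species
            for idx in chosen[:split1]:
                _corrupt_animal_count(plain[idx], registry, r_def)
            for idx in chosen[split1:split2]:
                plain[idx].label = "off_target_species"
                plain[idx].species = str(r_def.choice(OFF_TARGET_SPECIES))
            for idx in chosen[split2:]:
                plain[idx].label = "unknown_location"
                plain[idx].location = unknown_loc
        specs.extend(plain)

        # -- clean bath records reported in ml (kept through cleansing).
        bath = registry.get(BATH_KEPT_PRODUCT)
        for _ in range(plan.n_bath_ml):
            volume = float(r_rec.integers(5, 31)) * 100.0
            specs.append(
                _Spec(
                    label="clean",
                    year=year,
                    product_id=bath.product_id,
                    atc_code=bath.atc_code,
                    product_name=bath.vaccine_name,
                    quantity=volume,
                    unit="ml",
                    species=str(r_rec.choice(TARGET_SPECIES, p=(0.80, 0.15, 0.05))),
                    n_animals=None,
                    location=str(r_rec.choice(loc_pool)),
                )
            )

        # -- separate-record defect classes.
        for _ in range(d.practitioner_notification):
            s = clean_spec(r_def)
            s.label = "practitioner_notification"
            s.report_type = ReportType.PRACTITIONER_USE
            specs.append(s)
        for k in range(d.bath_dose_unit):
            pid = (
                BATH_KEPT_PRODUCT
                if k < plan.bath_excluded_061902
                else BATH_EXCLUDED_PRODUCT
            )
            prod = registry.get(pid)
            specs.append(
                _Spec(
                    label="bath_dose_unit",
                    year=year,
                    product_id=pid,
                    atc_code=prod.atc_code,
                    product_name=prod.vaccine_name,
                    quantity=float(r_def.integers(100, 2_001)),
                    unit="stk",
                    species=str(r_def.choice(TARGET_SPECIES, p=(0.80, 0.15, 0.05))),
                    n_animals=int(r_def.integers(2_000, 90_001)),
                    location=str(r_def.choice(loc_pool)),
                )
            )
        for _ in range(d.g_mass_correctable):
            s = clean_spec(r_def)
            s.label = "g_mass_correctable"
            s.unit = "g"
            s.quantity = s.n_animals * registry.get(s.product_id).dose_ml  # true volume
            specs.append(s)
        for _ in range(d.kg_mass_correctable):
            s = clean_spec(r_def)
            s.label = "kg_mass_correctable"
            s.unit = "kg"
            s.quantity = s.n_animals * registry.get(s.product_id).dose_ml / 1000.0
            specs.append(s)
        for _ in range(d.mass_uncorrectable):
            s = clean_spec(r_def)
            s.label = "mass_uncorrectable"
            s.unit = "kg"
            s.quantity = float(r_def.integers(1, 10))
            dose = registry.get(s.product_id).dose_ml
            n = int(r_def.integers(1_000, 10_000))
            while abs(s.quantity * 1000.0 / dose - n) < 1 or n == int(s.quantity):
                n += 1
            s.n_animals = n
            specs.append(s)
        for _ in range(d.ml_to_stk_swap):
            s = clean_spec(r_def)
            s.label = "ml_to_stk_swap"
            s.unit = "ml"
            s.quantity = float(s.n_animals)  # doses miscoded as ml
            specs.append(s)
        for _ in range(d.stk_to_ml_swap):
            s = clean_spec(r_def)
            s.label = "stk_to_ml_swap"
            s.unit = "stk"
            s.quantity = s.n_animals * registry.get(s.product_id).dose_ml  # ml miscoded
            specs.append(s)
        for _ in range(d.out_of_scope_atc):
            s = clean_spec(r_def)
            s.label = "out_of_scope_atc"
            s.atc_code = OUT_OF_SCOPE_ATC
            specs.append(s)
        for _ in range(d.out_of_window_year):
            s = clean_spec(r_def)
            s.label = "out_of_window_year"
            s.delivery_year = pre_window_year
            specs.append(s)

    records = _materialize(specs, config, r_delay)
    truth = _bookkeep(specs, config, registry)
    sales = _make_sales(truth, config, registry, r_sales)
    return SyntheticDataset(records=records, sales=sales, truth=truth, config=config)


def _corrupt_animal_count(
    spec: _Spec, registry: ProductRegistry, rng: np.random.Generator
) -> None:
    """Shift n_animals away from the dose count without creating a swap match."""
    spec.label = "animal_count_inconsistent"
    prod = registry.get(spec.product_id)
    n = spec.n_animals
    delta = int(rng.integers(1, max(2, n // 10))) * int(rng.choice((-1, 1)))
    candidate = max(1, n + delta)
    doses_if_volume = spec.quantity / prod.dose_ml
    while (
        candidate == n
        or abs(candidate - spec.quantity) < 1  # would look like a label swap
        or abs(candidate - doses_if_volume) < 1
    ):
        candidate += 1
    spec.n_animals = candidate


def _materialize(
    specs: Sequence[_Spec], config: GeneratorConfig, rng: np.random.Generator
) -> list[PrescriptionRecord]:
    pharmacies = np.asarray(config.pharmacy_ids)
    weights = np.asarray(config.pharmacy_weights, dtype=float)
    weights = weights / weights.sum()
    delay_p = dict(zip(config.pharmacy_ids, config.pharmacy_delay_p))
    records = []
    for i, s in enumerate(specs):
        year = s.delivery_year if s.delivery_year is not None else s.year
        n_days = (date(year, 12, 31) - date(year, 1, 1)).days + 1
        delivery = date(year, 1, 1) + timedelta(days=int(rng.integers(0, n_days)))
        pharmacy = str(rng.choice(pharmacies, p=weights))
        delay = int(rng.geometric(delay_p[pharmacy])) - 1
        report_id = f"G{s.report_group:07d}" if s.report_group else f"R{i:07d}"
        records.append(
            PrescriptionRecord(
                report_id=report_id,
                registration_date=delivery + timedelta(days=delay),
                delivery_date=delivery,
                report_type=s.report_type,
                product_id=s.product_id,
                atc_code=s.atc_code,
                product_name=s.product_name,
                quantity=s.quantity,
                quantity_unit=s.unit,
                species=s.species,
                n_animals=s.n_animals,
                weight=s.weight,
                owner_location=s.location,
                pharmacy_id=pharmacy,
                record_id=i,
            )
        )
    return records


def _canonical_volume(spec: _Spec, registry: ProductRegistry) -> float | None:
    """True volume in ml of a record that survives cleansing; None if excluded."""
    if spec.label in (
        "practitioner_notification",
        "bath_dose_unit",
        "mass_uncorrectable",
        "out_of_scope_atc",
        "out_of_window_year",
    ):
        return None
    prod = registry.get(spec.product_id)
    if spec.unit == "stk":
        if spec.label == "stk_to_ml_swap":
            return spec.quantity  # quantity was ml all along
        return spec.quantity * prod.dose_ml
    if spec.unit == "ml":
        if spec.label == "ml_to_stk_swap":
            return spec.quantity * prod.dose_ml  # quantity was doses
        return spec.quantity
    if spec.unit == "g":
        return spec.quantity
    if spec.unit == "kg":
        return spec.quantity * 1000.0
    if spec.unit == "l":
        return spec.quantity * 1000.0
    raise AssertionError(f"unhandled unit {spec.unit}")


def _bookkeep(
    specs: Sequence[_Spec], config: GeneratorConfig, registry: ProductRegistry
) -> GroundTruth:
    totals: dict[str, int] = {c: 0 for c in ALL_CLASSES}
    totals["clean"] = 0
    per_year: dict[int, dict[str, int]] = {}
    labels: dict[int, str] = {}
    use: dict[tuple[str, int], float] = {}
    stk_clean = 0
    for i, s in enumerate(specs):
        labels[i] = s.label
        totals[s.label] += 1
        year_bucket = per_year.setdefault(s.year, {c: 0 for c in ALL_CLASSES} | {"clean": 0})
        year_bucket[s.label] += 1
        if s.unit == "stk" and s.label in (
            "clean",
            "animal_count_inconsistent",
            "off_target_species",
            "unknown_location",
        ) and registry.get(s.product_id).admin_type is AdminType.INJECTION:
            stk_clean += 1
        volume = _canonical_volume(s, registry)
        if volume is not None:
            key = (s.product_id, s.year)
            use[key] = use.get(key, 0.0) + volume
    return GroundTruth(
        totals=totals,
        per_year=per_year,
        labels=labels,
        use_ml=use,
        n_records=len(specs),
        stk_clean_conversions=stk_clean,
    )


def _make_sales(
    truth: GroundTruth,
    config: GeneratorConfig,
    registry: ProductRegistry,
    rng: np.random.Generator,
) -> list[WholesaleRecord]:
    sales: list[WholesaleRecord] = []
    for (pid, year), use_ml in sorted(truth.use_ml.items()):
        prod = registry.get(pid)
        if config.sales_policy == "independent":
            n_packs = int(rng.poisson(use_ml / prod.pack_size_ml))
            pack = prod.pack_size_ml
        else:
            scale = config.sales_scale if config.sales_policy == "scaled" else 1.0
            pack = use_ml * scale
            n_packs = 1
        sales.append(
            WholesaleRecord(
                year=year,
                atc_code=prod.atc_code,
                product_id=pid,
                vaccine_name=prod.vaccine_name,
                pack_size_ml=pack,
                n_packs=n_packs,
                marketed=True,
            )
        )
    if config.izovac_decoys:
        for year in sorted({y for (_, y) in truth.use_ml}):
            sales.append(
                WholesaleRecord(
                    year=year,
                    atc_code="QI10AB04",  # deliberately miscoded in the source
                    product_id="999999",
                    vaccine_name="IZOVAC ENCEPHALOMYELITS",
                    pack_size_ml=1000.0,
                    n_packs=int(rng.integers(1, 5)),
                    marketed=False,
                )
            )
    return sales


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write records.csv, sales.csv and truth.json; byte-stable per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "sales": outdir / "sales.csv",
        "truth": outdir / "truth.json",
    }
    write_prescriptions(dataset.records, paths["records"])
    write_wholesale(dataset.sales, paths["sales"])
    truth = dataset.truth
    payload = {
        "seed": dataset.config.seed,
        "sales_policy": dataset.config.sales_policy,
        "sales_scale": dataset.config.sales_scale,
        "n_records": truth.n_records,
        "stk_clean_conversions": truth.stk_clean_conversions,
        "totals": truth.totals,
        "per_year": {str(y): c for y, c in sorted(truth.per_year.items())},
        "labels": {str(k): v for k, v in truth.labels.items()},
        "use_ml": {f"{pid}:{year}": v for (pid, year), v in sorted(truth.use_ml.items())},
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Packaged profiles

#: Per-year census of the replication profile, 2016–2022. Columns:
#: (practitioner, bath-dose excl, excl-061902 share, uncorrectable, g->ml,
#:  kg->L, ml->stk swap, stk->ml swap, clean dose-unit, clean ml-unit,
#:  clean bath-ml). Clean splits are chosen so the routine dose->ml
#: conversions total 3,129 (allocated across years by largest remainder
#: in proportion to each year's clean-record count).
_TABLE3_YEARS: dict[int, tuple[int, int, int, int, int, int, int, int, int, int, int]] = {
    2016: (3, 7, 2, 0, 0, 0, 5, 0, 327, 373, 0),
    2017: (0, 79, 2, 0, 0, 0, 9, 0, 398, 453, 0),
    2018: (1, 144, 0, 0, 0, 0, 3, 0, 427, 485, 0),
    2019: (2, 257, 0, 0, 1, 3, 10, 1, 344, 392, 0),
    2020: (0, 114, 0, 0, 0, 0, 0, 1, 493, 560, 4),
    2021: (2, 33, 0, 1, 0, 0, 3, 1, 579, 659, 5),
    2022: (4, 50, 0, 2, 1, 0, 2, 0, 561, 639, 5),
}

#: Animal-count inconsistency planted per year: 31% of evaluable records.
_TABLE3_INCONSISTENT = {
    2016: 219,
    2017: 267,
    2018: 284,
    2019: 233,
    2020: 327,
    2021: 385,
    2022: 373,
}

_TABLE3_OFF_TARGET = {2016: 1, 2017: 1, 2018: 1, 2019: 1, 2020: 0, 2021: 1, 2022: 1}


def table3_profile(seed: int = 20160101) -> GeneratorConfig:
    """The packaged replication profile of the 2016–2022 cleansing census.

    Every planted count is deterministic: the per-class totals are
    7,443 in-scope records, 12 practitioner notifications, 684 bath-dose
    exclusions, 3 uncorrectable mass-unit records, 5 correctable mass-unit
    records (2 g→ml, 3 kg→L), 35 label-swap corrections (32 ml→stk,
    3 stk→ml) and 6,744 completeness survivors, regardless of the seed.
    A handful of out-of-scope records (10 foreign-ATC, 10 out-of-window)
    exercise the scope filter without entering the census.
    """
    plans = []
    for year, row in sorted(_TABLE3_YEARS.items()):
        (vet, bath, bath061, unc, g, kg, mlstk, stkml, n_stk, n_ml, n_bath_ml) = row
        plans.append(
            YearPlan(
                year=year,
                n_stk=n_stk,
                n_ml=n_ml,
                n_bath_ml=n_bath_ml,
                bath_excluded_061902=bath061,
                defects=DefectCounts(
                    practitioner_notification=vet,
                    bath_dose_unit=bath,
                    mass_uncorrectable=unc,
                    g_mass_correctable=g,
                    kg_mass_correctable=kg,
                    ml_to_stk_swap=mlstk,
                    stk_to_ml_swap=stkml,
                    animal_count_inconsistent=_TABLE3_INCONSISTENT[year],
                    off_target_species=_TABLE3_OFF_TARGET[year],
                    out_of_scope_atc=10 if year == 2019 else 0,
                    out_of_window_year=10 if year == 2016 else 0,
                ),
            )
        )
    return GeneratorConfig(seed=seed, plans=plans)


def simple_config(
    seed: int,
    n_records: int,
    defects: DefectCounts | None = None,
    years: tuple[int, int] = (2016, 2022),
    stk_fraction: float = 0.5,
    n_bath_ml: int = 0,
    sales_policy: str = "equal_to_use",
    sales_scale: float = 1.0,
    multi_vaccine_rate: float = 0.25,
) -> GeneratorConfig:
    """Build a generator config by spreading totals evenly across years.

    ``n_records`` counts every generated record, defect plants included.
    Defect counts are distributed over the years round-robin; clean
    records absorb the remainder. Raises when the requested defects
    exceed the record budget.
    """
    defects = defects or DefectCounts()
    year_list = list(range(years[0], years[1] + 1))
    n_years = len(year_list)
    base, extra = divmod(n_records, n_years)
    year_totals = {y: base + (1 if i < extra else 0) for i, y in enumerate(year_list)}

    per_year_defects = {y: DefectCounts() for y in year_list}
    for cls in ALL_CLASSES:
        count = getattr(defects, cls)
        for j in range(count):
            y = year_list[j % n_years]
            setattr(per_year_defects[y], cls, getattr(per_year_defects[y], cls) + 1)

    plans = []
    for y in year_list:
        d = per_year_defects[y]
        separate = sum(getattr(d, cls) for cls in SEPARATE_RECORD_CLASSES)
        bath_ml = min(n_bath_ml, year_totals[y])  # small, same in every year
        plain = year_totals[y] - separate - bath_ml
        if plain < 0:
            raise ValueError(f"year {y}: planted defects exceed record budget")
        n_stk = int(round(stk_fraction * plain))
        plans.append(
            YearPlan(
                year=y,
                n_stk=n_stk,
                n_ml=plain - n_stk,
                n_bath_ml=bath_ml,
                defects=d,
            )
        )
    config = GeneratorConfig(
        seed=seed,
        plans=plans,
        sales_policy=sales_policy,
        sales_scale=sales_scale,
        multi_vaccine_rate=multi_vaccine_rate,
    )
    config.validate()
    return config
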