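"""Unit harmonization, dose computation, and record-level validity checks.

The cleansing cascade brings every record to a canonical volume in ml so
register usage can be compared with wholesaler sales. For injectable
vaccines every product is given as one dose per fish, so the reported
number of animals serves as an internal reference: it lets mass-unit
records (g/kg) be reinterpreted as volume or dose counts, and it exposes
records whose ml/dose labels were swapped at entry.

Rule order (fixed): duplicate removal happens upstream in ingest; here a
record flows through mass-unit inference -> bath-dose exclusion -> routine
dose-to-ml conversion -> swap detection -> consistency flagging. A record
receives at most one correction, and corrections and exclusions are
mutually exclusive.

"Exact match" in every cross-check means integer equality after rounding
the computed dose count to the nearest integer, with an absolute tolerance
(default 1e-6) that only absorbs binary floating-point noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import (
    AdminType,
    AnimalConsistency,
    AuthorizationFlag,
    Correction,
    Disposition,
    ExclusionReason,
    HarmonizedRecord,
    LocationFlag,
    LocationRegistry,
    PrescriptionRecord,
    ProductInfo,
    ProductRegistry,
    SpeciesFlag,
    UnitFlag,
)

DEFAULT_TOLERANCE = 1e-6
DEFAULT_SPECIES_TARGETS = ("Atlantic salmon", "Rainbow trout", "Brown trout")
DEFAULT_ENTRY_ERROR_THRESHOLD = 100_000


def _matches(candidate: float, target: int | None, tol: float = DEFAULT_TOLERANCE) -> bool:
    """True when a computed count equals an integer target exactly."""
    if target is None:
        return False
    return abs(candidate - target) <= tol


def _excluded(
    record: PrescriptionRecord,
    reason: ExclusionReason,
    unit_flag: UnitFlag = UnitFlag.UNCORRECTABLE,
) -> HarmonizedRecord:
    return HarmonizedRecord(
        record=record,
        volume_ml=None,
        n_doses=None,
        disposition=Disposition.EXCLUDED,
        exclusion_reason=reason,
        unit_flag=unit_flag,
    )


def _resolved(
    record: PrescriptionRecord,
    product: ProductInfo,
    volume_ml: float,
    correction: Correction,
) -> HarmonizedRecord:
    n_doses = None
    if product.admin_type is AdminType.INJECTION:
        n_doses = volume_ml / product.dose_ml
    corrected = correction is not Correction.NONE
    return HarmonizedRecord(
        record=record,
        volume_ml=volume_ml,
        n_doses=n_doses,
        disposition=Disposition.CORRECTED if corrected else Disposition.KEPT,
        correction=correction,
        unit_flag=UnitFlag.CORRECTED if corrected else UnitFlag.OK,
    )


def harmonize_unit(
    record: PrescriptionRecord,
    products: ProductRegistry,
    tol: float = DEFAULT_TOLERANCE,
    bath_pack_multiple_inference: bool = True,
) -> HarmonizedRecord:
    """Run one record through the full unit-harmonization cascade.

    Never raises for data problems: unresolvable products, unrecognized
    units and failed inferences all become excluded dispositions with a
    reason, so batch conservation (kept + corrected + excluded = input)
    holds by construction.
    """
    product = products.get(record.product_id)
    if product is None or not record.unit_recognized:
        return _excluded(
            record, ExclusionReason.UNCORRECTABLE_UNIT, unit_flag=UnitFlag.UNRECOGNIZED
        )
    unit = record.quantity_unit
    if unit in ("g", "kg"):
        return infer_mass_unit(
            record, products, tol=tol, bath_pack_multiple_inference=bath_pack_multiple_inference
        )
    if unit == "stk":
        if product.admin_type is AdminType.BATH:
            # Dose counts for immersion vaccines cannot be converted to
            # volume: the number of fish per preparation varies.
            return _excluded(record, ExclusionReason.BATH_DOSE_UNIT)
        swap = detect_unit_swap(record, products, tol=tol)
        if swap is not None:
            return swap
        return _resolved(record, product, record.quantity * product.dose_ml, Correction.STK_TO_ML)
    if unit == "ml":
        if product.admin_type is AdminType.INJECTION:
            swap = detect_unit_swap(record, products, tol=tol)
            if swap is not None:
                return swap
        return _resolved(record, product, record.quantity, Correction.NONE)
    if unit == "l":
        return _resolved(record, product, record.quantity * 1000.0, Correction.NONE)
    return _excluded(record, ExclusionReason.UNCORRECTABLE_UNIT, unit_flag=UnitFlag.UNRECOGNIZED)


def infer_mass_unit(
    record: PrescriptionRecord,
    products: ProductRegistry,
    tol: float = DEFAULT_TOLERANCE,
    bath_pack_multiple_inference: bool = True,
) -> HarmonizedRecord:
    """Reinterpret a g/kg record as the matching volume or dose unit.

    The volume assumption (g was ml; kg was L) is tested first: if the dose
    count computed from the assumed volume equals the reported number of
    animals, the unit is corrected. Failing that, the dose-count assumption
    (quantity was "stk") is tested the same way. Records matching neither,
    or lacking a number of animals, are excluded as uncorrectable.

    For bath products the animal cross-check is undefined (no per-fish
    dose); the volume assumption is accepted only when the assumed volume
    is an exact positive integer multiple of the pack size, and this branch
    can be disabled via ``bath_pack_multiple_inference``.
    """
    product = products.get(record.product_id)
    if product is None or record.quantity_unit not in ("g", "kg"):
        raise ValueError("infer_mass_unit requires a resolvable g/kg record")
    is_kg = record.quantity_unit == "kg"
    assumed_volume_ml = record.quantity * (1000.0 if is_kg else 1.0)
    volume_correction = Correction.KG_TO_L if is_kg else Correction.G_TO_ML

    if product.admin_type is AdminType.BATH:
        if bath_pack_multiple_inference and assumed_volume_ml > 0:
            n_packs = assumed_volume_ml / product.pack_size_ml
            if _matches(n_packs, round(n_packs), tol) and round(n_packs) >= 1:
                return _resolved(record, product, assumed_volume_ml, volume_correction)
        return _excluded(record, ExclusionReason.UNCORRECTABLE_UNIT)

    n = record.n_animals
    if n is not None:
        candidate_doses = assumed_volume_ml / product.dose_ml
        if _matches(candidate_doses, n, tol):
            return _resolved(record, product, assumed_volume_ml, volume_correction)
        if _matches(record.quantity, n, tol):
            return _resolved(record, product, record.quantity * product.dose_ml, Correction.MASS_TO_STK)
    return _excluded(record, ExclusionReason.UNCORRECTABLE_UNIT)


def detect_unit_swap(
    record: PrescriptionRecord,
    products: ProductRegistry,
    tol: float = DEFAULT_TOLERANCE,
) -> HarmonizedRecord | None:
    """Detect ml/dose label swaps for injectable records via animal counts.

    A record reported in ml whose quantity (read as a dose count) equals
    the number of animals — while the volume reading does not — was doses
    miscoded as ml (``ml_to_stk``). Symmetrically, a record reported in
    stk whose quantity divided by the dose volume equals the number of
    animals — while the plain dose-count reading does not — was ml
    miscoded as doses (``stk_to_ml_swap``). Returns ``None`` when no swap
    is detected (including whenever the number of animals is absent).
    """
    product = products.get(record.product_id)
    if (
        product is None
        or product.admin_type is not AdminType.INJECTION
        or record.n_animals is None
        or record.quantity_unit not in ("ml", "stk")
    ):
        return None
    n = record.n_animals
    doses_if_volume = record.quantity / product.dose_ml
    if record.quantity_unit == "ml":
        if not _matches(doses_if_volume, n, tol) and _matches(record.quantity, n, tol):
            return _resolved(record, product, record.quantity * product.dose_ml, Correction.ML_TO_STK)
    else:  # stk
        if not _matches(record.quantity, n, tol) and _matches(doses_if_volume, n, tol):
            return _resolved(record, product, record.quantity, Correction.STK_TO_ML_SWAP)
    return None


def compute_doses(harmonized: HarmonizedRecord, products: ProductRegistry) -> float | None:
    """Dose count of a harmonized record: canonical volume / dose volume.

    Bath products (and excluded records) return ``None``: their dose count
    is undefined. A registry entry claiming injection without a dose volume
    breaches the registry invariant and raises.
    """
    if harmonized.disposition is Disposition.EXCLUDED or harmonized.volume_ml is None:
        return None
    product = products.get(harmonized.record.product_id)
    if product is None or product.admin_type is AdminType.BATH:
        return None
    if product.dose_ml is None:
        raise ValueError(f"injection product {product.product_id} lacks a dose volume")
    return harmonized.volume_ml / product.dose_ml


# ---------------------------------------------------------------------------
# Record-level validity flags


def check_animal_consistency(
    harmonized: HarmonizedRecord, tol: float = DEFAULT_TOLERANCE
) -> AnimalConsistency:
    """One dose per fish: the dose count should equal the animal count."""
    n = harmonized.record.n_animals
    if harmonized.disposition is Disposition.EXCLUDED or harmonized.n_doses is None or n is None:
        return AnimalConsistency.NOT_EVALUABLE
    if _matches(harmonized.n_doses, n, tol):
        return AnimalConsistency.CONSISTENT
    return AnimalConsistency.INCONSISTENT


def check_species(
    record: PrescriptionRecord,
    targets: Iterable[str] = DEFAULT_SPECIES_TARGETS,
    large_count_threshold: int = DEFAULT_ENTRY_ERROR_THRESHOLD,
) -> SpeciesFlag:
    """Flag species outside the salmonid target set.

    Non-target species with an implausibly large animal count (dispensings
    of hundreds of thousands of doses against, say, ornamental fish) are
    flagged as probable entry errors rather than genuine off-label use.
    """
    target_keys = {t.strip().lower() for t in targets}
    if record.species.strip().lower() in target_keys:
        return SpeciesFlag.TARGET
    if record.n_animals is not None and record.n_animals >= large_count_threshold:
        return SpeciesFlag.PROBABLE_ENTRY_ERROR
    return SpeciesFlag.OFF_TARGET


def check_location(record: PrescriptionRecord, registry: LocationRegistry) -> LocationFlag:
    if record.owner_location is None:
        return LocationFlag.MISSING
    if record.owner_location in registry:
        return LocationFlag.VALID
    return LocationFlag.UNKNOWN_LOCATION


def check_authorization(
    record: PrescriptionRecord, products: ProductRegistry
) -> AuthorizationFlag:
    """Was the product authorized in the delivery year?

    "Outside" is a flag, never an exclusion: products can legally be
    imported under special license outside their authorization interval.
    """
    product = products.get(record.product_id)
    if product is None:
        return AuthorizationFlag.UNKNOWN
    return (
        AuthorizationFlag.WITHIN
        if product.authorized_in(record.year)
        else AuthorizationFlag.OUTSIDE
    )


@dataclass(slots=True)
class RecordAssessment:
    """A harmonized record together with its validity flags."""

    harmonized: HarmonizedRecord
    animal_consistency: AnimalConsistency
    species_flag: SpeciesFlag
    location_flag: LocationFlag
    authorization_flag: AuthorizationFlag

    @property
    def record(self) -> PrescriptionRecord:
        return self.harmonized.record


def assess_records(
    records: Sequence[PrescriptionRecord],
    products: ProductRegistry,
    locations: LocationRegistry,
    tol: float = DEFAULT_TOLERANCE,
    species_targets: Iterable[str] = DEFAULT_SPECIES_TARGETS,
    entry_error_threshold: int = DEFAULT_ENTRY_ERROR_THRESHOLD,
    bath_pack_multiple_inference: bool = True,
) -> list[RecordAssessment]:
    """Harmonize and flag a batch of pharmacy records."""
    targets = tuple(species_targets)
    out = []
    for rec in records:
        h = harmonize_unit(
            rec, products, tol=tol, bath_pack_multiple_inference=bath_pack_multiple_inference
        )
        out.append(
            RecordAssessment(
                harmonized=h,
                animal_consistency=check_animal_consistency(h, tol=tol),
                species_flag=check_species(rec, targets, entry_error_threshold),
                location_flag=check_location(rec, locations),
                authorization_flag=check_authorization(rec, products),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Multi-vaccine odds ratio


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 association between multi-vaccine report IDs and inconsistency.

    Cells: a = multi-vaccine & inconsistent, b = multi-vaccine & consistent,
    c = single-vaccine & inconsistent, d = single-vaccine & consistent.
    The odds ratio is ad/bc with a Haldane–Anscombe 0.5 added to every cell
    when any cell is zero; the 95% CI is Woolf's log-normal interval.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None


def odds_ratio_from_cells(
    a: int,
    b: int,
    c: int,
    d: int,
    confidence: float = 0.95,
    p_method: str | None = "fisher",
) -> OddsRatioResult:
    """Odds ratio with Woolf CI (and optional exact/chi-square p) for a 2x2 table."""
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("degenerate contingency table")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5  # Haldane–Anscombe adjustment
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_) - z * se)
    ci_high = math.exp(math.log(or_) + z * se)
    p: float | None
    if p_method == "fisher":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    elif p_method == "chi2":
        p = stats.chi2_contingency([[a, b], [c, d]], correction=False).pvalue
    elif p_method is None:
        p = None
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return OddsRatioResult(a, b, c, d, float(or_), ci_low, ci_high, p)


def multi_vaccine_odds_ratio(
    assessments: Sequence[RecordAssessment],
    confidence: float = 0.95,
    p_method: str = "fisher",
) -> OddsRatioResult:
    """Association between shared-prescription reporting and inconsistency.

    Exposure: the record's report ID is shared by at least two distinct
    product rows (one prescription covering several vaccines). Outcome:
    the animal-count consistency flag; non-evaluable records are excluded
    from the table.
    """
    products_by_report: dict[str, set[str]] = {}
    for asm in assessments:
        products_by_report.setdefault(asm.record.report_id, set()).add(asm.record.product_id)
    multi = {rid for rid, pids in products_by_report.items() if len(pids) >= 2}
    a = b = c = d = 0
    for asm in assessments:
        if asm.animal_consistency is AnimalConsistency.NOT_EVALUABLE:
            continue
        exposed = asm.record.report_id in multi
        inconsistent = asm.animal_consistency is AnimalConsistency.INCONSISTENT
        if exposed and inconsistent:
            a += 1
        elif exposed:
            b += 1
        elif inconsistent:
            c += 1
        else:
            d += 1
    return odds_ratio_from_cells(a, b, c, d, confidence=confidence, p_method=p_method)
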