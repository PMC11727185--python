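"""Unit harmonization cascade, validity flags, and the odds-ratio estimator."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetregqa.model import (
    AnimalConsistency,
    AuthorizationFlag,
    Correction,
    Disposition,
    ExclusionReason,
    LocationFlag,
    LocationRegistry,
    PrescriptionRecord,
    ReportType,
    SpeciesFlag,
    UnitFlag,
)
from vetregqa.validity import (
    OddsRatioResult,
    assess_records,
    check_animal_consistency,
    check_authorization,
    check_location,
    check_species,
    compute_doses,
    detect_unit_swap,
    harmonize_unit,
    infer_mass_unit,
    multi_vaccine_odds_ratio,
    odds_ratio_from_cells,
)


def rec(**kw) -> PrescriptionRecord:
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


class TestHarmonizeUnit:
    def test_dose_unit_converted_via_product_dose(self, registry):
        h = harmonize_unit(rec(quantity=10_000, quantity_unit="stk"), registry)
        assert h.volume_ml == pytest.approx(500.0)
        assert h.n_doses == pytest.approx(10_000)
        assert h.correction is Correction.STK_TO_ML
        assert h.disposition is Disposition.CORRECTED

    def test_bath_vaccine_in_doses_is_excluded(self, registry):
        h = harmonize_unit(
            rec(product_id="480101", quantity=200, quantity_unit="stk", n_animals=None),
            registry,
        )
        assert h.disposition is Disposition.EXCLUDED
        assert h.exclusion_reason is ExclusionReason.BATH_DOSE_UNIT
        assert h.volume_ml is None

    def test_ml_record_kept_unchanged(self, registry):
        h = harmonize_unit(
            rec(product_id="130772", quantity=500, quantity_unit="ml", n_animals=5_000),
            registry,
        )
        assert h.volume_ml == 500.0
        assert h.correction is Correction.NONE
        assert h.disposition is Disposition.KEPT

    def test_litres_scaled_to_ml(self, registry):
        h = harmonize_unit(
            rec(quantity=0.5, quantity_unit="l", n_animals=10_000), registry
        )
        assert h.volume_ml == pytest.approx(500.0)
        assert h.disposition is Disposition.KEPT

    def test_unknown_product_excluded_as_unrecognized(self, registry):
        h = harmonize_unit(rec(product_id="999999"), registry)
        assert h.disposition is Disposition.EXCLUDED
        assert h.unit_flag is UnitFlag.UNRECOGNIZED

    def test_unrecognized_unit_excluded(self, registry):
        h = harmonize_unit(
            rec(quantity_unit="bottles", unit_recognized=False), registry
        )
        assert h.exclusion_reason is ExclusionReason.UNCORRECTABLE_UNIT
        assert h.unit_flag is UnitFlag.UNRECOGNIZED

    def test_idempotent_on_clean_ml_record(self, registry):
        base = rec(product_id="130772", quantity=500, quantity_unit="ml", n_animals=5_000)
        first = harmonize_unit(base, registry)
        second = harmonize_unit(first.record, registry)
        assert first == second
        assert second.disposition is Disposition.KEPT


class TestMassUnitInference:
    def test_grams_matching_volume_assumption(self, registry):
        # 100 g read as 100 ml of a 0.05 ml/dose product = 2,000 doses
        h = infer_mass_unit(
            rec(product_id="034501", quantity=100, quantity_unit="g", n_animals=2_000),
            registry,
        )
        assert h.correction is Correction.G_TO_ML
        assert h.volume_ml == pytest.approx(100.0)
        assert h.n_doses == pytest.approx(2_000)

    def test_kg_matching_volume_assumption(self, registry):
        # 0.5 kg read as 0.5 L = 500 ml = 10,000 doses at 0.05 ml
        h = infer_mass_unit(
            rec(product_id="034501", quantity=0.5, quantity_unit="kg", n_animals=10_000),
            registry,
        )
        assert h.correction is Correction.KG_TO_L
        assert h.volume_ml == pytest.approx(500.0)

    def test_kg_matching_neither_assumption_excluded(self, registry):
        h = infer_mass_unit(
            rec(product_id="034501", quantity=100, quantity_unit="kg", n_animals=7),
            registry,
        )
        assert h.disposition is Disposition.EXCLUDED
        assert h.exclusion_reason is ExclusionReason.UNCORRECTABLE_UNIT

    def test_dose_count_assumption_tested_second(self, registry):
        # 1,500 "g" with 1,500 animals: volume reading gives 30,000 doses
        # (mismatch), dose-count reading matches exactly.
        h = infer_mass_unit(
            rec(product_id="034501", quantity=1_500, quantity_unit="g", n_animals=1_500),
            registry,
        )
        assert h.correction is Correction.MASS_TO_STK
        assert h.volume_ml == pytest.approx(75.0)

    def test_missing_animal_count_uncorrectable(self, registry):
        h = infer_mass_unit(
            rec(product_id="034501", quantity=100, quantity_unit="g", n_animals=None),
            registry,
        )
        assert h.exclusion_reason is ExclusionReason.UNCORRECTABLE_UNIT

    def test_bath_product_pack_multiple_rule(self, registry):
        # 2 kg on a 1,000 ml pack: exactly 2 packs -> accepted as litres
        good = infer_mass_unit(
            rec(product_id="480101", quantity=2, quantity_unit="kg", n_animals=None),
            registry,
        )
        assert good.correction is Correction.KG_TO_L
        assert good.volume_ml == pytest.approx(2_000.0)
        bad = infer_mass_unit(
            rec(product_id="480101", quantity=2.5, quantity_unit="kg", n_animals=None),
            registry,
        )
        assert bad.disposition is Disposition.EXCLUDED

    def test_bath_inference_can_be_disabled(self, registry):
        h = infer_mass_unit(
            rec(product_id="480101", quantity=2, quantity_unit="kg", n_animals=None),
            registry,
            bath_pack_multiple_inference=False,
        )
        assert h.disposition is Disposition.EXCLUDED


class TestSwapDetection:
    def test_doses_miscoded_as_ml(self, registry):
        # 20,000 "ml" with 20,000 animals: the volume reading gives 400,000
        # doses, but read as doses the quantity matches the animals exactly.
        h = detect_unit_swap(
            rec(quantity=20_000, quantity_unit="ml", n_animals=20_000), registry
        )
        assert h is not None
        assert h.correction is Correction.ML_TO_STK
        assert h.volume_ml == pytest.approx(1_000.0)
        assert h.n_doses == pytest.approx(20_000)

    def test_ml_miscoded_as_doses(self, registry):
        # 500 "stk" with 10,000 animals: 500 doses mismatch, but 500 ml
        # at 0.05 ml/dose is exactly 10,000 doses.
        h = detect_unit_swap(
            rec(quantity=500, quantity_unit="stk", n_animals=10_000), registry
        )
        assert h is not None
        assert h.correction is Correction.STK_TO_ML_SWAP
        assert h.volume_ml == pytest.approx(500.0)

    def test_consistent_record_untouched(self, registry):
        assert (
            detect_unit_swap(
                rec(quantity=500, quantity_unit="ml", n_animals=10_000), registry
            )
            is None
        )

    def test_no_animal_count_is_noop(self, registry):
        assert (
            detect_unit_swap(
                rec(quantity=20_000, quantity_unit="ml", n_animals=None), registry
            )
            is None
        )


class TestComputeDoses:
    @pytest.mark.parametrize(
        "product_id,volume,expected",
        [("130772", 500.0, 5_000), ("027464", 250.0, 5_000), ("130772", 0.0, 0)],
    )
    def test_examples(self, registry, product_id, volume, expected):
        h = harmonize_unit(
            rec(product_id=product_id, quantity=volume, quantity_unit="ml", n_animals=None),
            registry,
        )
        assert compute_doses(h, registry) == pytest.approx(expected)

    def test_bath_record_has_no_dose_count(self, registry):
        h = harmonize_unit(
            rec(product_id="061902", quantity=1_000, quantity_unit="ml", n_animals=None),
            registry,
        )
        assert compute_doses(h, registry) is None

    def test_agrees_with_repeated_addition_oracle(self, registry):
        rng = np.random.default_rng(3)
        product = registry.get("130772")  # 0.1 ml per dose
        for n in rng.integers(1, 1_000, size=20):
            volume = float(n) * product.dose_ml
            # oracle: count how many doses fit by repeated addition
            total, count = 0.0, 0
            while total < volume - 1e-9:
                total += product.dose_ml
                count += 1
            h = harmonize_unit(
                rec(product_id="130772", quantity=volume, quantity_unit="ml", n_animals=None),
                registry,
            )
            assert round(compute_doses(h, registry)) == count


class TestRecordFlags:
    def test_animal_consistency_levels(self, registry):
        consistent = harmonize_unit(rec(quantity=10_000, quantity_unit="stk"), registry)
        assert check_animal_consistency(consistent) is AnimalConsistency.CONSISTENT
        off = harmonize_unit(
            rec(quantity=488, quantity_unit="ml", n_animals=9_500), registry
        )
        assert check_animal_consistency(off) is AnimalConsistency.INCONSISTENT
        bath = harmonize_unit(
            rec(product_id="061902", quantity=1_000, quantity_unit="ml", n_animals=500),
            registry,
        )
        assert check_animal_consistency(bath) is AnimalConsistency.NOT_EVALUABLE
        missing = harmonize_unit(
            rec(quantity=500, quantity_unit="ml", n_animals=None), registry
        )
        assert check_animal_consistency(missing) is AnimalConsistency.NOT_EVALUABLE

    def test_species_flags(self):
        assert check_species(rec(species="Atlantic salmon")) is SpeciesFlag.TARGET
        assert (
            check_species(rec(species="Ornamental fish", n_animals=500_000))
            is SpeciesFlag.PROBABLE_ENTRY_ERROR
        )
        assert (
            check_species(rec(species="Cyclopterus", n_animals=300))
            is SpeciesFlag.OFF_TARGET
        )

    def test_location_flags(self):
        registry = LocationRegistry(frozenset({"12345"}))
        assert check_location(rec(owner_location="12345"), registry) is LocationFlag.VALID
        assert (
            check_location(rec(owner_location="99999"), registry)
            is LocationFlag.UNKNOWN_LOCATION
        )
        assert check_location(rec(owner_location=None), registry) is LocationFlag.MISSING

    def test_authorization_flags(self, registry):
        within = rec(
            product_id="472689",
            delivery_date=date(2020, 6, 1),
            registration_date=date(2020, 6, 8),
        )
        assert check_authorization(within, registry) is AuthorizationFlag.WITHIN
        before = rec(
            product_id="472689",
            delivery_date=date(2017, 6, 1),
            registration_date=date(2017, 6, 8),
        )
        assert check_authorization(before, registry) is AuthorizationFlag.OUTSIDE
        unknown = rec(product_id="999999")
        assert check_authorization(unknown, registry) is AuthorizationFlag.UNKNOWN


class TestBatchInvariants:
    def test_conservation_and_single_correction(self, registry, locations):
        from vetregqa.synthetic import DefectCounts, generate, simple_config

        config = simple_config(
            seed=11,
            n_records=400,
            defects=DefectCounts(
                bath_dose_unit=5,
                g_mass_correctable=2,
                kg_mass_correctable=2,
                mass_uncorrectable=2,
                ml_to_stk_swap=4,
                stk_to_ml_swap=3,
                animal_count_inconsistent=30,
            ),
        )
        dataset = generate(config)
        pharmacy = [
            r for r in dataset.records if r.report_type is ReportType.PHARMACY_DELIVERY
        ]
        assessments = assess_records(pharmacy, registry, locations)
        kept = corrected = excluded = 0
        for asm in assessments:
            h = asm.harmonized
            if h.disposition is Disposition.KEPT:
                kept += 1
                assert h.correction is Correction.NONE
            elif h.disposition is Disposition.CORRECTED:
                corrected += 1
                assert h.correction is not Correction.NONE
                assert h.exclusion_reason is ExclusionReason.NONE
            else:
                excluded += 1
                assert h.correction is Correction.NONE
                assert h.exclusion_reason is not ExclusionReason.NONE
        assert kept + corrected + excluded == len(pharmacy)


class TestOddsRatio:
    def test_brute_force_cells(self):
        r = odds_ratio_from_cells(30, 70, 20, 80)
        assert r.odds_ratio == pytest.approx((30 * 80) / (70 * 20), rel=1e-12)
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_symmetric_table_gives_unity(self):
        r = odds_ratio_from_cells(25, 25, 25, 25)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_haldane_adjustment_on_zero_cell(self):
        r = odds_ratio_from_cells(0, 10, 10, 10)
        expected = (0.5 * 10.5) / (10.5 * 10.5)
        assert r.odds_ratio == pytest.approx(expected, rel=1e-12)
        assert math.isfinite(r.ci_low) and math.isfinite(r.ci_high)

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            odds_ratio_from_cells(0, 0, 10, 10)

    def test_p_value_methods(self):
        fisher = odds_ratio_from_cells(30, 70, 20, 80, p_method="fisher")
        chi2 = odds_ratio_from_cells(30, 70, 20, 80, p_method="chi2")
        none = odds_ratio_from_cells(30, 70, 20, 80, p_method=None)
        assert 0 <= fisher.p_value <= 1 and 0 <= chi2.p_value <= 1
        assert none.p_value is None

    def test_exposure_definition_report_ids(self, registry, locations):
        records = [
            rec(report_id="A", product_id="027475", quantity=100, quantity_unit="stk",
                n_animals=100),
            rec(report_id="A", product_id="130772", quantity=100, quantity_unit="stk",
                n_animals=90),  # inconsistent, multi-vaccine
            rec(report_id="B", product_id="027475", quantity=100, quantity_unit="stk",
                n_animals=100),
            rec(report_id="C", product_id="027475", quantity=100, quantity_unit="stk",
                n_animals=80),  # inconsistent, single
        ]
        result = multi_vaccine_odds_ratio(assess_records(records, registry, locations))
        assert (result.a, result.b, result.c, result.d) == (1, 1, 1, 1)

    def test_null_simulation_log_or_unbiased(self):
        """Under independence, ln(OR) over replicates has mean ~ 0."""
        rng = np.random.default_rng(17)
        log_ors = []
        for _ in range(500):
            pe, po = rng.uniform(0.2, 0.5, size=2)
            probs = [pe * po, pe * (1 - po), (1 - pe) * po, (1 - pe) * (1 - po)]
            a, b, c, d = rng.multinomial(2_000, probs)
            r = odds_ratio_from_cells(int(a), int(b), int(c), int(d), p_method=None)
            log_ors.append(math.log(r.odds_ratio))
        mean = np.mean(log_ors)
        se = np.std(log_ors, ddof=1) / math.sqrt(len(log_ors))
        assert abs(mean) < 3 * se


@settings(max_examples=50, derandomize=True)
@given(
    n=st.integers(min_value=1, max_value=50_000),
    pid=st.sampled_from(["027475", "130772", "034501", "556139"]),
)
def test_clean_stk_records_always_consistent(n, pid):
    """A dose-unit record with matching animal count converts and stays consistent."""
    from vetregqa import load_product_registry

    registry = load_product_registry()
    h = harmonize_unit(
        rec(product_id=pid, quantity=float(n), quantity_unit="stk", n_animals=n), registry
    )
    assert h.disposition is Disposition.CORRECTED
    assert h.correction is Correction.STK_TO_ML
    assert check_animal_consistency(h) is AnimalConsistency.CONSISTENT
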