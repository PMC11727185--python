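"""End-to-end quality-report assembly: ingest -> validity -> completeness -> timeliness.

The pipeline's point is auditability: every input record ends up in the
cleansing log with its disposition, correction and validity flags, the
yearly ledger reconciles exactly (input = survivors + exclusions), and the
provenance block records input digests, configuration and seed so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .completeness import coverage, render_coverage
from .ingest import (
    ReaderConfig,
    ScopeConfig,
    filter_scope,
    read_prescriptions,
    read_wholesale,
    remove_practitioner_duplicates,
    write_rejects,
)
from .model import (
    AnimalConsistency,
    Correction,
    Disposition,
    ExclusionReason,
    load_locations,
    load_product_registry,
)
from .timeliness import compute_delays, quantile_curve, summarize_timeliness
from .validity import (
    DEFAULT_ENTRY_ERROR_THRESHOLD,
    DEFAULT_SPECIES_TARGETS,
    DEFAULT_TOLERANCE,
    OddsRatioResult,
    RecordAssessment,
    assess_records,
    multi_vaccine_odds_ratio,
)

TOTAL = "total"

LEDGER_COLUMNS = [
    "year",
    "total",
    "practitioner_removed",
    "bath_dose_excluded",
    "uncorrectable_excluded",
    "corrected_g_to_ml",
    "corrected_kg_to_l",
    "corrected_ml_to_stk",
    "corrected_stk_to_ml_swap",
    "corrected_mass_to_stk",
    "converted_stk_to_ml",
    "final",
]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place.

    The CLI never hard-codes a threshold; this object round-trips through
    YAML so a run's configuration can be archived with its outputs.
    """

    scope: ScopeConfig = field(default_factory=ScopeConfig)
    species_targets: tuple[str, ...] = DEFAULT_SPECIES_TARGETS
    entry_error_threshold: int = DEFAULT_ENTRY_ERROR_THRESHOLD
    tolerance: float = DEFAULT_TOLERANCE
    bath_pack_multiple_inference: bool = True
    or_p_method: str = "fisher"
    delimiter: str = ","
    decimal: str = "."

    def reader_config(self) -> ReaderConfig:
        return ReaderConfig(delimiter=self.delimiter, decimal=self.decimal)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scope"] = dataclasses.asdict(self.scope)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        scope_raw = raw.pop("scope", {})
        for key in ("atc_prefixes", "wholesale_exclusions"):
            if key in scope_raw:
                scope_raw[key] = tuple(scope_raw[key])
        if "species_targets" in raw:
            raw["species_targets"] = tuple(raw["species_targets"])
        return cls(scope=ScopeConfig(**scope_raw), **raw)


@dataclass
class QualityReport:
    """Assembled quality summary: ledger, flags, coverage, timeliness."""

    ledger: pd.DataFrame
    cleansing_log: pd.DataFrame
    flag_summary: dict[str, dict[str, int]]
    or_result: OddsRatioResult | None
    coverage_product: pd.DataFrame
    coverage_vaccine: pd.DataFrame
    timeliness: pd.DataFrame
    curves: dict[str, pd.DataFrame]
    scope_drop_counts: dict[str, int]
    n_rejected_rows: int
    n_invalid_delays: int
    n_weight_unitless: int
    survivor_product_ids: int
    inconsistent_share: float | None
    provenance: dict[str, Any]

    def ledger_total(self, column: str) -> int:
        row = self.ledger[self.ledger["year"] == TOTAL]
        return int(row[column].iloc[0])


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_cleansing_log(
    practitioners: Sequence, assessments: Sequence[RecordAssessment]
) -> pd.DataFrame:
    rows = []
    for rec in practitioners:
        rows.append(
            {
                "record_id": rec.record_id,
                "report_id": rec.report_id,
                "year": rec.year,
                "product_id": rec.product_id,
                "quantity": rec.quantity,
                "quantity_unit": rec.quantity_unit,
                "disposition": Disposition.EXCLUDED.value,
                "correction": Correction.NONE.value,
                "exclusion_reason": ExclusionReason.PRACTITIONER_DUPLICATE.value,
                "unit_flag": "",
                "volume_ml": None,
                "n_doses": None,
                "animal_consistency": AnimalConsistency.NOT_EVALUABLE.value,
                "species_flag": "",
                "location_flag": "",
                "authorization_flag": "",
            }
        )
    for asm in assessments:
        h = asm.harmonized
        rec = h.record
        rows.append(
            {
                "record_id": rec.record_id,
                "report_id": rec.report_id,
                "year": rec.year,
                "product_id": rec.product_id,
                "quantity": rec.quantity,
                "quantity_unit": rec.quantity_unit,
                "disposition": h.disposition.value,
                "correction": h.correction.value,
                "exclusion_reason": h.exclusion_reason.value,
                "unit_flag": h.unit_flag.value,
                "volume_ml": h.volume_ml,
                "n_doses": h.n_doses,
                "animal_consistency": asm.animal_consistency.value,
                "species_flag": asm.species_flag.value,
                "location_flag": asm.location_flag.value,
                "authorization_flag": asm.authorization_flag.value,
            }
        )
    return pd.DataFrame(rows)


def _build_ledger(log: pd.DataFrame) -> pd.DataFrame:
    """Yearly cleansing ledger (the published census layout) plus a total row."""

    def summarize(group: pd.DataFrame) -> dict[str, int]:
        n = len(group)
        excl = group["exclusion_reason"]
        corr = group["correction"]
        out = {
            "total": n,
            "practitioner_removed": int((excl == "practitioner_duplicate").sum()),
            "bath_dose_excluded": int((excl == "bath_dose_unit").sum()),
            "uncorrectable_excluded": int((excl == "uncorrectable_unit").sum()),
            "corrected_g_to_ml": int((corr == "g_to_ml").sum()),
            "corrected_kg_to_l": int((corr == "kg_to_l").sum()),
            "corrected_ml_to_stk": int((corr == "ml_to_stk").sum()),
            "corrected_stk_to_ml_swap": int((corr == "stk_to_ml_swap").sum()),
            "corrected_mass_to_stk": int((corr == "mass_to_stk").sum()),
            "converted_stk_to_ml": int((corr == "stk_to_ml").sum()),
        }
        out["final"] = int((group["disposition"] != "excluded").sum())
        return out

    rows = []
    for year, group in log.groupby("year"):
        rows.append({"year": str(year)} | summarize(group))
    rows.append({"year": TOTAL} | summarize(log))
    return pd.DataFrame(rows, columns=LEDGER_COLUMNS)


def _flag_summary(assessments: Sequence[RecordAssessment]) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {
        "disposition": {},
        "correction": {},
        "exclusion_reason": {},
        "unit_flag": {},
        "animal_consistency": {},
        "species_flag": {},
        "location_flag": {},
        "authorization_flag": {},
    }

    def bump(table: str, key: str) -> None:
        out[table][key] = out[table].get(key, 0) + 1

    for asm in assessments:
        bump("disposition", asm.harmonized.disposition.value)
        bump("correction", asm.harmonized.correction.value)
        bump("exclusion_reason", asm.harmonized.exclusion_reason.value)
        bump("unit_flag", asm.harmonized.unit_flag.value)
        bump("animal_consistency", asm.animal_consistency.value)
        bump("species_flag", asm.species_flag.value)
        bump("location_flag", asm.location_flag.value)
        bump("authorization_flag", asm.authorization_flag.value)
    return out


def run_pipeline(
    records_path: str | Path,
    sales_path: str | Path,
    products_path: str | Path | None = None,
    locations_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> QualityReport:
    """Execute the full quality assessment and optionally write all outputs.

    Raises (fail-closed, no partial outputs) when an input file is missing
    or structurally broken; per-row data problems become reject-log rows
    and validity flags instead.
    """
    cfg = config or PipelineConfig()
    for p in (records_path, sales_path):
        if not Path(p).is_file():
            raise FileNotFoundError(p)
    for p in (products_path, locations_path):
        if p is not None and not Path(p).is_file():
            raise FileNotFoundError(p)
    registry = load_product_registry(products_path)
    locations = load_locations(locations_path)
    reader_cfg = cfg.reader_config()

    records, rejects = read_prescriptions(records_path, reader_cfg)
    scoped = filter_scope(records, cfg.scope)
    pharmacy_records, practitioners = remove_practitioner_duplicates(scoped.kept)

    assessments = assess_records(
        pharmacy_records,
        registry,
        locations,
        tol=cfg.tolerance,
        species_targets=cfg.species_targets,
        entry_error_threshold=cfg.entry_error_threshold,
        bath_pack_multiple_inference=cfg.bath_pack_multiple_inference,
    )
    log = _build_cleansing_log(practitioners, assessments)
    ledger = _build_ledger(log)
    flag_summary = _flag_summary(assessments)

    try:
        or_result = multi_vaccine_odds_ratio(assessments, p_method=cfg.or_p_method)
    except ValueError:
        or_result = None

    evaluable = [
        a
        for a in assessments
        if a.animal_consistency is not AnimalConsistency.NOT_EVALUABLE
    ]
    inconsistent_share = (
        sum(a.animal_consistency is AnimalConsistency.INCONSISTENT for a in evaluable)
        / len(evaluable)
        if evaluable
        else None
    )

    sales, sales_log = read_wholesale(sales_path, cfg.scope, reader_cfg)
    cov_product = coverage(assessments, sales, registry, level="product_id")
    cov_vaccine = coverage(assessments, sales, registry, level="vaccine_name")

    survivors = [
        a for a in assessments if a.harmonized.disposition is not Disposition.EXCLUDED
    ]
    delay_records, invalid_delays = compute_delays([a.record for a in survivors])
    timeliness = summarize_timeliness(delay_records)
    curves = {}
    by_year: dict[int, list[int]] = {}
    for d in delay_records:
        by_year.setdefault(d.year, []).append(d.delay_days)
    for year, delays in sorted(by_year.items()):
        curves[str(year)] = quantile_curve(delays)

    provenance = {
        "software_version": __version__,
        "seed": seed,
        "config": cfg.to_dict(),
        "inputs": {
            "records": {"path": str(records_path), "sha256": _sha256(records_path)},
            "sales": {"path": str(sales_path), "sha256": _sha256(sales_path)},
        },
        "n_records_read": len(records),
        "n_rejected_rows": len(rejects),
        "scope_drop_counts": scoped.drop_counts,
        "wholesale_log": dataclasses.asdict(sales_log),
    }

    report = QualityReport(
        ledger=ledger,
        cleansing_log=log,
        flag_summary=flag_summary,
        or_result=or_result,
        coverage_product=cov_product,
        coverage_vaccine=cov_vaccine,
        timeliness=timeliness,
        curves=curves,
        scope_drop_counts=scoped.drop_counts,
        n_rejected_rows=len(rejects),
        n_invalid_delays=len(invalid_delays),
        n_weight_unitless=sum(r.weight is not None for r in pharmacy_records),
        survivor_product_ids=len({a.record.product_id for a in survivors}),
        inconsistent_share=inconsistent_share,
        provenance=provenance,
    )
    _verify_reconciliation(report)
    if outdir is not None:
        write_report(report, outdir, rejects=rejects)
    return report


def _verify_reconciliation(report: QualityReport) -> None:
    """Ledger must reconcile per year and in total: input = survivors + exclusions."""
    for _, row in report.ledger.iterrows():
        lhs = int(row["total"])
        rhs = (
            int(row["final"])
            + int(row["practitioner_removed"])
            + int(row["bath_dose_excluded"])
            + int(row["uncorrectable_excluded"])
        )
        if lhs != rhs:
            raise AssertionError(f"ledger does not reconcile for year {row['year']}")


def _or_dict(r: OddsRatioResult | None) -> dict[str, Any] | None:
    if r is None:
        return None
    return {
        "cells": {"a": r.a, "b": r.b, "c": r.c, "d": r.d},
        "odds_ratio": r.odds_ratio,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p_value": r.p_value,
    }


def write_report(report: QualityReport, outdir: str | Path, rejects=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.cleansing_log.to_csv(outdir / "cleansing_log.csv", index=False)
    render_coverage(report.coverage_product).to_csv(
        outdir / "coverage_product.csv", index=False
    )
    render_coverage(report.coverage_vaccine).to_csv(
        outdir / "coverage_vaccine.csv", index=False
    )
    report.timeliness.to_csv(outdir / "timeliness.csv", index=False)
    for stratum, curve in report.curves.items():
        curve.to_csv(outdir / f"curve_year_{stratum}.csv", index=False)
    if rejects is not None:
        write_rejects(rejects, outdir / "rejects.csv")
    validity_summary = {
        "flag_counts": report.flag_summary,
        "inconsistent_share": report.inconsistent_share,
        "odds_ratio": _or_dict(report.or_result),
        "n_weight_present_unitless": report.n_weight_unitless,
        "n_invalid_delays": report.n_invalid_delays,
    }
    with open(outdir / "validity_summary.json", "w", encoding="utf-8") as fh:
        json.dump(validity_summary, fh, indent=1, sort_keys=True)
    quality_summary = {
        "ledger": report.ledger.to_dict(orient="records"),
        "scope_drop_counts": report.scope_drop_counts,
        "n_rejected_rows": report.n_rejected_rows,
        "survivor_product_ids": report.survivor_product_ids,
        "validity": validity_summary,
        "provenance": report.provenance,
    }
    with open(outdir / "quality_summary.json", "w", encoding="utf-8") as fh:
        json.dump(quality_summary, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(summarize(report))


def summarize(report: QualityReport) -> str:
    """Human-readable attribute x issue summary of a quality report."""
    lines = ["Quality summary", "===============", "", "Cleansing ledger (per delivery year)"]
    lines.append(report.ledger.to_string(index=False))
    lines.append("")
    lines.append("Validity")
    unit_corrected = sum(
        n
        for k, n in report.flag_summary["correction"].items()
        if k in ("g_to_ml", "kg_to_l", "ml_to_stk", "stk_to_ml_swap", "mass_to_stk")
    )
    unit_uncorrectable = report.flag_summary["exclusion_reason"].get("uncorrectable_unit", 0)
    lines.append(f"  unit corrected (manual-edit classes): {unit_corrected}")
    lines.append(f"  unit uncorrectable (excluded):        {unit_uncorrectable}")
    cons = report.flag_summary["animal_consistency"]
    lines.append(
        "  animal count: "
        + ", ".join(f"{k}={v}" for k, v in sorted(cons.items()))
        + (
            f" (inconsistent share {report.inconsistent_share:.1%})"
            if report.inconsistent_share is not None
            else ""
        )
    )
    for table in ("species_flag", "location_flag", "authorization_flag"):
        counts = report.flag_summary[table]
        lines.append(f"  {table}: " + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    lines.append(f"  weight present but unitless: {report.n_weight_unitless}")
    if report.or_result is not None:
        r = report.or_result
        lines.append(
            f"  multi-vaccine odds ratio: {r.odds_ratio:.2f} "
            f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}, p={r.p_value:.3g})"
        )
    lines.append("")
    lines.append("Completeness (coverage status counts, product level)")
    status_counts = report.coverage_product["status"].value_counts().to_dict()
    lines.append("  " + ", ".join(f"{k}={v}" for k, v in sorted(status_counts.items())))
    lines.append("")
    lines.append("Timeliness (days to reach 50/75/95% of records)")
    tl = report.timeliness
    head = tl[tl["stratum_type"].isin(["overall", "year", "pharmacy"])]
    lines.append(head.to_string(index=False))
    lines.append("")
    lines.append(
        f"Provenance: version {report.provenance['software_version']}, "
        f"seed {report.provenance['seed']}, "
        f"config digest {_config_digest(report.provenance['config'])}"
    )
    return "\n".join(lines) + "\n"


def _config_digest(config_dict: dict[str, Any]) -> str:
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def check_outputs(outdir: str | Path) -> bool:
    """Re-verify ledger reconciliation of an existing output directory."""
    outdir = Path(outdir)
    with open(outdir / "quality_summary.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    log = pd.read_csv(outdir / "cleansing_log.csv")
    ledger = pd.DataFrame(summary["ledger"])
    recomputed = _build_ledger(log)
    recomputed["year"] = recomputed["year"].astype(str)
    ledger = ledger[LEDGER_COLUMNS].astype({c: int for c in LEDGER_COLUMNS[1:]})
    ledger["year"] = ledger["year"].astype(str)
    if not recomputed.reset_index(drop=True).equals(ledger.reset_index(drop=True)):
        raise AssertionError("cleansing log and stored ledger disagree")
    for _, row in ledger.iterrows():
        if int(row["total"]) != (
            int(row["final"])
            + int(row["practitioner_removed"])
            + int(row["bath_dose_excluded"])
            + int(row["uncorrectable_excluded"])
        ):
            raise AssertionError(f"ledger does not reconcile for year {row['year']}")
    return True
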