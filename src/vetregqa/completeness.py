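"""Coverage of register-reported usage against wholesaler sales.

Coverage is 100 x use / sales in ml for the same key and period, with
wholesaler sales as the reference standard: below 100 means less reported
use than sales, above 100 more. Both registers reduce to volume — sales as
pack size x number of packs, register usage as the harmonized canonical
volume — so the comparison is done in ml, never in rounded pack counts.

Name-level coverage pools numerators and denominators across the vaccine's
product IDs before dividing (a pooled ratio, not a mean of ratios); the
same pooling defines the "total" period across years. Year attribution is
by delivery year on the register side and reported sales year on the sales
side; the known one-year billing lag between the two is surfaced as-is.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    Disposition,
    ProductRegistry,
    WholesaleRecord,
    load_name_aliases,
    normalize_vaccine_name,
)
from .validity import RecordAssessment

TOTAL = "total"

STATUS_OK = "ok"
STATUS_NOT_IN_SALES = "not_in_sales"
STATUS_NOT_IN_USE = "not_in_use"
STATUS_ABSENT = "absent"


def expand_sales(sales: Iterable[WholesaleRecord]) -> pd.DataFrame:
    """Sales volume in ml per (product_id, year): sum of pack_size x n_packs.

    Raises for rows without a positive pack size — volume is unrecoverable
    without it. Keys with zero packs are retained (0 ml sold is a datum).
    """
    rows = []
    for i, rec in enumerate(sales):
        if rec.pack_size_ml is None or rec.pack_size_ml <= 0:
            raise ValueError(f"sales row {i} ({rec.product_id}, {rec.year}): missing pack size")
        rows.append(
            {
                "product_id": rec.product_id,
                "vaccine_name": rec.vaccine_name,
                "year": rec.year,
                "sales_ml": rec.pack_size_ml * rec.n_packs,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["product_id", "vaccine_name", "year", "sales_ml"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["product_id", "year"], as_index=False)
        .agg(vaccine_name=("vaccine_name", "first"), sales_ml=("sales_ml", "sum"))
        [["product_id", "vaccine_name", "year", "sales_ml"]]
    )


def usage_volumes(assessments: Sequence[RecordAssessment]) -> pd.DataFrame:
    """Register usage in ml per (product_id, year) over non-excluded records."""
    rows = [
        {
            "product_id": asm.record.product_id,
            "year": asm.record.year,
            "use_ml": asm.harmonized.volume_ml,
        }
        for asm in assessments
        if asm.harmonized.disposition is not Disposition.EXCLUDED
        and asm.harmonized.volume_ml is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["product_id", "year", "use_ml"])
    return pd.DataFrame(rows).groupby(["product_id", "year"], as_index=False)["use_ml"].sum()


def _status(use: float, sales: float) -> str:
    if use > 0 and sales > 0:
        return STATUS_OK
    if use > 0:
        return STATUS_NOT_IN_SALES
    if sales > 0:
        return STATUS_NOT_IN_USE
    return STATUS_ABSENT


def _name_key(
    product_id: str,
    fallback_name: str,
    products: ProductRegistry | None,
    aliases: Mapping[str, str],
) -> str:
    product = products.get(product_id) if products is not None else None
    name = product.vaccine_name if product is not None else fallback_name
    return normalize_vaccine_name(name, aliases)


def coverage(
    assessments: Sequence[RecordAssessment],
    sales: Iterable[WholesaleRecord],
    products: ProductRegistry | None = None,
    level: str = "product_id",
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Coverage table per key and year plus a pooled "total" row per key.

    ``level`` is ``"product_id"`` or ``"vaccine_name"``. Name keys are
    normalized through the alias table (packaged default) after resolving
    the registry name for known product IDs, so that reports filed under a
    wrong pack-size product ID still pool under the right vaccine.
    ``coverage_pct`` is NaN where sales are zero; the ``status`` column
    carries the degenerate cases. Values are full precision — rounding to
    two decimals is presentation-only.
    """
    if level not in ("product_id", "vaccine_name"):
        raise ValueError(f"unknown coverage level {level!r}")
    if aliases is None:
        aliases = load_name_aliases()
    use = usage_volumes(assessments)
    sold = expand_sales(sales)
    if level == "vaccine_name":
        use = use.assign(
            key=[_name_key(pid, pid, products, aliases) for pid in use["product_id"]]
        )
        sold = sold.assign(
            key=[
                _name_key(pid, name, products, aliases)
                for pid, name in zip(sold["product_id"], sold["vaccine_name"])
            ]
        )
    else:
        use = use.assign(key=use["product_id"])
        sold = sold.assign(key=sold["product_id"])
    use = use.groupby(["key", "year"], as_index=False)["use_ml"].sum()
    sold = sold.groupby(["key", "year"], as_index=False)["sales_ml"].sum()
    merged = use.merge(sold, on=["key", "year"], how="outer")
    for col in ("use_ml", "sales_ml"):
        merged[col] = pd.to_numeric(merged[col], errors="coerce").fillna(0.0)
    totals = (
        merged.groupby("key", as_index=False)[["use_ml", "sales_ml"]].sum().assign(year=TOTAL)
    )
    cells = pd.concat([merged, totals], ignore_index=True)
    cells["coverage_pct"] = 100.0 * cells["use_ml"].where(cells["sales_ml"] > 0) / cells[
        "sales_ml"
    ].where(cells["sales_ml"] > 0)
    cells["status"] = [
        _status(u, s) for u, s in zip(cells["use_ml"], cells["sales_ml"])
    ]
    cells["year"] = cells["year"].astype(str)
    order = cells["year"].where(cells["year"] != TOTAL, "9999")
    cells = (
        cells.assign(_order=order)
        .sort_values(["key", "_order"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return cells[["key", "year", "use_ml", "sales_ml", "coverage_pct", "status"]]


def render_coverage(cells: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy with volumes and coverage rounded to 2 decimals."""
    out = cells.copy()
    for col in ("use_ml", "sales_ml", "coverage_pct"):
        out[col] = out[col].round(2)
    return out
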