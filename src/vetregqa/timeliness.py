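"""Reporting delay: empirical quantiles and ECDF curves per stratum.

The delay of a record is the whole-day difference between registration and
delivery. Quantiles use the inverse-ECDF (left-continuous step) convention
with no interpolation, so a reported "time to reach q" is always an
observed integer number of days: the smallest d with ECDF(d) >= q.
Registrations predating delivery are data errors, not fast reporting;
they are diverted to an invalid list and never enter quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import PrescriptionRecord

DEFAULT_QUANTILES = (0.50, 0.75, 0.95)


@dataclass(slots=True, frozen=True)
class DelayRecord:
    record_id: int
    delay_days: int
    year: int
    pharmacy_id: str


def compute_delays(
    records: Sequence[PrescriptionRecord],
) -> tuple[list[DelayRecord], list[tuple[PrescriptionRecord, str]]]:
    """Delay in whole days per record; negative delays go to the invalid list."""
    valid: list[DelayRecord] = []
    invalid: list[tuple[PrescriptionRecord, str]] = []
    for rec in records:
        delay = (rec.registration_date - rec.delivery_date).days
        if delay < 0:
            invalid.append((rec, "registration precedes delivery"))
        else:
            valid.append(
                DelayRecord(
                    record_id=rec.record_id,
                    delay_days=delay,
                    year=rec.year,
                    pharmacy_id=rec.pharmacy_id,
                )
            )
    return valid, invalid


def time_to_quantile(delays: Iterable[int], q: float) -> int:
    """Smallest delay d such that at least a fraction q of records have delay <= d."""
    values = np.sort(np.asarray(list(delays), dtype=np.int64))
    if values.size == 0:
        raise ValueError("empty stratum")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    index = math.ceil(q * values.size) - 1
    return int(values[index])


def quantile_curve(delays: Iterable[int]) -> pd.DataFrame:
    """ECDF table over the observed support: (days, percent reported <= days).

    Monotone nondecreasing and terminating at exactly 100%.
    """
    values = np.asarray(list(delays), dtype=np.int64)
    if values.size == 0:
        raise ValueError("empty stratum")
    days, counts = np.unique(values, return_counts=True)
    percent = 100.0 * np.cumsum(counts) / values.size
    return pd.DataFrame({"days": days, "percent": percent})


def summarize_timeliness(
    delay_records: Sequence[DelayRecord],
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
) -> pd.DataFrame:
    """Quantile summary overall and stratified by year, pharmacy, and both."""
    if not delay_records:
        return pd.DataFrame(
            columns=["stratum_type", "stratum", "n"]
            + [f"q{int(q * 100)}_days" for q in quantiles]
        )
    df = pd.DataFrame(
        {
            "delay": [d.delay_days for d in delay_records],
            "year": [d.year for d in delay_records],
            "pharmacy": [d.pharmacy_id for d in delay_records],
        }
    )
    strata: list[tuple[str, str, pd.Series]] = [("overall", "all", df["delay"])]
    for year, grp in df.groupby("year"):
        strata.append(("year", str(year), grp["delay"]))
    for pharm, grp in df.groupby("pharmacy"):
        strata.append(("pharmacy", str(pharm), grp["delay"]))
    for (year, pharm), grp in df.groupby(["year", "pharmacy"]):
        strata.append(("year_pharmacy", f"{year}:{pharm}", grp["delay"]))
    rows = []
    for stratum_type, stratum, delays in strata:
        row = {"stratum_type": stratum_type, "stratum": stratum, "n": int(delays.size)}
        for q in quantiles:
            row[f"q{int(q * 100)}_days"] = time_to_quantile(delays, q)
        rows.append(row)
    return pd.DataFrame(rows)
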