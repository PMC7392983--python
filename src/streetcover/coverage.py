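"""Availability, image-age, and image-age-variance summaries at each level.

Image age is measured in whole months before a reference year-month
(default April 2019).  Standard deviations use the n-1 denominator; values
are kept at full precision internally and rounded only when reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedUnitError

REF_YEAR = 2019
REF_MONTH = 4


@dataclass(frozen=True)
class CoverageSummary:
    unit_id: str
    n_points: int
    n_available: int
    availability_pct: float
    mean_age_months: float | None
    sd_age_months: float | None


def image_age_months(
    capture_year: int,
    capture_month: int,
    ref_year: int = REF_YEAR,
    ref_month: int = REF_MONTH,
) -> int:
    """Whole months between a capture year-month and the reference year-month."""
    for name, month in (("capture_month", capture_month), ("ref_month", ref_month)):
        if not 1 <= int(month) <= 12:
            raise InvalidInputError(f"{name} must be in 1..12, got {month}")
    age = (int(ref_year) - int(capture_year)) * 12 + (int(ref_month) - int(capture_month))
    if age < 0:
        raise InvalidInputError(
            f"capture date {capture_year}-{capture_month:02d} is after the "
            f"reference {ref_year}-{ref_month:02d}"
        )
    return age


def summarize_unit(unit_frame: pd.DataFrame, unit_id: str = "") -> CoverageSummary:
    """Coverage summary of one unit's audited points (ERROR rows removed)."""
    n_points = len(unit_frame)
    if n_points == 0:
        raise UndefinedUnitError(f"unit {unit_id!r} has no audited points")
    avail = unit_frame[unit_frame["available"].astype(bool)]
    n_available = len(avail)
    ages = avail["age_months"].astype(float).to_numpy()
    mean_age = float(np.mean(ages)) if n_available >= 1 else None
    sd_age = float(np.std(ages, ddof=1)) if n_available >= 2 else None
    return CoverageSummary(
        unit_id=unit_id,
        n_points=n_points,
        n_available=n_available,
        availability_pct=100.0 * n_available / n_points,
        mean_age_months=mean_age,
        sd_age_months=sd_age,
    )


_LEVEL_KEYS = {"subcity": "subcity_id", "city": "city_id", "country": "country"}


def aggregate_coverage(frame: pd.DataFrame, level: str = "subcity") -> pd.DataFrame:
    """Per-unit coverage summaries at the subcity, city, or country level.

    Expects an audited frame already restricted to complete cases
    (``analysis_ok``); rows with a null grouping key are dropped.
    """
    try:
        key = _LEVEL_KEYS[level]
    except KeyError:
        raise InvalidInputError(f"unknown level {level!r}") from None
    if "analysis_ok" in frame.columns:
        frame = frame[frame["analysis_ok"].astype(bool)]
    frame = frame[frame[key].notna()]
    rows = []
    for unit_id, grp in frame.groupby(key, sort=True):
        s = summarize_unit(grp, unit_id=str(unit_id))
        rows.append(
            {
                "unit_id": s.unit_id,
                "n_points": s.n_points,
                "n_available": s.n_available,
                "availability_pct": s.availability_pct,
                "mean_age_months": s.mean_age_months,
                "sd_age_months": s.sd_age_months,
            }
        )
    return pd.DataFrame(rows)


def availability_report(frame: pd.DataFrame) -> dict:
    """Overall availability counts with report-style rounded percentages.

    Percent available / unavailable are rounded to one decimal; the error
    rate is rounded to three decimals (it is typically far below 1%).
    """
    n = len(frame)
    n_ok = int(frame["available"].astype(bool).sum()) if n else 0
    n_err = (
        int((frame["status"] == "ERROR").sum()) if n and "status" in frame.columns else 0
    )
    n_zero = n - n_ok - n_err
    return {
        "n_total": n,
        "n_available": n_ok,
        "n_unavailable": n_zero,
        "n_error": n_err,
        "pct_available": round(100.0 * n_ok / n, 1) if n else 0.0,
        "pct_unavailable": round(100.0 * n_zero / n, 1) if n else 0.0,
        "pct_error": round(100.0 * n_err / n, 3) if n else 0.0,
    }
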