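"""Pandemic-year effort anomaly: monthly 2020 effort against the 2015–2019 baseline.

Weekly effort is rolled up to months (a week belongs to the month holding at
least 4 of its 7 days), and each 2020 month is expressed both as a percent
difference from the baseline mean ("+75%" means 75% higher than normal) and
as percent of normal (175 on the same inputs).  The baseline envelope is the
min–max range across the five pre-pandemic years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["monthly_totals", "percent_of_normal", "build_pandemic_summary"]

BASELINE_YEARS = (2015, 2016, 2017, 2018, 2019)
PANDEMIC_YEAR = 2020


def monthly_totals(weekly: pd.DataFrame, region: str, year: int) -> pd.Series:
    """Sum weekly effort into 12 monthly totals for one region-year.

    Requires the complete 52-week year; each week contributes to exactly one
    month (its majority-day label), so the 12 totals sum to the annual total.
    """
    sub = weekly[(weekly["region"] == region) & (weekly["year"] == year)]
    if len(sub) != 52:
        raise ValueError(
            f"region {region!r} year {year}: expected 52 weeks, found {len(sub)}")
    totals = sub.groupby("month")["effort"].sum()
    return totals.reindex(range(1, 13), fill_value=0.0)


def percent_of_normal(effort_2020: pd.Series, baselines: pd.DataFrame,
                      center: str = "mean") -> pd.DataFrame:
    """Monthly 2020 effort relative to the pre-pandemic baseline.

    ``effort_2020`` is a 12-long monthly series; ``baselines`` has one row per
    baseline year and one column per month (1..12).  The central value is the
    arithmetic mean across baseline years (configurable to the median); the
    envelope is the min/max.  ``pct_diff`` = 100*(E2020 - baseline)/baseline,
    ``pct_of_normal`` = 100*E2020/baseline.
    """
    missing = set(BASELINE_YEARS) - set(baselines.index)
    if missing:
        raise ValueError(f"baseline year(s) missing: {sorted(missing)}")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    rows = []
    for m in range(1, 13):
        base = baselines[m].astype(float)
        center_val = float(base.mean() if center == "mean" else base.median())
        if center_val == 0:
            raise ZeroDivisionError(
                f"baseline {center} effort is zero for month {m}; "
                "percent of normal is undefined")
        e20 = float(effort_2020[m])
        rows.append({
            "month": m, "effort_2020": e20,
            "baseline_mean": center_val,
            "baseline_min": float(base.min()), "baseline_max": float(base.max()),
            "pct_diff": 100.0 * (e20 - center_val) / center_val,
            "pct_of_normal": 100.0 * e20 / center_val,
        })
    return pd.DataFrame(rows)


def build_pandemic_summary(weekly: pd.DataFrame, regions=("east", "west"),
                           baseline_years=BASELINE_YEARS,
                           pandemic_year: int = PANDEMIC_YEAR,
                           center: str = "mean") -> pd.DataFrame:
    """24-row summary (2 regions x 12 months) of the pandemic-year anomaly."""
    frames = []
    for region in regions:
        e20 = monthly_totals(weekly, region, pandemic_year)
        base = pd.DataFrame(
            {m: {y: monthly_totals(weekly, region, y)[m] for y in baseline_years}
             for m in range(1, 13)})
        out = percent_of_normal(e20, base, center=center)
        out.insert(0, "region", region)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
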