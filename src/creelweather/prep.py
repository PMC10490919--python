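"""Data preparation: from daily weather and weekly effort to model-ready designs.

The pipeline implemented here mirrors how weekly creel-survey effort is paired
with weather in the source analyses: hourly regional weather is reduced to
daily summaries (max temperature, total precipitation, max wind), daily values
are aggregated to the survey week with *effort weights* (each day of the week
weighted by its historical share of fishing effort, ~70% falling on Fri–Sun),
coastal study areas are rolled up into east/west regions, confounded weeks are
removed (tropical-storm/hurricane-warning weeks, summer-holiday weeks, and the
2020 pandemic year), and the four predictors are standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical predictor order: precipitation (1), temperature (2), wind (3),
#: small-craft advisories (4)
PREDICTORS = ("ew_precip", "ew_tmax", "ew_windmax", "sca_count")
Z_COLUMNS = ("z_precip", "z_temp", "z_wind", "z_sca")

#: coastal study area -> region rollup; offshore effort cannot be attributed
#: to either region and is dropped.
AREA_TO_REGION = {
    "Pontchartrain": "east",
    "Barataria": "east",
    "Terrebonne/Timbalier": "east",
    "Vermilion/Teche": "west",
    "Calcasieu": "west",
}


# ---------------------------------------------------------------------------
# Effort weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffortWeights:
    """Share of weekly fishing effort on each day of the week (Mon..Sun).

    Defaults place 70% of the mass on Fri–Sun, matching the creel program's
    estimate that about 70% of effort takes place on the weekend (defined as
    Friday, Saturday and Sunday).
    """

    mon: float = 0.075
    tue: float = 0.075
    wed: float = 0.075
    thu: float = 0.075
    fri: float = 0.15
    sat: float = 0.30
    sun: float = 0.25

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0):
            raise ValueError("effort weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"effort weights must sum to 1, got {w.sum():.12f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mon, self.tue, self.wed, self.thu,
                         self.fri, self.sat, self.sun], dtype=float)

    @property
    def weekend_share(self) -> float:
        """Mass on Fri+Sat+Sun."""
        return self.fri + self.sat + self.sun


# ---------------------------------------------------------------------------
# Daily summarization and regional rollup
# ---------------------------------------------------------------------------

def daily_from_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Reduce an hourly table (hour, region, temp, precip, wind) to daily summaries.

    Per region-day: ``tmax`` = max temperature, ``precip_total`` = summed
    precipitation, ``wind_max`` = max wind.  Every day must have all 24 hours.
    """
    df = hourly.copy()
    ts = pd.to_datetime(df["hour"])
    df["date"] = ts.dt.normalize()
    counts = df.groupby(["region", "date"]).size()
    bad = counts[counts != 24]
    if len(bad):
        region, day = bad.index[0]
        raise ValueError(
            f"partial day in hourly table: {day.date()} ({region}) has "
            f"{bad.iloc[0]} of 24 hours"
        )
    out = (
        df.groupby(["region", "date"])
        .agg(tmax=("temp", "max"), precip_total=("precip", "sum"),
             wind_max=("wind", "max"))
        .reset_index()
    )
    return out


def aggregate_regions(effort_by_area: pd.DataFrame,
                      area_to_region: dict[str, str] | None = None) -> pd.DataFrame:
    """Roll up coastal-study-area effort into east/west regional weekly effort.

    Offshore rows are dropped (their region is ambiguous), as are charter rows
    if a ``mode`` column is present (only private recreational effort is
    analyzed).  Any other unmapped area label is an error.
    """
    mapping = AREA_TO_REGION if area_to_region is None else area_to_region
    df = effort_by_area.copy()
    if "mode" in df.columns:
        df = df[df["mode"] != "charter"]
    offshore = df["area"].str.lower() == "offshore"
    df = df[~offshore]
    unmapped = set(df["area"]) - set(mapping)
    if unmapped:
        raise ValueError(f"unmapped coastal study area(s): {sorted(unmapped)}")
    df["region"] = df["area"].map(mapping)
    keys = [c for c in ("year", "week_index", "monday") if c in df.columns]
    out = df.groupby(keys + ["region"], as_index=False)["effort"].sum()
    return out


# ---------------------------------------------------------------------------
# Effort-weighted weekly aggregation
# ---------------------------------------------------------------------------

def effort_weighted_week(daily_values, weights: EffortWeights) -> float:
    """Weighted mean of 7 ordered Mon–Sun daily values with the effort weights."""
    v = np.asarray(daily_values, dtype=float)
    if v.shape != (7,):
        raise ValueError(f"expected exactly 7 Mon–Sun values, got shape {v.shape}")
    if np.any(np.isnan(v)):
        missing = int(np.flatnonzero(np.isnan(v))[0])
        raise ValueError(f"missing day-of-week value at index {missing} (0=Mon)")
    return float(v @ weights.as_array())


def weekly_weather(daily: pd.DataFrame, calendar: pd.DataFrame,
                   weights: EffortWeights) -> pd.DataFrame:
    """Effort-weighted weekly summaries of the daily weather table.

    For every (region, calendar week) the 7 Mon–Sun daily values are combined
    with the day-of-week effort weights, yielding ``ew_tmax``, ``ew_precip``
    (effort-weighted average of daily precipitation totals) and ``ew_windmax``.
    """
    w = weights.as_array()
    rows = []
    for region, sub in daily.groupby("region"):
        sub = sub.set_index(pd.to_datetime(sub["date"]))
        for _, wk in calendar.iterrows():
            days = pd.date_range(wk["monday"], periods=7)
            try:
                block = sub.loc[days]
            except KeyError:
                raise ValueError(
                    f"daily weather missing day(s) in week starting "
                    f"{wk['monday'].date()} for region {region!r}"
                ) from None
            rows.append({
                "year": int(wk["year"]), "week_index": int(wk["week_index"]),
                "monday": wk["monday"], "month": int(wk["month"]),
                "region": region,
                "ew_tmax": float(block["tmax"].to_numpy() @ w),
                "ew_precip": float(block["precip_total"].to_numpy() @ w),
                "ew_windmax": float(block["wind_max"].to_numpy() @ w),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Warning-week realignment and exclusion filtering
# ---------------------------------------------------------------------------

def realign_warning_weeks(advisories: pd.DataFrame, storms) -> pd.DataFrame:
    """Move a lead-week tropical-storm/hurricane warning onto its landfall week.

    Warnings carry a ~36-hour lead, so a warning can be issued in the survey
    week before the week whose effort it affects.  For every storm, warning
    counts appearing in the week immediately before the landfall week (in the
    storm's impacted region) are reassigned to the landfall week.  Warning
    counts with no storm within ±1 week are logged and left in place.
    """
    adv = advisories.sort_values(["region", "monday"]).reset_index(drop=True)
    adv = adv.copy()
    landfall_weeks = {}
    for s in storms:
        lf = pd.Timestamp(s.landfall_date)
        monday = lf - pd.Timedelta(days=int(lf.weekday()))
        landfall_weeks[(s.impacted_region, monday)] = s.storm_id

    warn_cols = ["ts_warn_count", "hu_warn_count"]
    for i, row in adv.iterrows():
        if not any(row[c] > 0 for c in warn_cols):
            continue
        key_same = (row["region"], row["monday"])
        key_next = (row["region"], row["monday"] + pd.Timedelta(days=7))
        if key_same in landfall_weeks:
            continue  # already aligned
        if key_next in landfall_weeks:
            target = (adv["region"] == row["region"]) & (adv["monday"] == key_next[1])
            for c in warn_cols:
                adv.loc[target, c] = adv.loc[target, c] + row[c]
                adv.at[i, c] = 0
        else:
            logger.warning(
                "warning counts in week of %s (%s) have no storm landfall "
                "within +1 week; left in place", row["monday"].date(), row["region"]
            )
    return adv


def _holidays(year: int) -> list[date]:
    """Memorial Day (last Monday of May), July 4, Labor Day (first Monday of Sep)."""
    d = date(year, 5, 31)
    memorial = d - timedelta(days=d.weekday())
    d = date(year, 9, 1)
    labor = d + timedelta(days=(7 - d.weekday()) % 7)
    return [memorial, date(year, 7, 4), labor]


def is_holiday_week(monday: pd.Timestamp) -> bool:
    """True if the Mon–Sun span starting at ``monday`` contains a summer holiday."""
    start = monday.date()
    end = start + timedelta(days=6)
    for yr in {start.year, end.year}:
        for h in _holidays(yr):
            if start <= h <= end:
                return True
    return False


def exclusion_filter(records: pd.DataFrame,
                     pandemic_year: int = 2020) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove confounded weeks before the weather–effort model is fit.

    Dropped: weeks with any tropical-storm or hurricane warning, weeks whose
    Mon–Sun span contains Memorial Day / July 4 / Labor Day, and the entire
    pandemic year.  Returns ``(retained, audit)`` where the audit log lists
    region, year, week and the reason(s) for every dropped row.
    """
    df = records.copy()
    reasons = []
    for _, row in df.iterrows():
        r = []
        if row.get("ts_warn_count", 0) > 0 or row.get("hu_warn_count", 0) > 0:
            r.append("storm_warning")
        if is_holiday_week(row["monday"]):
            r.append("holiday_week")
        if int(row["year"]) == pandemic_year:
            r.append("pandemic_year")
        reasons.append(";".join(r))
    df["_drop_reason"] = reasons
    dropped = df[df["_drop_reason"] != ""]
    audit = dropped[["region", "year", "week_index", "monday", "_drop_reason"]].rename(
        columns={"_drop_reason": "reason"}).reset_index(drop=True)
    retained = df[df["_drop_reason"] == ""].drop(columns="_drop_reason")
    return retained.reset_index(drop=True), audit


# ---------------------------------------------------------------------------
# Assembly and standardization
# ---------------------------------------------------------------------------

def assemble_weekly_records(effort_region: pd.DataFrame, weekly_wx: pd.DataFrame,
                            advisories: pd.DataFrame) -> pd.DataFrame:
    """Join regional effort, effort-weighted weather and advisory counts.

    One row per (region, year, week_index): effort, ew_* covariates, advisory
    and warning counts, month label, and calendar flags.
    """
    keys = ["region", "year", "week_index"]
    wx = weekly_wx.copy()
    eff = effort_region.drop(columns=[c for c in ("monday", "month") if c in effort_region.columns])
    adv = advisories.drop(columns=[c for c in ("monday",) if c in advisories.columns])
    df = wx.merge(eff, on=keys, how="left", validate="one_to_one")
    df = df.merge(adv, on=keys, how="left", validate="one_to_one")
    if df["effort"].isna().any():
        bad = df[df["effort"].isna()].iloc[0]
        raise ValueError(
            f"no effort row for region={bad['region']!r} year={bad['year']} "
            f"week={bad['week_index']}"
        )
    for c in ("sca_count", "ts_warn_count", "hu_warn_count"):
        df[c] = pd.to_numeric(df[c], errors="coerce").fillna(0).astype(int)
    df["holiday_week"] = df["monday"].map(is_holiday_week)
    df["warning_week"] = (df["ts_warn_count"] > 0) | (df["hu_warn_count"] > 0)
    df["pandemic_year"] = df["year"] == 2020
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError("duplicate (region, year, week) rows after assembly")
    return df


@dataclass
class DesignTable:
    """Standardized per-region design for the weather–effort model.

    ``frame`` has columns log_effort, z_precip, z_temp, z_wind, z_sca, month;
    the centering means and scaling SDs (sample SD, ddof=1) are retained so
    effects can be mapped back to natural units.
    """

    frame: pd.DataFrame
    means: dict[str, float]
    sds: dict[str, float]
    region: str = ""
    log_base: str = "natural"

    @property
    def n(self) -> int:
        return len(self.frame)

    def scaling(self) -> pd.DataFrame:
        return pd.DataFrame({"predictor": list(self.means),
                             "mean": list(self.means.values()),
                             "sd": list(self.sds.values())})


def standardize(records: pd.DataFrame, region: str = "") -> DesignTable:
    """Log-transform effort and z-score the four predictors.

    Effort is natural-log transformed; each predictor is mean-centered and
    divided by its sample standard deviation (ddof=1).  A zero-variance
    predictor is an error naming the column.
    """
    df = records.copy()
    means, sds = {}, {}
    out = pd.DataFrame(index=df.index)
    out["log_effort"] = np.log(df["effort"].astype(float))
    for raw, z in zip(PREDICTORS, Z_COLUMNS):
        x = df[raw].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance predictor: {raw}")
        means[raw] = float(x.mean())
        sds[raw] = float(sd)
        out[z] = (x - means[raw]) / sd
    out["month"] = df["month"].astype(int)
    return DesignTable(frame=out.reset_index(drop=True), means=means, sds=sds,
                       region=region)


# ---------------------------------------------------------------------------
# Collinearity screen and post-hoc descriptives
# ---------------------------------------------------------------------------

def correlation_screen(records: pd.DataFrame):
    """Pairwise Pearson correlations among the four predictors.

    Returns ``(matrix, max_abs, pair)`` where ``pair`` names the predictor
    pair with the largest |off-diagonal| correlation.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    corr = records[list(PREDICTORS)].astype(float).corr(method="pearson")
    a = corr.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    i, j = np.unravel_index(np.abs(a).argmax(), a.shape)
    return corr, float(a[i, j]), (PREDICTORS[i], PREDICTORS[j])


def monthly_sd(records: pd.DataFrame, column: str, month: int) -> float:
    """Sample SD of ``column`` across weeks labeled with ``month``."""
    sub = records[records["month"] == month][column].astype(float)
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 rows for month {month}")
    return float(sub.std(ddof=1))


def conditional_r2(records: pd.DataFrame, x: str, y: str, threshold_col: str,
                   threshold: float, above: bool = True) -> float:
    """Squared Pearson correlation of ``x`` and ``y`` on a threshold subset."""
    mask = (records[threshold_col] >= threshold) if above else (records[threshold_col] < threshold)
    sub = records[mask]
    if len(sub) < 3:
        raise ValueError("threshold subset has fewer than 3 rows")
    r = np.corrcoef(sub[x].astype(float), sub[y].astype(float))[0, 1]
    return float(r * r)


def descriptive_stats(records: pd.DataFrame, column: str = "ew_tmax") -> pd.DataFrame:
    """Monthly sample SDs of a column (the post-hoc variability summary)."""
    rows = [{"month": m, "sd": monthly_sd(records, column, m)}
            for m in sorted(records["month"].unique())]
    return pd.DataFrame(rows)
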