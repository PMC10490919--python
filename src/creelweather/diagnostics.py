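"""Convergence diagnostics, interval summaries, and the end-to-end pipeline.

R-hat is the split-chain, rank-normalized potential-scale-reduction factor:
each chain is split in half, draws are rank-normalized (so the statistic is
robust to heavy tails and invariant under monotone transformations), and the
classic between/within variance ratio is computed on both the rank-normal
scores and their folded (|x - median|) counterparts, reporting the larger of
the two.  Values below 1.1 are taken to indicate convergence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "gelman_rubin", "credible_interval", "RhatReport", "rhat_report",
    "PipelineConfig", "run_pipeline", "ReportBundle",
]


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------

def _psrf(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor on an (M, N) draw array."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return np.nan
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, axis=None).reshape(x.shape)
    return ndtri((r - 0.375) / (x.size + 0.25))


def gelman_rubin(chains) -> float:
    """Split-chain rank-normalized R-hat for one parameter.

    ``chains`` is an (M, N) array of M >= 2 chains of N >= 4 draws.  Constant
    chains make the statistic undefined: a warning is emitted and NaN
    returned.  Deterministic given the draws.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains to compute R-hat")
    if n < 4:
        raise ValueError("need at least 4 draws per chain to split-chain R-hat")
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant chains: R-hat is undefined; returning NaN",
                      RuntimeWarning)
        return float("nan")
    half = n // 2
    split = np.vstack([x[:, :half], x[:, half:2 * half]])
    bulk = _psrf(_rank_normalize(split))
    folded = _psrf(_rank_normalize(np.abs(split - np.median(split))))
    vals = [v for v in (bulk, folded) if np.isfinite(v)]
    return float(max(vals)) if vals else float("nan")


def credible_interval(draws, level: float = 0.95):
    """Central credible interval from empirical quantiles (linear interpolation).

    Returns ``(lower, upper, excludes_zero)``.
    """
    d = np.asarray(draws, dtype=float).reshape(-1)
    if d.size == 0:
        raise ValueError("no draws supplied")
    if d.size < 2:
        raise ValueError("need at least 2 draws for an interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [a, 1.0 - a])
    return float(lo), float(hi), not (lo <= 0.0 <= hi)


@dataclass
class RhatReport:
    """Per-parameter R-hat values with the overall convergence verdict."""

    values: dict
    threshold: float = 1.1

    @property
    def max_rhat(self) -> float:
        finite = [v for v in self.values.values() if np.isfinite(v)]
        return float(max(finite)) if finite else float("nan")

    @property
    def converged(self) -> bool:
        return np.isfinite(self.max_rhat) and self.max_rhat < self.threshold

    def to_json(self, path) -> None:
        payload = {"max_rhat": self.max_rhat, "converged": self.converged,
                   "threshold": self.threshold,
                   "parameters": {k: (None if not np.isfinite(v) else float(v))
                                  for k, v in self.values.items()}}
        Path(path).write_text(json.dumps(payload, indent=1))


def rhat_report(posterior, threshold: float = 1.1) -> RhatReport:
    """Build an R-hat report from any posterior exposing ``scalar_draws()``."""
    values = {name: gelman_rubin(arr) for name, arr in posterior.scalar_draws()}
    return RhatReport(values=values, threshold=threshold)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Seeds, schedules and toggles for the end-to-end run."""

    seed: int = 1
    start_year: int = 2015
    end_year: int = 2021
    regions: tuple = ("east", "west")
    weather_chains: int = 3
    weather_iterations: int = 4000
    weather_burnin: int = 2000
    weather_thin: int = 1
    tc_chains: int = 3
    tc_iterations: int = 3000
    tc_burnin: int = 1000
    full_schedule: bool = False  # the published 3 x 100,000 / 30,000 / thin-2 run
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "regions" in data:
            data["regions"] = tuple(data["regions"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["regions"] = list(data["regions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def weather_spec(self):
        from .weather_model import WeatherModelSpec
        if self.full_schedule:
            return WeatherModelSpec.full_schedule()
        return WeatherModelSpec(chains=self.weather_chains,
                                iterations=self.weather_iterations,
                                burnin=self.weather_burnin,
                                thin=self.weather_thin)

    def tc_spec(self):
        from .tc_model import TCModelSpec
        return TCModelSpec(chains=self.tc_chains, iterations=self.tc_iterations,
                           burnin=self.tc_burnin)


@dataclass
class ReportBundle:
    """Everything a pipeline run produced, with file paths."""

    monthly_effects: pd.DataFrame
    temperature_trends: dict
    tc_slopes: pd.DataFrame
    tc_level2: pd.DataFrame
    pandemic: pd.DataFrame
    rhat_reports: dict
    audit: pd.DataFrame
    paths: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir) -> ReportBundle:
    """simulate -> prep -> fit weather (per region) -> fit TC -> pandemic -> report.

    Writes all tables as CSV, R-hat reports as JSON, and best-effort summary
    figures; every filter decision and seed is logged.
    """
    from . import prep, synth
    from .tc_model import build_tc_subset, fit_tc_model, classify_recovery
    from .weather_model import (build_weather_model, fit_weather_model,
                                summarize_monthly_effects,
                                temperature_month_trend)
    from .pandemic import build_pandemic_summary

    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("creelweather")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    paths: dict = {}
    stage = "configure"
    try:
        weather_spec = config.weather_spec()  # fails fast on a bad schedule
        tc_spec = config.tc_spec()
        logger.info("pipeline seed=%d years=%d-%d", config.seed,
                    config.start_year, config.end_year)

        stage = "simulate"
        ds = synth.simulate_dataset(config.seed, config.start_year,
                                    config.end_year)
        paths.update(synth.write_dataset(ds, out / "data"))

        stage = "prep"
        region_effort = prep.aggregate_regions(ds.effort_by_area)
        adv = prep.realign_warning_weeks(ds.advisories, ds.storms)
        records = prep.assemble_weekly_records(region_effort, ds.weekly_weather,
                                               adv)
        retained, audit = prep.exclusion_filter(records)
        audit.to_csv(out / "results" / "exclusion_audit.csv", index=False)
        logger.info("exclusion filter removed %d region-weeks", len(audit))

        stage = "fit-weather"
        effects, trends, rhat_reports = [], {}, {}
        seeds = np.random.default_rng(config.seed).integers(
            0, 2 ** 31 - 1, size=len(config.regions) + 1)
        for i, region in enumerate(config.regions):
            design = prep.standardize(
                retained[retained["region"] == region], region=region)
            corr, max_r, pair = prep.correlation_screen(
                retained[retained["region"] == region])
            logger.info("%s: max predictor correlation %.2f (%s vs %s)",
                        region, max_r, *pair)
            model = build_weather_model(design, weather_spec)
            post = fit_weather_model(model, weather_spec, seed=int(seeds[i]))
            rep = rhat_report(post)
            rep.to_json(out / "results" / f"rhat_{region}.json")
            rhat_reports[region] = rep
            effects.append(summarize_monthly_effects(post, region))
            trends[region] = temperature_month_trend(post)
            post.to_frame().to_csv(out / "results" / f"draws_{region}.csv.gz",
                                   index=False, compression="gzip")
        monthly_effects = pd.concat(effects, ignore_index=True)
        monthly_effects.to_csv(out / "results" / "monthly_effects.csv",
                               index=False)
        trend_rows = []
        for region, tr in trends.items():
            for g in ("gamma0", "gamma1"):
                trend_rows.append({"region": region, "parameter": g, **tr[g]})
        pd.DataFrame(trend_rows).to_csv(out / "results" / "temperature_trend.csv",
                                        index=False)

        stage = "fit-tc"
        subset = build_tc_subset(ds.effort, ds.storms, ds.advisories)
        tc_post = fit_tc_model(subset, tc_spec, seed=int(seeds[-1]))
        tc_slopes = classify_recovery(tc_post)
        tc_slopes.to_csv(out / "results" / "tc_slopes.csv", index=False)
        d0 = tc_post.draws["delta0"].reshape(-1)
        d1 = tc_post.draws["delta1"].reshape(-1)
        lvl2 = []
        for name, d in (("delta0", d0), ("delta1", d1)):
            lo, hi, excl = credible_interval(d)
            lvl2.append({"parameter": name, "mean": float(d.mean()),
                         "lower": lo, "upper": hi, "credible": excl})
        tc_level2 = pd.DataFrame(lvl2)
        tc_level2.to_csv(out / "results" / "tc_level2.csv", index=False)

        stage = "pandemic"
        pandemic = build_pandemic_summary(ds.effort, regions=config.regions)
        pandemic.to_csv(out / "results" / "pandemic_summary.csv", index=False)

        if config.make_plots:
            stage = "plots"
            (out / "figures").mkdir(exist_ok=True)
            _plot_monthly_effects(monthly_effects, trends,
                                  out / "figures" / "monthly_effects.png")
            _plot_tc(subset, tc_slopes, out / "figures" / "tc_recovery.png")
            _plot_pandemic(pandemic, out / "figures" / "pandemic.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return ReportBundle(monthly_effects=monthly_effects,
                        temperature_trends=trends, tc_slopes=tc_slopes,
                        tc_level2=tc_level2, pandemic=pandemic,
                        rhat_reports=rhat_reports, audit=audit, paths=paths)


# ---------------------------------------------------------------------------
# Best-effort figures (the CSV tables are the analysis surface)
# ---------------------------------------------------------------------------

def _agg_backend():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def _plot_monthly_effects(effects: pd.DataFrame, trends: dict, path) -> None:
    plt = _agg_backend()
    regions = effects["region"].unique()
    variables = effects["variable"].unique()
    fig, axes = plt.subplots(len(variables), len(regions), figsize=(9, 11),
                             sharex=True)
    axes = np.atleast_2d(axes)
    for a, var in enumerate(variables):
        for b, region in enumerate(regions):
            ax = axes[a, b]
            sub = effects[(effects["variable"] == var)
                          & (effects["region"] == region)]
            colors = np.where(sub["credible"], "firebrick", "steelblue")
            ax.vlines(sub["month"], sub["lower"], sub["upper"], colors=colors)
            ax.scatter(sub["month"], sub["mean"], c=colors, zorder=3, s=14)
            ax.axhline(0, lw=0.5, color="gray")
            if var == "temperature" and region in trends:
                line = trends[region]["line"]
                ax.plot(line["month"], line["mean"], color="black", lw=1)
            ax.set_title(f"{region} — {var}", fontsize=9)
    fig.supxlabel("month")
    fig.supylabel("standardized effect on log effort")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_tc(subset: pd.DataFrame, slopes: pd.DataFrame, path) -> None:
    plt = _agg_backend()
    fig, axes = plt.subplots(3, 4, figsize=(10, 7), sharex=True)
    for ax, (sid, grp) in zip(axes.ravel(), subset.groupby("storm_id", sort=False)):
        row = slopes[slopes["storm_id"] == sid].iloc[0]
        color = "firebrick" if row["significant_positive"] else "steelblue"
        ax.scatter(grp["relative_week"], grp["log_effort"], color="black", s=12)
        coef = np.polyfit(grp["relative_week"], grp["log_effort"], 1)
        xs = np.array([1, 5])
        ax.plot(xs, np.polyval(coef, xs), color=color)
        ax.set_title(f"{sid} (cat {row['category']})", fontsize=8)
    fig.supxlabel("relative week to landfall")
    fig.supylabel("log effort")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_pandemic(pandemic: pd.DataFrame, path) -> None:
    plt = _agg_backend()
    regions = pandemic["region"].unique()
    fig, axes = plt.subplots(1, len(regions), figsize=(10, 3.5), sharey=True)
    for ax, region in zip(np.atleast_1d(axes), regions):
        sub = pandemic[pandemic["region"] == region]
        colors = np.where(sub["pct_diff"] >= 0, "firebrick", "steelblue")
        ax.bar(sub["month"], sub["pct_diff"], color=colors)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_title(region)
        ax.set_xlabel("month")
    np.atleast_1d(axes)[0].set_ylabel("% difference from pre-pandemic mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
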