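"""Tropical-cyclone effort-recovery model.

For each storm that made landfall, the five survey weeks starting at landfall
(week 1 contains the landfall day) form a short recovery series.  Log effort
in the impacted region is modeled with a varying-intercepts / varying-slopes
regression on relative week (1–5), and the storm-specific recovery slopes are
regressed, at the second level, on storm severity (Saffir–Simpson category,
with 0 denoting a tropical storm):

    log E_{k,w} ~ Normal(a_k + b_k * w, sigma^2)
    a_k ~ Normal(mu_a, sigma_a^2)
    b_k ~ Normal(delta0 + delta1 * category_k, tau^2)

All location hyperparameters carry diffuse Normal(0, 100^2) priors; standard
deviations carry Uniform(0, 10) priors.  The conjugate structure is exploited
by a Gibbs sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mcmc import sample_mvn_prec, sample_trunc_invgamma_var

__all__ = [
    "StormEvent", "TCModelSpec", "TCPosterior",
    "build_tc_subset", "fit_tc_model", "classify_recovery", "per_storm_ols",
]


@dataclass(frozen=True)
class StormEvent:
    """A tropical cyclone that made landfall during the study period."""

    storm_id: str
    name: str
    landfall_date: pd.Timestamp
    category: int  # 0 = tropical storm, 1-5 = Saffir-Simpson at landfall
    impacted_region: str
    effect_scale: float = 1.0  # generative knob: scales the storm's effort effect

    def __post_init__(self) -> None:
        if not (0 <= int(self.category) <= 5):
            raise ValueError(f"category must be in 0..5, got {self.category}")
        object.__setattr__(self, "landfall_date", pd.Timestamp(self.landfall_date))

    @property
    def landfall_monday(self) -> pd.Timestamp:
        lf = self.landfall_date
        return lf - pd.Timedelta(days=int(lf.weekday()))


def storm_window_start(storm: StormEvent,
                       advisories: pd.DataFrame | None = None) -> pd.Timestamp:
    """Monday of recovery week 1 for a storm.

    Normally the landfall week.  Edge rule: when landfall falls early in its
    week (Mon/Tue) and the tropical-storm/hurricane warning was issued in the
    previous week (36-hour lead time), the window starts at the warning week —
    the impending landfall already suppressed that week's effort.
    """
    monday = storm.landfall_monday
    if advisories is None:
        return monday
    if int(storm.landfall_date.weekday()) > 1:
        return monday
    prev = monday - pd.Timedelta(days=7)
    sub = advisories[(advisories["region"] == storm.impacted_region)
                     & (advisories["monday"] == prev)]
    if len(sub) and (sub.iloc[0].get("ts_warn_count", 0) > 0
                     or sub.iloc[0].get("hu_warn_count", 0) > 0):
        return prev
    return monday


def build_tc_subset(effort: pd.DataFrame, storms,
                    advisories: pd.DataFrame | None = None) -> pd.DataFrame:
    """Five consecutive region-weeks of log effort per storm.

    ``effort`` is the UNfiltered regional weekly series (warning weeks must be
    present).  Relative week 1 starts at the landfall week, or at the warning
    week under the early-landfall edge rule (see :func:`storm_window_start`).
    """
    rows = []
    for s in storms:
        start = storm_window_start(s, advisories)
        sub = effort[effort["region"] == s.impacted_region]
        for w in range(5):
            monday = start + pd.Timedelta(days=7 * w)
            match = sub[sub["monday"] == monday]
            if len(match) != 1:
                raise ValueError(
                    f"storm {s.storm_id} ({s.name}): effort series lacks week "
                    f"starting {monday.date()} (need 5 weeks from {start.date()})"
                )
            rows.append({
                "storm_id": s.storm_id, "name": s.name, "category": int(s.category),
                "region": s.impacted_region, "relative_week": w + 1,
                "monday": monday,
                "log_effort": float(np.log(match.iloc[0]["effort"])),
            })
    return pd.DataFrame(rows)


@dataclass
class TCModelSpec:
    """MCMC schedule and priors for the recovery model."""

    chains: int = 3
    iterations: int = 3000
    burnin: int = 1000
    thin: int = 1
    prior_mean_sd: float = 100.0
    sd_upper: float = 10.0
    fix_delta1: bool = False

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @property
    def retained(self) -> int:
        return self.chains * ((self.iterations - self.burnin) // self.thin)


@dataclass
class TCPosterior:
    """Draws from the recovery model, with per-storm metadata."""

    storm_ids: list
    categories: np.ndarray
    draws: dict  # name -> (chains, kept[, n_storms]) arrays
    rhat: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.draws["sigma"].size)

    def slope_draws(self, k: int) -> np.ndarray:
        return self.draws["b"][..., k].reshape(-1)

    def scalar_draws(self):
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                yield name, arr
            else:
                for k, sid in enumerate(self.storm_ids):
                    yield f"{name}[{sid}]", arr[..., k]


def fit_tc_model(subset: pd.DataFrame, spec: TCModelSpec | None = None,
                 seed: int = 0) -> TCPosterior:
    """Gibbs sampler for the varying-intercepts/varying-slopes recovery model."""
    spec = spec or TCModelSpec()
    ids = list(dict.fromkeys(subset["storm_id"]))
    S = len(ids)
    cats = np.array([int(subset[subset["storm_id"] == sid]["category"].iloc[0])
                     for sid in ids], dtype=float)
    if len(np.unique(cats)) < 2 and not spec.fix_delta1:
        raise ValueError(
            "all storms share one severity category: the level-2 slope delta1 "
            "is unidentified — refit with spec.fix_delta1=True"
        )
    y = np.stack([subset[subset["storm_id"] == sid].sort_values("relative_week")
                  ["log_effort"].to_numpy() for sid in ids])  # (S, 5)
    if y.shape[1] != 5:
        raise ValueError("each storm needs exactly 5 relative weeks")
    w = np.arange(1.0, 6.0)
    X = np.column_stack([np.ones(5), w])
    XtX = X.T @ X
    Xty = X.T @ y.T  # (2, S), constant across iterations
    prior_prec_mean = 1.0 / spec.prior_mean_sd ** 2

    kept = (spec.iterations - spec.burnin) // spec.thin
    out = {
        "a": np.empty((spec.chains, kept, S)),
        "b": np.empty((spec.chains, kept, S)),
        "mu_a": np.empty((spec.chains, kept)),
        "delta0": np.empty((spec.chains, kept)),
        "delta1": np.empty((spec.chains, kept)),
        "tau": np.empty((spec.chains, kept)),
        "sigma_a": np.empty((spec.chains, kept)),
        "sigma": np.empty((spec.chains, kept)),
    }

    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(child)
        # Overdispersed initialization around per-storm least squares.
        ab = np.linalg.solve(XtX, X.T @ y.T).T  # (S, 2)
        a = ab[:, 0] + rng.normal(0, 0.5, S)
        b = ab[:, 1] + rng.normal(0, 0.2, S)
        mu_a, sig_a2 = float(a.mean()), 1.0
        d0, d1 = float(b.mean()), 0.0
        tau2 = 0.1
        sig2 = max(float(np.var(y - ab @ X.T)), 1e-3)
        j = 0
        for it in range(spec.iterations):
            # (a_k, b_k) joint bivariate conjugate update; the precision is
            # shared across storms, so one Cholesky serves all of them
            prior_mean_b = d0 + d1 * cats
            P0 = np.diag([1.0 / sig_a2, 1.0 / tau2])
            prec = P0 + XtX / sig2
            L = np.linalg.cholesky(prec)
            shifts = P0 @ np.vstack([np.full(S, mu_a), prior_mean_b]) + Xty / sig2
            tmp = np.linalg.solve(L, shifts)
            means = np.linalg.solve(L.T, tmp)
            ab = means + np.linalg.solve(L.T, rng.standard_normal((2, S)))
            a, b = ab[0].copy(), ab[1].copy()
            # intercept hyperparameters
            v = 1.0 / (S / sig_a2 + prior_prec_mean)
            mu_a = rng.normal(v * a.sum() / sig_a2, np.sqrt(v))
            sig_a2 = sample_trunc_invgamma_var((S - 1) / 2.0,
                                               float(((a - mu_a) ** 2).sum()) / 2.0,
                                               spec.sd_upper, rng)
            # level-2 regression of slopes on category
            if spec.fix_delta1:
                v = 1.0 / (S / tau2 + prior_prec_mean)
                d0 = rng.normal(v * b.sum() / tau2, np.sqrt(v))
                d1 = 0.0
            else:
                C = np.column_stack([np.ones(S), cats])
                prec = C.T @ C / tau2 + prior_prec_mean * np.eye(2)
                d0, d1 = sample_mvn_prec(prec, C.T @ b / tau2, rng)
            resid_b = b - d0 - d1 * cats
            tau2 = sample_trunc_invgamma_var((S - 1) / 2.0,
                                             float((resid_b ** 2).sum()) / 2.0,
                                             spec.sd_upper, rng)
            # residual variance
            resid = y - (a[:, None] + np.outer(b, w))
            sig2 = sample_trunc_invgamma_var((y.size - 1) / 2.0,
                                             float((resid ** 2).sum()) / 2.0,
                                             spec.sd_upper, rng)
            if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0:
                out["a"][c, j] = a
                out["b"][c, j] = b
                out["mu_a"][c, j] = mu_a
                out["delta0"][c, j] = d0
                out["delta1"][c, j] = d1
                out["tau"][c, j] = np.sqrt(tau2)
                out["sigma_a"][c, j] = np.sqrt(sig_a2)
                out["sigma"][c, j] = np.sqrt(sig2)
                j += 1

    post = TCPosterior(storm_ids=ids, categories=cats, draws=out)
    from .diagnostics import gelman_rubin
    skip = {"delta1", "tau"} if spec.fix_delta1 else set()
    for name, arr in post.scalar_draws():
        if name.split("[")[0] in skip:
            continue
        post.rhat[name] = gelman_rubin(arr)
    finite = [v for v in post.rhat.values() if np.isfinite(v)]
    if finite and max(finite) >= 1.1:
        warnings.warn(f"TC model: max R-hat {max(finite):.3f} >= 1.1; "
                      "chains may not have converged", UserWarning)
    return post


def classify_recovery(posterior: TCPosterior, level: float = 0.95) -> pd.DataFrame:
    """Per-storm recovery-slope summary with the significant-positive flag.

    A storm is flagged significant-positive iff its slope's central credible
    interval lies strictly above 0 (effort credibly increasing after landfall).
    """
    from .diagnostics import credible_interval
    rows = []
    for k, sid in enumerate(posterior.storm_ids):
        d = posterior.slope_draws(k)
        lo, hi, excl = credible_interval(d, level)
        rows.append({
            "storm_id": sid, "category": int(posterior.categories[k]),
            "slope_mean": float(d.mean()), "lower": lo, "upper": hi,
            "significant": excl, "significant_positive": lo > 0,
        })
    return pd.DataFrame(rows)


def per_storm_ols(subset: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Independent per-storm least-squares recovery fits (5 points each).

    Exposed alongside the hierarchical slopes: the partial-pooling estimates
    shrink extreme storms toward the population line, while these independent
    fits treat each storm on its own (classical t-based intervals).
    """
    rows = []
    for sid, grp in subset.groupby("storm_id", sort=False):
        g = grp.sort_values("relative_week")
        res = stats.linregress(g["relative_week"], g["log_effort"])
        tcrit = stats.t.ppf(0.5 + level / 2, df=len(g) - 2)
        half = tcrit * res.stderr
        rows.append({
            "storm_id": sid, "category": int(g["category"].iloc[0]),
            "slope": res.slope, "lower": res.slope - half,
            "upper": res.slope + half, "pvalue": res.pvalue,
            "significant_positive": res.slope - half > 0,
        })
    return pd.DataFrame(rows)
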