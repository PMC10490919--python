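"""Bayesian hierarchical weather–effort model.

Weekly log effort y_i in a region is regressed on four standardized weather
predictors — precipitation (k=1), maximum temperature (k=2), maximum wind
(k=3) and small-craft-advisory count (k=4) — with month-specific intercepts
and slopes:

    y_i ~ Normal(alpha_{j(i)} + sum_k beta_{j(i),k} z_{ik}, sigma^2)
    (beta_j1, ..., beta_j4) ~ MVN(mu_j, Sigma)
    mu_j = (mu_b1, gamma0 + gamma1 * z_month(j), mu_b3, mu_b4)
    alpha_j ~ Normal(mu_alpha, sigma_alpha^2)

so the temperature slope carries a second-level linear trend across the
calendar (z_month(j) = j - 6.5), while the other slopes share exchangeable
population means.  Sigma uses the scaled inverse-Wishart construction
(Sigma = Lambda Q Lambda with Q ~ IW(K+1, I) and free scale parameters
Lambda = diag(xi)); location hyperparameters carry Normal(0, 100^2) priors
and standard deviations Uniform(0, 10) priors.  Everything is conjugate, so
the posterior is sampled with a blocked Gibbs sampler (the non-centered
beta_j = mu_j + Lambda eta_j parameterization makes every full conditional a
normal, inverse-Wishart, or truncated inverse-gamma draw).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import sample_mvn_prec, sample_trunc_invgamma_var, sample_invwishart

__all__ = [
    "WeatherModelSpec", "WeatherModel", "WeatherPosterior",
    "build_weather_model", "fit_weather_model", "retained_draws",
    "summarize_monthly_effects", "temperature_month_trend",
]

VARIABLES = ("precipitation", "temperature", "wind", "sca")
K = 4


@dataclass
class WeatherModelSpec:
    """MCMC schedule and prior constants.

    The desk-scale default (3 chains x 4,000 iterations, half discarded) is
    what the tests and pipeline run; :meth:`full_schedule` reproduces the
    published 3 x 100,000 / 30,000 burn-in / thin-2 schedule whose arithmetic
    retains 105,000 draws.
    """

    chains: int = 3
    iterations: int = 4000
    burnin: int = 2000
    thin: int = 1
    n_months: int = 12
    month_trend: bool = True
    prior_mean_sd: float = 100.0
    sd_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")

    @classmethod
    def full_schedule(cls, **kw) -> "WeatherModelSpec":
        return cls(chains=3, iterations=100_000, burnin=30_000, thin=2, **kw)


def retained_draws(spec: WeatherModelSpec) -> int:
    """Retained-draw count implied by the schedule: chains x floor((iters - burnin)/thin)."""
    return spec.chains * ((spec.iterations - spec.burnin) // spec.thin)


class WeatherModel:
    """Design data plus spec, validated and pre-indexed for the sampler."""

    def __init__(self, y: np.ndarray, Z: np.ndarray, month: np.ndarray,
                 spec: WeatherModelSpec, region: str = ""):
        self.y = np.asarray(y, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.month = np.asarray(month, dtype=int)  # 0-based
        self.spec = spec
        self.region = region
        self.n = len(self.y)
        self.J = spec.n_months
        self.zmonth = np.arange(1, self.J + 1) - (self.J + 1) / 2.0
        missing = sorted(set(range(self.J)) - set(self.month))
        if missing:
            raise ValueError("no data for month(s): "
                             + ", ".join(str(m + 1) for m in missing))
        sds = self.Z.std(axis=0, ddof=1)
        if np.any(sds == 0):
            k = int(np.flatnonzero(sds == 0)[0])
            raise ValueError(f"predictor {VARIABLES[k]} has zero variance")
        self.idx = [np.flatnonzero(self.month == j) for j in range(self.J)]
        self.ZtZ = [self.Z[ix].T @ self.Z[ix] for ix in self.idx]

    def log_joint(self, alpha, beta, mu, gamma0, gamma1, Sigma, sigma,
                  mu_alpha=None, sigma_alpha=1.0) -> float:
        """Log joint density at a parameter point (finite wherever valid)."""
        alpha = np.asarray(alpha, float)
        beta = np.asarray(beta, float)
        eta = self.y - alpha[self.month] - np.einsum(
            "ik,ik->i", self.Z, beta[self.month])
        ll = -0.5 * self.n * np.log(2 * np.pi * sigma ** 2) \
            - 0.5 * np.sum(eta ** 2) / sigma ** 2
        mu_j = np.tile(np.asarray(mu, float), (self.J, 1))
        if self.spec.month_trend:
            mu_j[:, 1] = gamma0 + gamma1 * self.zmonth
        dev = beta - mu_j
        Sinv = np.linalg.inv(Sigma)
        _, logdet = np.linalg.slogdet(Sigma)
        lp = -0.5 * self.J * (K * np.log(2 * np.pi) + logdet) \
            - 0.5 * np.einsum("jk,kl,jl->", dev, Sinv, dev)
        ma = np.mean(alpha) if mu_alpha is None else mu_alpha
        lp += np.sum(-0.5 * ((alpha - ma) / sigma_alpha) ** 2
                     - np.log(sigma_alpha) - 0.5 * np.log(2 * np.pi))
        sd0 = self.spec.prior_mean_sd
        for v in (mu[0], mu[2], mu[3], gamma0, gamma1, ma):
            lp += -0.5 * (v / sd0) ** 2 - np.log(sd0) - 0.5 * np.log(2 * np.pi)
        if not (0 < sigma < self.spec.sd_upper):
            return -np.inf
        return float(ll + lp)


def build_weather_model(design, spec: WeatherModelSpec | None = None) -> WeatherModel:
    """Assemble the model from a standardized design table.

    ``design`` is a :class:`~creelweather.prep.DesignTable` or a DataFrame
    with columns log_effort, z_precip, z_temp, z_wind, z_sca, month (1-based).
    """
    spec = spec or WeatherModelSpec()
    frame = design.frame if hasattr(design, "frame") else design
    region = getattr(design, "region", "")
    y = frame["log_effort"].to_numpy(dtype=float)
    Z = frame[["z_precip", "z_temp", "z_wind", "z_sca"]].to_numpy(dtype=float)
    month = frame["month"].to_numpy(dtype=int) - 1
    return WeatherModel(y, Z, month, spec, region=region)


@dataclass
class WeatherPosterior:
    """Posterior draws (chain, draw, ...) and per-parameter split R-hat."""

    draws: dict
    region: str = ""
    month_trend: bool = True
    rhat: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.draws["sigma"].size)

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return float(max(vals)) if vals else float("nan")

    def scalar_draws(self):
        """Yield (name, (chains, kept) array) for every monitored scalar."""
        J = self.draws["alpha"].shape[2]
        for j in range(J):
            yield f"alpha[{j + 1}]", self.draws["alpha"][:, :, j]
        for j in range(J):
            for k in range(K):
                yield f"beta[{j + 1},{k + 1}]", self.draws["beta"][:, :, j, k]
        for name in ("mu_beta1", "mu_beta2", "mu_beta3", "mu_beta4",
                     "gamma0", "gamma1", "sigma"):
            if name in self.draws:
                yield name, self.draws[name]
        for a in range(K):
            for b in range(a, K):
                yield f"Sigma[{a + 1},{b + 1}]", self.draws["Sigma"][:, :, a, b]

    def to_frame(self) -> pd.DataFrame:
        """Flat draw table (one column per monitored scalar)."""
        cols = {name: arr.reshape(-1) for name, arr in self.scalar_draws()}
        return pd.DataFrame(cols)


def fit_weather_model(model: WeatherModel, spec: WeatherModelSpec | None = None,
                      seed: int = 0) -> WeatherPosterior:
    """Blocked Gibbs sampler for the hierarchical model.

    Runs ``spec.chains`` chains from overdispersed starts (distinct
    sub-streams of ``seed``), discards the burn-in, thins, computes the
    split-chain rank-normalized R-hat for every monitored parameter, and
    warns (without failing) if any R-hat is >= 1.1.
    """
    spec = spec or model.spec
    y, Z, month, J = model.y, model.Z, model.month, model.J
    n = model.n
    idx, ZtZ = model.idx, model.ZtZ
    zm = model.zmonth
    trend = spec.month_trend
    pm = 1.0 / spec.prior_mean_sd ** 2

    # level-1 design for the (mu, gamma) block
    if trend:
        Xmu = np.column_stack([Z[:, 0], Z[:, 1], zm[month] * Z[:, 1],
                               Z[:, 2], Z[:, 3]])
    else:
        Xmu = Z
    XmuTXmu = Xmu.T @ Xmu
    pdim = Xmu.shape[1]

    kept = (spec.iterations - spec.burnin) // spec.thin
    out = {
        "alpha": np.empty((spec.chains, kept, J)),
        "beta": np.empty((spec.chains, kept, J, K)),
        "mu_beta1": np.empty((spec.chains, kept)),
        "mu_beta3": np.empty((spec.chains, kept)),
        "mu_beta4": np.empty((spec.chains, kept)),
        "sigma": np.empty((spec.chains, kept)),
        "Sigma": np.empty((spec.chains, kept, K, K)),
    }
    if trend:
        out["gamma0"] = np.empty((spec.chains, kept))
        out["gamma1"] = np.empty((spec.chains, kept))
    else:
        out["mu_beta2"] = np.empty((spec.chains, kept))

    # pooled least squares for initialization
    Xfull = np.column_stack([np.ones(n), Z])
    ols, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid_sd = max(float(np.std(y - Xfull @ ols)), 0.05)

    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(spec.chains)):
        rng = np.random.default_rng(child)
        alpha = np.array([y[ix].mean() for ix in idx]) + rng.normal(0, 0.5, J)
        coef = np.zeros(pdim)
        coef[:] = rng.normal(0, 0.1, pdim)
        coef[0] = ols[1] + rng.normal(0, 0.1)
        coef[1] = ols[2] + rng.normal(0, 0.1)
        if trend:
            coef[3] = ols[3] + rng.normal(0, 0.1)
            coef[4] = ols[4] + rng.normal(0, 0.1)
        else:
            coef[2] = ols[3] + rng.normal(0, 0.1)
            coef[3] = ols[4] + rng.normal(0, 0.1)
        eta = rng.normal(0, 0.5, (J, K))
        xi = 1.0 + rng.normal(0, 0.3, K)
        Q = np.eye(K)
        sig2 = (resid_sd * float(np.exp(rng.normal(0, 0.3)))) ** 2
        mu_alpha, sig_a2 = float(alpha.mean()), 1.0

        j_out = 0
        for it in range(spec.iterations):
            mu_j = _mu_matrix(coef, J, zm, trend)
            beta = mu_j + xi * eta

            # --- alpha_j | .  (vectorized across months)
            r = y - np.einsum("ik,ik->i", Z, beta[month])
            sums = np.bincount(month, weights=r, minlength=J)
            nj = np.bincount(month, minlength=J)
            v = 1.0 / (nj / sig2 + 1.0 / sig_a2)
            alpha = rng.normal(v * (sums / sig2 + mu_alpha / sig_a2), np.sqrt(v))

            # --- intercept hyperparameters
            v = 1.0 / (J / sig_a2 + pm)
            mu_alpha = rng.normal(v * alpha.sum() / sig_a2, np.sqrt(v))
            sig_a2 = sample_trunc_invgamma_var(
                (J - 1) / 2.0, float(((alpha - mu_alpha) ** 2).sum()) / 2.0,
                spec.sd_upper, rng)

            # --- eta_j | .  (non-centered monthly deviations)
            r_base = y - alpha[month] - Xmu @ coef
            Qinv = np.linalg.inv(Q)
            Lam = np.diag(xi)
            for j in range(J):
                ix = idx[j]
                A = Lam @ ZtZ[j] @ Lam
                prec = Qinv + A / sig2
                shift = (xi * (Z[ix].T @ r_base[ix])) / sig2
                eta[j] = sample_mvn_prec(prec, shift, rng)

            # --- xi | .  (scale parameters of the scaled inverse-Wishart)
            W = Z * eta[month]  # column k: z_ik * eta_{j(i),k}
            prec = W.T @ W / sig2 + pm * np.eye(K)
            xi = sample_mvn_prec(prec, W.T @ r_base / sig2, rng)

            # --- (mu, gamma) | .
            r_mu = y - alpha[month] - np.einsum("ik,ik->i", Z, (xi * eta)[month])
            prec = XmuTXmu / sig2 + pm * np.eye(pdim)
            coef = sample_mvn_prec(prec, Xmu.T @ r_mu / sig2, rng)

            # --- Q | .  inverse-Wishart, df = K+1+J
            Q = sample_invwishart(K + 1 + J, np.eye(K) + eta.T @ eta, rng)

            # --- sigma | .
            mu_j = _mu_matrix(coef, J, zm, trend)
            beta = mu_j + xi * eta
            resid = y - alpha[month] - np.einsum("ik,ik->i", Z, beta[month])
            sig2 = sample_trunc_invgamma_var(
                (n - 1) / 2.0, float((resid ** 2).sum()) / 2.0,
                spec.sd_upper, rng)

            if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0:
                out["alpha"][c, j_out] = alpha
                out["beta"][c, j_out] = beta
                out["mu_beta1"][c, j_out] = coef[0]
                if trend:
                    out["gamma0"][c, j_out] = coef[1]
                    out["gamma1"][c, j_out] = coef[2]
                    out["mu_beta3"][c, j_out] = coef[3]
                    out["mu_beta4"][c, j_out] = coef[4]
                else:
                    out["mu_beta2"][c, j_out] = coef[1]
                    out["mu_beta3"][c, j_out] = coef[2]
                    out["mu_beta4"][c, j_out] = coef[3]
                out["sigma"][c, j_out] = np.sqrt(sig2)
                out["Sigma"][c, j_out] = np.outer(xi, xi) * Q
                j_out += 1

    post = WeatherPosterior(draws=out, region=model.region, month_trend=trend)
    from .diagnostics import gelman_rubin
    for name, arr in post.scalar_draws():
        post.rhat[name] = gelman_rubin(arr)
    if np.isfinite(post.max_rhat) and post.max_rhat >= 1.1:
        worst = max(post.rhat, key=lambda k: post.rhat[k]
                    if np.isfinite(post.rhat[k]) else -np.inf)
        warnings.warn(
            f"weather model ({model.region or 'unnamed region'}): max R-hat "
            f"{post.max_rhat:.3f} >= 1.1 ({worst}); inspect the chains",
            UserWarning)
    return post


def _mu_matrix(coef: np.ndarray, J: int, zm: np.ndarray, trend: bool) -> np.ndarray:
    mu_j = np.empty((J, K))
    if trend:
        mu_j[:, 0] = coef[0]
        mu_j[:, 1] = coef[1] + coef[2] * zm
        mu_j[:, 2] = coef[3]
        mu_j[:, 3] = coef[4]
    else:
        mu_j[:] = coef[:K]
    return mu_j


def summarize_monthly_effects(posterior: WeatherPosterior,
                              region: str | None = None,
                              level: float = 0.95) -> pd.DataFrame:
    """One row per (variable, month): posterior mean, central 95% interval,
    and the credible flag (interval excludes zero)."""
    from .diagnostics import credible_interval
    if "beta" not in posterior.draws or posterior.draws["beta"].size == 0:
        raise ValueError("posterior has no coefficient draws")
    region = posterior.region if region is None else region
    beta = posterior.draws["beta"]
    J = beta.shape[2]
    rows = []
    for k, var in enumerate(VARIABLES):
        for j in range(J):
            d = beta[:, :, j, k].reshape(-1)
            lo, hi, excl = credible_interval(d, level)
            rows.append({"region": region, "variable": var, "month": j + 1,
                         "mean": float(d.mean()), "lower": lo, "upper": hi,
                         "credible": excl})
    return pd.DataFrame(rows)


def temperature_month_trend(posterior: WeatherPosterior,
                            level: float = 0.95) -> dict:
    """Level-2 temperature trend: gamma summaries plus the fitted line by month."""
    from .diagnostics import credible_interval
    if "gamma0" not in posterior.draws:
        raise ValueError("posterior was fit without the temperature month trend")
    g0 = posterior.draws["gamma0"].reshape(-1)
    g1 = posterior.draws["gamma1"].reshape(-1)
    J = posterior.draws["alpha"].shape[2]
    zm = np.arange(1, J + 1) - (J + 1) / 2.0
    line = []
    for j in range(J):
        d = g0 + g1 * zm[j]
        lo, hi, _ = credible_interval(d, level)
        line.append({"month": j + 1, "mean": float(d.mean()),
                     "lower": lo, "upper": hi})
    lo0, hi0, ex0 = credible_interval(g0, level)
    lo1, hi1, ex1 = credible_interval(g1, level)
    return {
        "gamma0": {"mean": float(g0.mean()), "lower": lo0, "upper": hi0,
                   "credible": ex0},
        "gamma1": {"mean": float(g1.mean()), "lower": lo1, "upper": hi1,
                   "credible": ex1, "negative": float(g1.mean()) < 0},
        "line": pd.DataFrame(line),
    }
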