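"""Small conjugate-update primitives shared by the Gibbs samplers.

These are deliberately minimal: every full conditional in the hierarchical
normal models reduces to a multivariate-normal draw given a precision matrix,
an inverse-Wishart draw, or a truncated inverse-gamma draw for a variance
whose standard deviation carries a Uniform(0, upper) prior.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaincc, gammainccinv

__all__ = [
    "sample_mvn_prec",
    "sample_trunc_invgamma_var",
    "sample_invwishart",
]


def sample_mvn_prec(prec: np.ndarray, shift: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw x ~ N(prec^{-1} shift, prec^{-1}) via a Cholesky factor of ``prec``."""
    L = np.linalg.cholesky(prec)
    tmp = solve_triangular(L, shift, lower=True)
    mean = solve_triangular(L.T, tmp, lower=False)
    z = rng.standard_normal(prec.shape[0])
    return mean + solve_triangular(L.T, z, lower=False)


def sample_trunc_invgamma_var(a: float, scale: float, upper_sd: float,
                              rng: np.random.Generator) -> float:
    """Draw a variance v with density ∝ v^{-(a+1)} exp(-scale/v) on (0, upper_sd²).

    This is the full conditional of a normal variance whose standard deviation
    has a Uniform(0, upper_sd) prior.  Sampled by inverse-CDF using the
    regularized upper incomplete gamma function (CDF(v) = Q(a, scale/v)).
    """
    if a <= 0.0:
        # No information in the likelihood (a single group): draw from the
        # Uniform(0, upper_sd) prior on the standard deviation.
        return float(rng.uniform(0.0, upper_sd)) ** 2
    if scale <= 0.0:
        # Degenerate sum of squares (e.g. a perfect fit): return a tiny variance.
        return 1e-12
    upper_var = upper_sd * upper_sd
    cmax = float(gammaincc(a, scale / upper_var))
    u = rng.uniform(0.0, cmax)
    u = max(u, 1e-300)
    return float(scale / gammainccinv(a, u))


def sample_invwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw Q ~ Inverse-Wishart(df, scale) by the Bartlett decomposition.

    If W ~ Wishart(df, scale^{-1}) then W^{-1} ~ IW(df, scale).
    """
    p = scale.shape[0]
    # Cholesky of scale^{-1}: solve from the factor of `scale` itself.
    Ls = np.linalg.cholesky(scale)
    inv_Ls = solve_triangular(Ls, np.eye(p), lower=True)
    L = inv_Ls.T  # scale^{-1} = L @ L.T with L lower? inv(scale) = inv_Ls.T @ inv_Ls
    # Build Bartlett factor A (lower triangular).
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
    idx = np.tril_indices(p, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    # W = C A A' C' where C C' = scale^{-1}; take C = inv_Ls.T? We need C lower.
    # inv(scale) = inv_Ls.T @ inv_Ls, which is an upper*lower product; use the
    # Cholesky of inv(scale) directly for clarity (p is tiny).
    C = np.linalg.cholesky(inv_Ls.T @ inv_Ls)
    CA = C @ A
    W = CA @ CA.T
    Q = np.linalg.inv(W)
    # Symmetrize against round-off.
    return 0.5 * (Q + Q.T)
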