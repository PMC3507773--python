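"""Sampling primitives and kernels for the whole-genome regression models.

All full-conditional draws used by the BayesA and Bayesian-LASSO Gibbs
samplers live here so each conditional law can be exercised (and its
moments checked) in isolation:

* scaled inverse chi-square draws for per-marker variances and the
  residual variance,
* gamma draw for the LASSO ``lambda^2`` under its Gamma(0.05, 1) hyperprior,
* truncated gamma draw for the BayesA scale ``s^2`` (uniform prior on
  ``s`` over (0, Q], honoured by rejection at ``s > Q``),
* inverse-Gaussian draws for the LASSO ``1/sigma2_gi`` conditionals,
* random-walk Metropolis step on ``log nu`` for the BayesA degrees of
  freedom (uniform prior on a bounded interval, no closed form).

The single-site update sweep over marker effects is compiled with numba;
its normal deviates are drawn outside the kernel from the caller's
generator, so chains are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln


def sample_scaled_inv_chi2(rng, df: float, scale, size=None):
    """Draw from scaled-inv-chi2(df, scale): df*scale / chi2_df.

    Mean is df*scale/(df-2) for df > 2.
    """
    return df * np.asarray(scale) / rng.chisquare(df, size)


def sample_sigma2_g_bayesa(rng, beta: np.ndarray, nu: float, s2: float):
    """Per-marker variance conditionals: scaled-inv-chi2 with df nu+1 and
    scale (nu s2 + beta_i^2)/(nu + 1)."""
    return sample_scaled_inv_chi2(
        rng, nu + 1.0, (nu * s2 + beta**2) / (nu + 1.0), size=len(beta)
    )


def sample_sigma2_e(rng, weighted_sse: float, n: int, s0_sq: float,
                    prior_df: float = 4.0):
    """Residual-variance conditional: scaled-inv-chi2 with df prior_df + n
    and scale (prior_df*s0_sq + weighted_sse)/(prior_df + n).

    ``s0_sq`` is half the prior expectation, so that the prior
    (df = 4) has mean equal to the residual variance used in the
    pedigree BLUP run.
    """
    df = prior_df + n
    return float(sample_scaled_inv_chi2(
        rng, df, (prior_df * s0_sq + weighted_sse) / df
    ))


def sample_s2(rng, n_markers: int, nu: float, sum_inv_sigma2g: float,
              s_max: float = 100.0, max_tries: int = 1000):
    """BayesA scale conditional: Gamma(0.5 p nu + 1, rate 0.5 nu sum(1/s2_gi)),
    truncated so that s = sqrt(s2) <= s_max."""
    shape = 0.5 * n_markers * nu + 1.0
    rate = 0.5 * nu * sum_inv_sigma2g
    for _ in range(max_tries):
        s2 = rng.gamma(shape, 1.0 / rate)
        if np.sqrt(s2) <= s_max:
            return float(s2)
    return float(s_max**2)


def sample_lambda2(rng, n_markers: int, sum_tau2: float,
                   prior_shape: float = 0.05, prior_rate: float = 1.0):
    """LASSO lambda^2 conditional: Gamma(p + a, rate sum(tau2)/2 + b)."""
    return float(rng.gamma(n_markers + prior_shape,
                           1.0 / (0.5 * sum_tau2 + prior_rate)))


def sample_inv_tau2_blasso(rng, beta: np.ndarray, lambda2: float,
                           sigma2_e: float):
    """LASSO conditionals for the scaled marker variances.

    With sigma2_gi = sigma2_e * tau2_i, the reciprocals have
    1/tau2_i ~ InvGaussian(sqrt(lambda2 sigma2_e / beta_i^2), lambda2).
    """
    b2 = np.maximum(beta**2, 1e-12)
    mean = np.sqrt(lambda2 * sigma2_e / b2)
    return rng.wald(mean, lambda2)


def nu_log_posterior(nu: float, s2: float, sigma2_g: np.ndarray) -> float:
    """Log posterior kernel of the BayesA degrees of freedom.

    Product over markers of scaled-inv-chi2(sigma2_gi | nu, s2) densities;
    the uniform prior on the allowed interval is handled by the caller.
    """
    p = len(sigma2_g)
    half = 0.5 * nu
    return (
        p * (half * np.log(half * s2) - gammaln(half))
        - (1.0 + half) * np.sum(np.log(sigma2_g))
        - half * s2 * np.sum(1.0 / sigma2_g)
    )


def metropolis_nu(rng, nu: float, s2: float, sigma2_g: np.ndarray,
                  step: float, nu_max: float = 1.0):
    """One random-walk Metropolis update of nu on the log scale.

    Proposals outside (0, nu_max] are rejected; the log-scale random walk
    contributes a Jacobian factor nu'/nu.  Returns (nu, accepted).
    """
    prop = nu * np.exp(step * rng.standard_normal())
    if not (0.0 < prop <= nu_max):
        return nu, False
    log_ratio = (
        nu_log_posterior(prop, s2, sigma2_g)
        - nu_log_posterior(nu, s2, sigma2_g)
        + np.log(prop / nu)
    )
    if np.log(rng.random()) < log_ratio:
        return float(prop), True
    return nu, False


@njit(cache=True)
def beta_sweep(X, e, beta, xwx, w, sigma2_g, sigma2_e, z):  # pragma: no cover
    """Single-site Gibbs sweep over marker effects.

    ``X`` is the (centred) training genotype matrix, ``e`` the current
    residual vector (updated in place together with ``beta``), ``xwx`` the
    precomputed weighted column norms, ``w`` the record weights and ``z``
    one standard-normal deviate per marker.
    """
    n, p = X.shape
    for j in range(p):
        bj = beta[j]
        r = 0.0
        for i in range(n):
            r += X[i, j] * w[i] * e[i]
        r += xwx[j] * bj
        denom = xwx[j] + sigma2_e / sigma2_g[j]
        mean = r / denom
        new = mean + z[j] * np.sqrt(sigma2_e / denom)
        diff = new - bj
        if diff != 0.0:
            for i in range(n):
                e[i] -= X[i, j] * diff
        beta[j] = new


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5):
    """Simple Geweke convergence z-score between early and late chain
    segments (reported as a diagnostic, never enforced)."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)
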