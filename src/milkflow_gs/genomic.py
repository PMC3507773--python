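"""Stage-two genomic prediction models on deregressed proofs.

Three univariate models of the training sires' dEBV:

* :class:`GBLUP` — mixed-model equations with the genomic relationship
  matrix in place of the numerator relationship matrix; validation
  animals, carrying no records, obtain predictions through their G ties.
* :class:`BayesA` — per-marker normal effects with scaled-inv-chi-square
  variances whose scale ``s^2`` and degrees of freedom ``nu`` are
  estimated from the data (``s^2`` by a truncated gamma conditional,
  ``nu`` by a Metropolis step on a bounded interval).
* :class:`BayesianLasso` — per-marker normal effects with exponential
  variance mixing (double-exponential marginal), single shrinkage
  parameter ``lambda`` under an essentially flat Gamma(0.05, 1) prior.

All three weight each record ``i`` by ``w_i`` (residual variance
``sigma2_e / w_i``).  Direct genomic values are ``DGV = Z beta`` with the
same allele-frequency centring as the G matrix, and genome-enhanced
breeding values blend DGV with the adjusted parent average by selection
index on their reliabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import samplers
from .data import GenotypeMatrix
from .relationship import RelationshipMatrix, invert_dense


# ---------------------------------------------------------------------------
# GBLUP

class GBLUP:
    """Genomic BLUP of deregressed proofs for one trait.

    Parameters
    ----------
    debv, weights : Series indexed by training animal id.
    G : RelationshipMatrix over all genotyped animals (training and
        validation); inverted internally (blend beforehand if G is
        singular).
    sigma2_a : additive genetic variance of the trait (complete-data
        value from the variance-component configuration).
    sigma2_e : residual variance on the record scale; each record i has
        residual variance ``sigma2_e / w_i``.
    """

    def __init__(self, debv: pd.Series, weights: pd.Series,
                 G: RelationshipMatrix, sigma2_a: float, sigma2_e: float):
        self.debv = debv
        self.weights = weights
        self.G = G
        self.sigma2_a = float(sigma2_a)
        self.sigma2_e = float(sigma2_e)
        if np.any(weights.loc[debv.index].to_numpy() <= 0):
            raise ValueError("record weights must be positive")
        self._train_idx = G.index_of(debv.index)

    def fit(self) -> "GBLUPResults":
        n = len(self.G.ids)
        if self.G.kind in ("G", "G_blended"):
            Ginv = invert_dense(self.G, "G_inverse").to_dense()
        else:
            Ginv = self.G.to_dense()
        w = self.weights.loc[self.debv.index].to_numpy(dtype=float)
        y = self.debv.to_numpy(dtype=float)
        idx = self._train_idx

        dim = 1 + n
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        C[0, 0] = w.sum() / self.sigma2_e
        zw = np.zeros(n)
        np.add.at(zw, idx, w)
        C[0, 1:] = zw / self.sigma2_e
        C[1:, 0] = zw / self.sigma2_e
        zwz = np.zeros(n)
        np.add.at(zwz, idx, w)
        C[1:, 1:] = np.diag(zwz / self.sigma2_e) + Ginv / self.sigma2_a
        rhs[0] = (w * y).sum() / self.sigma2_e
        wy = np.zeros(n)
        np.add.at(wy, idx, w * y)
        rhs[1:] = wy / self.sigma2_e

        sol = np.linalg.solve(C, rhs)
        u = pd.Series(sol[1:], index=self.G.ids, name="gblup")
        return GBLUPResults(model=self, mu=float(sol[0]), u=u)


@dataclass
class GBLUPResults:
    model: GBLUP
    mu: float
    u: pd.Series  # genomic breeding values for every animal in G

    def predict(self, ids) -> pd.Series:
        return self.u.loc[np.asarray(ids, dtype=object)]

    def summary(self) -> str:
        return (f"GBLUP: {len(self.model.debv)} training records, "
                f"{len(self.u)} genotyped animals, mu = {self.mu:.4f}, "
                f"sd(u) = {self.u.std():.4f}")


# ---------------------------------------------------------------------------
# MCMC marker models

@dataclass
class MCMCConfig:
    """Gibbs chain settings.  Production chains are typically far longer
    (100k+); the defaults are desk-scale."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    nu_interval: tuple = (0.0, 1.0)
    s_max: float = 100.0
    metropolis_step: float = 0.5

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MarkerPosterior:
    """Posterior summaries of a whole-genome regression fit."""

    method: str
    beta: pd.Series  # posterior-mean marker effects
    mu: float
    sigma2_e: float
    freqs: np.ndarray
    hyper: dict
    chain: pd.DataFrame  # thinned post-burn-in scalar parameters
    acceptance: float | None = None

    def dgv(self, genotypes: GenotypeMatrix) -> pd.Series:
        """Direct genomic values: centred genotype rows times the
        posterior-mean marker effects."""
        return compute_dgv(self.beta.to_numpy(), genotypes, self.freqs)

    def geweke(self) -> pd.Series:
        return pd.Series({c: samplers.geweke_z(self.chain[c].to_numpy())
                          for c in self.chain.columns})

    def summary(self) -> str:
        lines = [f"{self.method}: {len(self.beta)} markers",
                 f"mu = {self.mu:.4f}  sigma2_e = {self.sigma2_e:.4f}"]
        for k, v in self.hyper.items():
            lines.append(f"{k} = {v:.4f}")
        if self.acceptance is not None:
            lines.append(f"Metropolis acceptance = {self.acceptance:.2f}")
        lines.append("Geweke z: " + "  ".join(
            f"{c}={z:.2f}" for c, z in self.geweke().items()))
        return "\n".join(lines)


class _MarkerModel:
    """Shared machinery of the BayesA and Bayesian-LASSO Gibbs samplers."""

    method = ""

    def __init__(self, debv: pd.Series, weights: pd.Series,
                 genotypes: GenotypeMatrix, sigma2_e_expectation: float,
                 freqs: np.ndarray | None = None):
        if not genotypes.is_complete:
            raise ValueError("marker models require complete genotypes")
        if len(debv) < 2:
            raise ValueError("need at least two training records")
        self.debv = debv
        self.weights = weights
        rows = genotypes.row_index(debv.index)
        if freqs is None:
            freqs = genotypes.codes.mean(axis=0) / 2.0
        self.freqs = np.asarray(freqs, dtype=float)
        self.X = genotypes.codes[rows] - 2.0 * self.freqs
        self.sigma2_e_expectation = float(sigma2_e_expectation)

    def _common_state(self, rng):
        y = self.debv.to_numpy(dtype=float)
        w = self.weights.loc[self.debv.index].to_numpy(dtype=float)
        X = np.asfortranarray(self.X)  # column-major: the sweep scans columns
        n, p = X.shape
        xwx = np.einsum("ij,i,ij->j", X, w, X)
        mu = float(np.average(y, weights=w))
        beta = np.zeros(p)
        e = y - mu
        sigma2_e = self.sigma2_e_expectation
        return y, w, X, n, p, xwx, mu, beta, e, sigma2_e

    def _sweep_and_mu(self, rng, X, e, beta, xwx, w, sigma2_g, sigma2_e, mu):
        samplers.beta_sweep(X, e, beta, xwx, w, sigma2_g, sigma2_e,
                            rng.standard_normal(len(beta)))
        e += mu
        wsum = w.sum()
        mu = float(rng.normal((w * e).sum() / wsum, np.sqrt(sigma2_e / wsum)))
        e -= mu
        return mu


class BayesA(_MarkerModel):
    """BayesA with unknown scale and degrees of freedom.

    Marker variances are scaled-inv-chi-square(nu, s^2); ``nu`` has a
    uniform prior on ``config.nu_interval`` (default (0, 1], implying very
    heavy-tailed effect distributions) sampled by random-walk Metropolis
    on the log scale, and ``s`` a uniform prior on (0, s_max] handled by
    truncating the gamma conditional of ``s^2``.
    """

    method = "BayesA"

    def fit(self, config: MCMCConfig | None = None) -> MarkerPosterior:
        config = config or MCMCConfig()
        rng = np.random.default_rng(config.seed)
        y, w, X, n, p, xwx, mu, beta, e, sigma2_e = self._common_state(rng)
        s0_sq = 0.5 * self.sigma2_e_expectation
        nu_lo, nu_max = config.nu_interval
        nu = min(0.5 * (nu_lo + nu_max) or 0.5, nu_max)
        s2 = min(0.05, config.s_max**2)
        sigma2_g = np.full(p, max(s2, 1e-4))
        step = config.metropolis_step

        beta_sum = np.zeros(p)
        mu_sum = 0.0
        kept = 0
        accepted = tried = 0
        rows = []
        for it in range(config.n_iter):
            mu = self._sweep_and_mu(rng, X, e, beta, xwx, w, sigma2_g,
                                    sigma2_e, mu)
            sigma2_g = samplers.sample_sigma2_g_bayesa(rng, beta, nu, s2)
            sigma2_e = samplers.sample_sigma2_e(
                rng, float(np.sum(w * e * e)), n, s0_sq)
            if not np.isfinite(sigma2_e) or sigma2_e <= 0:
                raise FloatingPointError(
                    f"non-finite residual variance at iteration {it}")
            s2 = samplers.sample_s2(rng, p, nu, float(np.sum(1.0 / sigma2_g)),
                                    config.s_max)
            nu, acc = samplers.metropolis_nu(rng, nu, s2, sigma2_g, step,
                                             nu_max)
            tried += 1
            accepted += acc
            # tune the proposal during burn-in towards 20-50% acceptance
            if it < config.burn_in and it and it % 100 == 0:
                rate = accepted / tried
                if rate < 0.2:
                    step *= 0.8
                elif rate > 0.5:
                    step *= 1.25
                accepted = tried = 0
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                beta_sum += beta
                mu_sum += mu
                kept += 1
                rows.append((it, mu, sigma2_e, s2, nu))

        chain = pd.DataFrame(rows, columns=["iteration", "mu", "sigma2_e",
                                            "s2", "nu"]).set_index("iteration")
        return MarkerPosterior(
            method=self.method,
            beta=pd.Series(beta_sum / kept, index=range(p), name="beta"),
            mu=mu_sum / kept,
            sigma2_e=float(chain["sigma2_e"].mean()),
            freqs=self.freqs,
            hyper={"s2": float(chain["s2"].mean()),
                   "nu": float(chain["nu"].mean())},
            chain=chain,
            acceptance=accepted / max(tried, 1),
        )


class BayesianLasso(_MarkerModel):
    """Bayesian LASSO with a single shrinkage parameter lambda.

    Marker variances have exponential priors with mean ``2 / lambda^2``;
    their reciprocals have inverse-Gaussian full conditionals, and
    ``lambda^2`` a gamma conditional under the Gamma(0.05, 1) hyperprior.
    """

    method = "BayesianLASSO"

    def fit(self, config: MCMCConfig | None = None) -> MarkerPosterior:
        config = config or MCMCConfig()
        rng = np.random.default_rng(config.seed)
        y, w, X, n, p, xwx, mu, beta, e, sigma2_e = self._common_state(rng)
        s0_sq = 0.5 * self.sigma2_e_expectation
        lambda2 = 1.0
        tau2 = np.full(p, 0.01)  # scaled variances: sigma2_gi = sigma2_e tau2_i

        beta_sum = np.zeros(p)
        mu_sum = 0.0
        kept = 0
        rows = []
        for it in range(config.n_iter):
            mu = self._sweep_and_mu(rng, X, e, beta, xwx, w,
                                    sigma2_e * tau2, sigma2_e, mu)
            inv_tau2 = samplers.sample_inv_tau2_blasso(rng, beta, lambda2,
                                                       sigma2_e)
            tau2 = 1.0 / inv_tau2
            lambda2 = samplers.sample_lambda2(rng, p, float(np.sum(tau2)))
            sigma2_e = samplers.sample_sigma2_e(
                rng, float(np.sum(w * e * e)), n, s0_sq)
            if not np.isfinite(sigma2_e) or sigma2_e <= 0:
                raise FloatingPointError(
                    f"non-finite residual variance at iteration {it}")
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                beta_sum += beta
                mu_sum += mu
                kept += 1
                rows.append((it, mu, sigma2_e, lambda2))

        chain = pd.DataFrame(rows, columns=["iteration", "mu", "sigma2_e",
                                            "lambda2"]).set_index("iteration")
        return MarkerPosterior(
            method=self.method,
            beta=pd.Series(beta_sum / kept, index=range(p), name="beta"),
            mu=mu_sum / kept,
            sigma2_e=float(chain["sigma2_e"].mean()),
            freqs=self.freqs,
            hyper={"lambda2": float(chain["lambda2"].mean())},
            chain=chain,
        )


# ---------------------------------------------------------------------------
# DGV and GEBV

def compute_dgv(beta: np.ndarray, genotypes: GenotypeMatrix,
                freqs: np.ndarray | None = None) -> pd.Series:
    """Direct genomic values: sum of marker effects over the genome,
    using the same allele-frequency centring as the G matrix."""
    if not genotypes.is_complete:
        raise ValueError("DGV requires complete genotypes")
    if freqs is None:
        freqs = genotypes.codes.mean(axis=0) / 2.0
    Z = genotypes.codes - 2.0 * np.asarray(freqs, dtype=float)
    return pd.Series(Z @ np.asarray(beta, dtype=float),
                     index=genotypes.animal_ids, name="dgv")


def blend_gebv(dgv, r2_dgv, apa, r2_apa):
    """Selection-index blend of DGV with the adjusted parent average.

    Treating the two sources as independent, the index weights are
    proportional to the reliabilities; the combined reliability is
    ``r2_DGV + r2_aPA - r2_DGV * r2_aPA`` (capped at 1).  Returns
    ``(gebv, r2_gebv)``.
    """
    dgv = np.asarray(dgv, dtype=float)
    apa = np.asarray(apa, dtype=float)
    r2_dgv = np.asarray(r2_dgv, dtype=float)
    r2_apa = np.asarray(r2_apa, dtype=float)
    total = r2_dgv + r2_apa
    zero = total <= 0
    if np.any(zero):
        warnings.warn("both reliabilities zero for some animals; GEBV set to 0")
    safe = np.where(zero, 1.0, total)
    gebv = np.where(zero, 0.0, (r2_dgv * dgv + r2_apa * apa) / safe)
    r2 = np.minimum(r2_dgv + r2_apa - r2_dgv * r2_apa, 1.0)
    if np.isscalar(dgv) or dgv.ndim == 0:
        return float(gebv), float(r2)
    return gebv, r2
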