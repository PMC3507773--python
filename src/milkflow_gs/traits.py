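"""Trait parameters for the six milkability traits.

The six traits are total milking time (TMT), ascending time (AT), time of
plateau (TP), descending time (DT), maximum milk flow (MMF) and average milk
flow (AVGF).  Genetic merit and environment act on all six jointly, so the
parameter set carries heritabilities together with genetic and phenotypic
correlation matrices; the residual correlation matrix is derived from them.

The default parameter values are the published multi-trait estimates for
Italian Brown Swiss.  The printed genetic correlation matrix is not positive
definite (e.g. MMF-AVGF = 0.95 and MMF-TP = 0.85 are jointly incompatible
with AVGF-TP = -0.84), so both derived covariance matrices are repaired to
the nearest positive-definite correlation matrix by eigenvalue clipping
followed by re-standardisation to unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAIT_NAMES = ("TMT", "AT", "TP", "DT", "MMF", "AVGF")

# Heritabilities (multi-trait animal model estimates), trait order as above.
DEFAULT_H2 = {
    "TMT": 0.42,
    "AT": 0.02,
    "TP": 0.32,
    "DT": 0.05,
    "MMF": 0.11,
    "AVGF": 0.27,
}

# Genetic correlations (upper triangle of the published table).
_GENETIC_CORR = {
    ("MMF", "AVGF"): 0.95,
    ("MMF", "AT"): -0.61,
    ("MMF", "TP"): 0.85,
    ("MMF", "DT"): 0.73,
    ("MMF", "TMT"): -0.88,
    ("AVGF", "AT"): -0.58,
    ("AVGF", "TP"): -0.84,
    ("AVGF", "DT"): -0.58,
    ("AVGF", "TMT"): -0.90,
    ("AT", "TP"): -0.76,
    ("AT", "DT"): -0.26,
    ("AT", "TMT"): 0.82,
    ("TP", "DT"): 0.31,
    ("TP", "TMT"): -0.93,
    ("DT", "TMT"): -0.44,
}

# Phenotypic correlations (lower triangle of the published table).
_PHENOTYPIC_CORR = {
    ("AVGF", "MMF"): 0.83,
    ("AT", "MMF"): -0.01,
    ("AT", "AVGF"): -0.03,
    ("TP", "MMF"): 0.40,
    ("TP", "AVGF"): -0.27,
    ("TP", "AT"): -0.26,
    ("DT", "MMF"): 0.39,
    ("DT", "AVGF"): -0.36,
    ("DT", "AT"): -0.04,
    ("DT", "TP"): -0.15,
    ("TMT", "MMF"): -0.34,
    ("TMT", "AVGF"): -0.32,
    ("TMT", "AT"): 0.17,
    ("TMT", "TP"): -0.59,
    ("TMT", "DT"): -0.10,
}


def _corr_from_pairs(pairs: dict, names) -> np.ndarray:
    n = len(names)
    idx = {t: i for i, t in enumerate(names)}
    m = np.eye(n)
    for (a, b), r in pairs.items():
        m[idx[a], idx[b]] = r
        m[idx[b], idx[a]] = r
    return m


def nearest_pd_correlation(
    corr: np.ndarray, eig_floor: float = 1e-4, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped up to it and the matrix is
    re-standardised to unit diagonal; the two steps are iterated because the
    re-standardisation can reintroduce small negative eigenvalues.

    Returns the repaired matrix and the maximum absolute entrywise
    adjustment relative to the input.
    """
    m = np.asarray(corr, dtype=float).copy()
    m = 0.5 * (m + m.T)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(m)
        if w.min() >= eig_floor * (1.0 - 1e-12):
            break
        w = np.clip(w, eig_floor, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
    return m, float(np.max(np.abs(m - np.asarray(corr, dtype=float))))


def residual_correlation(
    phenotypic_corr: np.ndarray, genetic_corr: np.ndarray, h2: np.ndarray
) -> np.ndarray:
    """Residual correlations implied by phenotypic and genetic correlations.

    r_e(i,j) = (r_p(i,j) - r_g(i,j) h_i h_j) / sqrt((1-h2_i)(1-h2_j))
    with h_i = sqrt(h2_i).  Values are clipped to [-1, 1] before any
    positive-definite repair.
    """
    h = np.sqrt(np.asarray(h2, dtype=float))
    denom = np.sqrt(np.outer(1.0 - h2, 1.0 - h2))
    re = (phenotypic_corr - genetic_corr * np.outer(h, h)) / denom
    re = np.clip(re, -1.0, 1.0)
    np.fill_diagonal(re, 1.0)
    return 0.5 * (re + re.T)


@dataclass
class TraitParameters:
    """Variance components for a set of (possibly correlated) traits.

    Parameters
    ----------
    trait_names : tuple of str
    h2 : array of heritabilities in (0, 1)
    phenotypic_var : per-trait phenotypic variances (default 1, i.e. the
        traits are analysed on a standardised scale)
    genetic_corr, phenotypic_corr : correlation matrices as published; both
        the genetic and the derived residual correlation matrix are repaired
        to positive definite on construction.
    """

    trait_names: tuple = TRAIT_NAMES
    h2: np.ndarray = None
    phenotypic_var: np.ndarray = None
    genetic_corr: np.ndarray = None
    phenotypic_corr: np.ndarray = None
    eig_floor: float = 1e-4
    # filled in __post_init__
    residual_corr: np.ndarray = field(default=None, repr=False)
    genetic_corr_adjustment: float = field(default=0.0, repr=False)
    residual_corr_adjustment: float = field(default=0.0, repr=False)

    def __post_init__(self):
        names = tuple(self.trait_names)
        self.trait_names = names
        n = len(names)
        if self.h2 is None:
            self.h2 = np.array([DEFAULT_H2[t] for t in names])
        self.h2 = np.asarray(self.h2, dtype=float)
        if np.any(self.h2 <= 0) or np.any(self.h2 >= 1):
            raise ValueError("heritabilities must lie strictly in (0, 1)")
        if self.phenotypic_var is None:
            self.phenotypic_var = np.ones(n)
        self.phenotypic_var = np.asarray(self.phenotypic_var, dtype=float)
        if np.any(self.phenotypic_var <= 0):
            raise ValueError("phenotypic variances must be positive")
        if self.genetic_corr is None:
            self.genetic_corr = _corr_from_pairs(_GENETIC_CORR, names)
        if self.phenotypic_corr is None:
            self.phenotypic_corr = _corr_from_pairs(_PHENOTYPIC_CORR, names)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        self.phenotypic_corr = np.asarray(self.phenotypic_corr, dtype=float)
        for m in (self.genetic_corr, self.phenotypic_corr):
            if m.shape != (n, n) or not np.allclose(m, m.T):
                raise ValueError("correlation matrices must be symmetric n x n")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("correlation matrices must have unit diagonal")
        raw_re = residual_correlation(self.phenotypic_corr, self.genetic_corr, self.h2)
        self.genetic_corr, self.genetic_corr_adjustment = nearest_pd_correlation(
            self.genetic_corr, self.eig_floor
        )
        self.residual_corr, self.residual_corr_adjustment = nearest_pd_correlation(
            raw_re, self.eig_floor
        )

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def sigma2_a(self) -> np.ndarray:
        """Additive genetic variances sigma2_a = h2 * phenotypic_var."""
        return self.h2 * self.phenotypic_var

    @property
    def sigma2_e(self) -> np.ndarray:
        """Residual variances (1 - h2) * phenotypic_var."""
        return (1.0 - self.h2) * self.phenotypic_var

    @property
    def genetic_cov(self) -> np.ndarray:
        """Additive genetic covariance matrix G0 (PD-repaired)."""
        s = np.sqrt(self.sigma2_a)
        return self.genetic_corr * np.outer(s, s)

    @property
    def residual_cov(self) -> np.ndarray:
        """Residual covariance matrix R0 (PD-repaired)."""
        s = np.sqrt(self.sigma2_e)
        return self.residual_corr * np.outer(s, s)

    def index(self, trait: str) -> int:
        return self.trait_names.index(trait)
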