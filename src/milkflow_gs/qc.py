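"""Marker quality control.

Three per-SNP filters, applied in the order call rate -> minor allele
frequency -> Hardy-Weinberg equilibrium, with strict boundaries: a marker is
removed iff call rate < 0.90, iff MAF < 0.05, iff the 1-d.f. Hardy-Weinberg
chi-square exceeds 300.  Allele frequencies and the HWE statistic use
non-missing calls only.  Each removed SNP is assigned the first reason that
triggers.  Post-QC missing calls are imputed with the mean dosage 2p, which
keeps column means (and hence the centering of the genomic relationship
matrix) unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the reference allele from non-missing calls.

    p_i = (sum of codes) / (2 * number of non-missing animals).  SNPs with
    all calls missing get NaN (they always fail the call-rate filter).
    """
    codes = genotypes.codes
    n_called = np.sum(~np.isnan(codes), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(codes, axis=0) / (2.0 * n_called)
    p[n_called == 0] = np.nan
    return p


def hwe_chi_square(n0: int, n1: int, n2: int) -> float:
    """1-d.f. Hardy-Weinberg goodness-of-fit chi-square on genotype counts.

    Expected counts are ``n * (q^2, 2pq, p^2)`` with ``p`` the reference
    (code-2) allele frequency; cells with expected count 0 contribute 0
    when the observed count is also 0 (a monomorphic SNP in perfect HWE
    scores 0).  No continuity correction.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("HWE test requires at least one called genotype")
    p = (2.0 * n2 + n1) / (2.0 * n)
    q = 1.0 - p
    exp = n * np.array([q * q, 2.0 * p * q, p * p])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = 0.0
    for o, e in zip(obs, exp):
        if e > 0:
            chi2 += (o - e) ** 2 / e
        elif o > 0:
            chi2 = np.inf
    return float(chi2)


def _hwe_chi_square_columns(codes: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square for every SNP column (NaN-aware)."""
    n0 = np.sum(codes == 0, axis=0).astype(float)
    n1 = np.sum(codes == 1, axis=0).astype(float)
    n2 = np.sum(codes == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2.0 * n2 + n1) / (2.0 * n)
        q = 1.0 - p
        exp = np.stack([n * q * q, n * 2.0 * p * q, n * p * p])
        obs = np.stack([n0, n1, n2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        terms = np.where((exp <= 0) & (obs > 0), np.inf, terms)
        chi2 = terms.sum(axis=0)
    chi2[n == 0] = np.nan
    return chi2


@dataclass
class QCReport:
    """Per-SNP QC metrics and the filtering outcome."""

    table: pd.DataFrame  # snp, call_rate, p, maf, hwe_chi2, kept, removal_reason

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def removal_counts(self) -> dict:
        counts = self.table["removal_reason"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in ("call_rate", "maf", "hwe", "none")}

    def removed(self, reason: str) -> list:
        t = self.table
        return list(t.loc[t["removal_reason"] == reason, "snp"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def qc_filter(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_chi2_max: float = 300.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three marker filters; returns the surviving panel + report.

    Filters are sequential (MAF and HWE are evaluated only for SNPs that
    pass the call-rate filter) and boundaries strict: removal iff
    ``call_rate < call_rate_min``, iff ``maf < maf_min``, iff
    ``chi2 > hwe_chi2_max``.
    """
    codes = genotypes.codes
    n_animals = genotypes.n_animals
    call_rate = np.sum(~np.isnan(codes), axis=0) / n_animals
    p = allele_frequencies(genotypes)
    maf = np.minimum(p, 1.0 - p)
    chi2 = _hwe_chi_square_columns(codes)

    reason = np.full(genotypes.n_snps, "none", dtype=object)
    reason[call_rate < call_rate_min] = "call_rate"
    ok = reason == "none"
    with np.errstate(invalid="ignore"):
        reason[ok & (maf < maf_min)] = "maf"
        ok = reason == "none"
        reason[ok & (chi2 > hwe_chi2_max)] = "hwe"
    kept = reason == "none"

    report = QCReport(pd.DataFrame({
        "snp": genotypes.snp_ids,
        "call_rate": call_rate,
        "p": p,
        "maf": maf,
        "hwe_chi2": chi2,
        "kept": kept,
        "removal_reason": reason,
    }))
    if not kept.any():
        warnings.warn("QC removed every SNP; the surviving panel is empty")
    return genotypes.subset_snps(kept), report


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the mean dosage 2 p_i of their SNP."""
    if genotypes.is_complete:
        return genotypes
    p = allele_frequencies(genotypes)
    codes = genotypes.codes.copy()
    miss = np.isnan(codes)
    codes[miss] = np.broadcast_to(2.0 * p, codes.shape)[miss]
    return GenotypeMatrix(genotypes.animal_ids.copy(), genotypes.snp_ids.copy(),
                          codes, genotypes.chrom.copy(), genotypes.pos.copy())
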