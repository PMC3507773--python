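"""Synthetic dairy population generator.

Emulates the data structure of a progeny-testing dairy scheme: overlapping
generations of AI sires, each with a cohort of phenotyped, non-genotyped
daughters (about 28 per sire), a 29-autosome SNP panel gene-dropped through
the pedigree, and six correlated milkability traits simulated from an
infinitesimal-plus-QTL additive model with the published heritabilities and
genetic/phenotypic correlations as defaults.

Layout of a simulated population with ``n_generations = G``:

* generation 0: founder males and founder females (unknown parents);
* generations ``1..G``: each male of generation ``g-1`` sires a cohort of
  daughters in generation ``g`` (cohort size drawn around the configured
  mean); new males are created in generations ``1..G-1`` with parents drawn
  from the previous generation.

All males therefore have daughter cohorts; males of generation ``G-1`` are
the youngest proven sires (daughters only, no descendant sires) and are the
natural validation set, mirroring an "older sires train, young sires
validate" split.

Every operation draws from an independent substream of the master seed, so
adding or re-running one stage never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree
from .traits import TraitParameters


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG substream derived from a master seed and a label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass
class SimulationConfig:
    """Population and marker-panel settings for the synthetic study.

    Defaults describe the reference desk-scale study: 4 generations with
    100 sires each (400 genotyped sires), 28 +/- 2.6 daughters per sire and
    a 1,000-SNP panel over 29 autosomes.
    """

    n_founder_sires: int = 100
    n_founder_dams: int = 3000
    n_generations: int = 4
    n_sires_per_generation: int = 100
    daughters_per_sire_mean: float = 28.0
    daughters_per_sire_sd: float = 2.6
    # young (terminal-generation) test bulls have only a first crop of
    # daughters; None disables the distinction.  This is what makes the
    # proven/young reliability split meaningful.
    young_sire_daughters_mean: float | None = 8.0
    young_sire_daughters_sd: float = 2.6
    n_snps: int = 1000
    n_chromosomes: int = 29
    founder_maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 100
    qtl_variance_fraction: float = 0.8
    missing_rate: float = 0.0
    linkage: bool = False
    chromosome_length_morgans: float = 1.0
    cg_size: int = 50
    cg_effect_var: float = 0.1
    trait_means: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founder_sires", "n_founder_dams", "n_generations",
                     "n_sires_per_generation", "n_snps", "n_chromosomes",
                     "cg_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_qtl < 0 or self.n_qtl > self.n_snps:
            raise ValueError("n_qtl must lie in [0, n_snps]")
        for name in ("missing_rate", "qtl_variance_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.daughters_per_sire_mean <= 0:
            raise ValueError("daughters_per_sire_mean must be positive")


def simulate_pedigree(config: SimulationConfig, rng_seed: int) -> Pedigree:
    """Simulate the multi-generation progeny-testing pedigree.

    Returns a topologically ordered pedigree; founders have unknown
    parents; every created male receives a daughter cohort in the next
    generation.
    """
    rng = substream(rng_seed, "pedigree")
    records = []  # (id, sire, dam, sex, gen)
    males = [f"G0M{k:04d}" for k in range(config.n_founder_sires)]
    females = [f"G0F{k:05d}" for k in range(config.n_founder_dams)]
    for m in males:
        records.append((m, "0", "0", "M", 0))
    for f in females:
        records.append((f, "0", "0", "F", 0))

    for g in range(1, config.n_generations + 1):
        prev_males, prev_females = males, females
        new_males, new_females = [], []
        # new sires for this generation (none in the terminal generation:
        # a male created there would never receive a daughter cohort)
        if g <= config.n_generations - 1:
            for k in range(config.n_sires_per_generation):
                mid = f"G{g}M{k:04d}"
                s = prev_males[rng.integers(len(prev_males))]
                d = prev_females[rng.integers(len(prev_females))]
                records.append((mid, s, d, "M", g))
                new_males.append(mid)
        # daughter cohorts of the previous generation's males; the
        # youngest (terminal-generation) sires get first-crop cohorts
        young = (g == config.n_generations and config.n_generations >= 2
                 and config.young_sire_daughters_mean is not None)
        mean = (config.young_sire_daughters_mean if young
                else config.daughters_per_sire_mean)
        sd = (config.young_sire_daughters_sd if young
              else config.daughters_per_sire_sd)
        counts = np.maximum(
            1, np.rint(rng.normal(mean, sd, len(prev_males))).astype(int)
        )
        total = int(counts.sum())
        # each dam contributes one daughter where the pool allows it
        if total <= len(prev_females):
            dams = rng.permutation(len(prev_females))[:total]
        else:
            dams = rng.integers(len(prev_females), size=total)
        k = 0
        pos = 0
        for si, s in enumerate(prev_males):
            for _ in range(counts[si]):
                fid = f"G{g}F{k:05d}"
                records.append((fid, s, prev_females[dams[pos]], "F", g))
                new_females.append(fid)
                k += 1
                pos += 1
        males, females = new_males if new_males else prev_males, new_females
    return Pedigree.from_records(records)


def sire_ids(pedigree: Pedigree) -> np.ndarray:
    """Ids of all males with at least one offspring (the genotyped set)."""
    has_offspring = np.zeros(len(pedigree), dtype=bool)
    has_offspring[pedigree.sire[pedigree.sire >= 0]] = True
    return pedigree.ids[(pedigree.sex == "M") & has_offspring]


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, rng_seed: int
) -> GenotypeMatrix:
    """Gene-drop a biallelic SNP panel through the pedigree.

    Founder haplotype alleles are Bernoulli draws at frequencies sampled
    from ``founder_maf_range`` (randomly assigned to either allele);
    offspring receive one gamete per parent.  By default loci segregate
    independently; with ``config.linkage`` the gamete strand follows a
    Markov chain along each chromosome with Haldane recombination
    fractions from the map positions.
    """
    rng = substream(rng_seed, "genotypes")
    n, m = len(pedigree), config.n_snps
    lo, hi = config.founder_maf_range
    maf = rng.uniform(lo, hi, m)
    flip = rng.random(m) < 0.5
    p = np.where(flip, 1.0 - maf, maf)

    chrom = (np.arange(m) * config.n_chromosomes) // m + 1
    pos = np.zeros(m, dtype=np.int64)
    cm_per_chrom = config.chromosome_length_morgans * 100.0
    for c in range(1, config.n_chromosomes + 1):
        on = chrom == c
        k = int(on.sum())
        if k:
            pos[on] = np.linspace(1, cm_per_chrom * 1e4, k).astype(np.int64)

    # recombination fraction between adjacent SNPs (Haldane); 0.5 across
    # chromosome boundaries and everywhere when loci are unlinked
    if config.linkage:
        d_morgan = np.diff(pos) / 1e6
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        r[np.diff(chrom) != 0] = 0.5
    else:
        r = np.full(m - 1, 0.5)

    hap = np.zeros((n, 2, m), dtype=np.uint8)
    founders = np.flatnonzero(pedigree.is_founder)
    hap[founders] = (rng.random((len(founders), 2, m)) < p).astype(np.uint8)

    def gamete(parent_row: np.ndarray) -> np.ndarray:
        switch = rng.random(m - 1) < r
        strand = np.zeros(m, dtype=np.int64)
        strand[0] = rng.integers(2)
        strand[1:] = switch
        strand = np.cumsum(strand) % 2
        return parent_row[strand, np.arange(m)]

    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            continue
        hap[i, 0] = gamete(hap[s]) if s >= 0 else (rng.random(m) < p)
        hap[i, 1] = gamete(hap[d]) if d >= 0 else (rng.random(m) < p)

    codes = hap.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = np.nan
    snps = np.array([f"SNP{j:05d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(pedigree.ids.copy(), snps, codes, chrom, pos)


def simulate_true_breeding_values(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    params: TraitParameters,
    config: SimulationConfig,
    rng_seed: int,
    mendelian_sampling: bool = True,
    inbreeding_adjusted: bool = True,
) -> pd.DataFrame:
    """True breeding values from an infinitesimal + QTL additive model.

    A fraction ``config.qtl_variance_fraction`` of the additive covariance
    is carried by ``config.n_qtl`` marker loci with multivariate-normal
    effects (rescaled so the realised founder QTL covariance matches the
    target exactly); the remainder is an infinitesimal component simulated
    down the pedigree as parent average plus a Mendelian-sampling deviation
    with covariance ``k * C_inf`` where ``k = 0.5 - 0.25 (f_s + f_d)``
    (plus 0.25 per unknown parent).

    Returns a DataFrame indexed by animal id, one column per trait.
    """
    rng = substream(rng_seed, "tbv")
    n, T = len(pedigree), params.n_traits
    C = params.genetic_cov
    frac = config.qtl_variance_fraction if config.n_qtl > 0 else 0.0

    tbv = np.zeros((n, T))
    if frac > 0:
        founders = pedigree.is_founder
        qtl = rng.choice(config.n_snps, size=config.n_qtl, replace=False)
        X = genotypes.codes[:, qtl]
        if np.any(np.isnan(X)):
            raise ValueError("QTL simulation requires complete genotypes")
        pbar = X[founders].mean(axis=0) / 2.0
        Xc = X - 2.0 * pbar
        het = np.sum(2.0 * pbar * (1.0 - pbar))
        B = rng.multivariate_normal(
            np.zeros(T), frac * C / max(het, 1e-12), size=config.n_qtl,
            method="cholesky",
        )
        U = Xc @ B
        # rescale so the realised founder QTL covariance equals frac * C
        # (skipped when too few founders to estimate it)
        if founders.sum() > T + 1:
            S = np.cov(U[founders], rowvar=False)
            if np.linalg.eigvalsh(S).min() > 1e-10:
                Ls = np.linalg.cholesky(S)
                Lt = np.linalg.cholesky(frac * C)
                U = U @ np.linalg.solve(Ls.T, Lt.T)
        U -= U[founders].mean(axis=0)
        tbv += U

    C_inf = (1.0 - frac) * C
    L = np.linalg.cholesky(C_inf + 1e-12 * np.eye(T))
    z = rng.standard_normal((n, T))
    inf = np.zeros((n, T))
    if inbreeding_adjusted:
        from .relationship import compute_inbreeding

        f = compute_inbreeding(pedigree).values
    else:
        f = np.zeros(n)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            inf[i] = z[i] @ L.T
            continue
        pa = np.zeros(T)
        k = 0.0
        for par in (s, d):
            if par >= 0:
                pa += 0.5 * inf[par]
                k += 0.25 * (1.0 - f[par])
            else:
                k += 0.25
        if mendelian_sampling:
            inf[i] = pa + np.sqrt(k) * (z[i] @ L.T)
        else:
            inf[i] = pa
    tbv += inf
    return pd.DataFrame(tbv, index=pedigree.ids, columns=list(params.trait_names))


def simulate_phenotypes(
    pedigree: Pedigree,
    tbv: pd.DataFrame,
    params: TraitParameters,
    config: SimulationConfig,
    rng_seed: int,
) -> pd.DataFrame:
    """One six-trait record per cow.

    Each non-founder female gets exactly one record:
    ``y = mean + contemporary-group effect + TBV + e`` with residuals
    multivariate normal under the (PD-repaired) residual covariance.
    Contemporary groups are formed within generation with about
    ``config.cg_size`` cows each; their effects are normal with variance
    ``config.cg_effect_var``, common to all traits of a group.

    Returns a DataFrame with columns ``id``, ``cg`` and one per trait.
    """
    rng = substream(rng_seed, "phenotypes")
    T = params.n_traits
    means = (np.zeros(T) if config.trait_means is None
             else np.asarray(config.trait_means, dtype=float))
    cows = np.flatnonzero((pedigree.sex == "F") & (pedigree.generation > 0))
    if len(cows) == 0:
        return pd.DataFrame(columns=["id", "cg", *params.trait_names])
    L = np.linalg.cholesky(params.residual_cov)
    e = rng.standard_normal((len(cows), T)) @ L.T

    cg_labels = np.empty(len(cows), dtype=object)
    cg_effects = {}
    gens = pedigree.generation[cows]
    for g in np.unique(gens):
        at = np.flatnonzero(gens == g)
        order = rng.permutation(at)
        n_groups = max(1, int(round(len(at) / config.cg_size)))
        for j, chunk in enumerate(np.array_split(order, n_groups)):
            label = f"G{g}C{j:03d}"
            cg_labels[chunk] = label
            cg_effects[label] = rng.normal(0.0, np.sqrt(config.cg_effect_var))
    cg_vals = np.array([cg_effects[c] for c in cg_labels])

    y = means + tbv.values[cows] + e + cg_vals[:, None]
    out = pd.DataFrame(y, columns=list(params.trait_names))
    out.insert(0, "cg", cg_labels)
    out.insert(0, "id", pedigree.ids[cows])
    return out


def degrade_genotypes(
    genotypes: GenotypeMatrix,
    missing_rate: float,
    n_monomorphic: int,
    n_hwe_violating: int,
    rng_seed: int,
) -> tuple[GenotypeMatrix, dict]:
    """Inject QC-triggering defects into a genotype matrix.

    Missing calls are injected uniformly at random; ``n_monomorphic`` SNPs
    are overwritten with a single code and ``n_hwe_violating`` SNPs with a
    half-0/half-2, zero-heterozygote pattern whose Hardy-Weinberg chi-square
    equals the number of animals (far above the 300 cut-off for the panel
    sizes used here).  Returns the degraded matrix and a dict of injected
    defect SNP ids.
    """
    if n_monomorphic + n_hwe_violating > genotypes.n_snps:
        raise ValueError("defect counts exceed the number of SNPs")
    rng = substream(rng_seed, "degrade")
    codes = genotypes.codes.copy()
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = np.nan
    chosen = rng.choice(genotypes.n_snps, n_monomorphic + n_hwe_violating,
                        replace=False)
    mono, hwe = chosen[:n_monomorphic], chosen[n_monomorphic:]
    codes[:, mono] = 0.0
    n = genotypes.n_animals
    half = n // 2
    for j in hwe:
        col = np.zeros(n)
        col[rng.permutation(n)[:half]] = 2.0
        codes[:, j] = col
    out = GenotypeMatrix(genotypes.animal_ids.copy(), genotypes.snp_ids.copy(),
                         codes, genotypes.chrom.copy(), genotypes.pos.copy())
    report = {
        "monomorphic": list(genotypes.snp_ids[np.sort(mono)]),
        "hwe_violating": list(genotypes.snp_ids[np.sort(hwe)]),
    }
    return out, report
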