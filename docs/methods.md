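# Methods

`milkflow-gs` implements a complete genomic-prediction study for six
milkability traits in dairy cattle — total milking time (TMT), ascending
time (AT), time of plateau (TP), descending time (DT), maximum milk flow
(MMF) and average milk flow (AVGF) — on synthetic populations that emulate
a medium-sized progeny-testing breed. This note documents the models, the
generator, the numerical choices and the design decisions that were
genuinely open.

## Variance components

Traits are analysed on a standardised scale (phenotypic variance 1 per
trait by default). The default heritabilities (TMT 0.42, AT 0.02, TP 0.32,
DT 0.05, MMF 0.11, AVGF 0.27) and the genetic/phenotypic correlation
matrices are published multi-trait estimates for Italian Brown Swiss.
Variance components are *inputs*: REML estimation is out of scope,
mirroring the original analysis where an external mixed-model package
estimated them.

The published genetic correlation matrix is not positive definite (its
smallest eigenvalue is about −1.22; for example MMF–AVGF = 0.95 and
MMF–TP = 0.85 are jointly incompatible with AVGF–TP = −0.84). Both the
genetic and the derived residual correlation matrix

    r_e(i,j) = (r_p(i,j) − r_g(i,j) h_i h_j) / sqrt((1−h²_i)(1−h²_j))

are repaired to the nearest positive-definite correlation matrix by
eigenvalue clipping (floor 1e−4) followed by re-standardisation to unit
diagonal, iterated to convergence. The repair is substantial (maximum
entrywise adjustment ≈ 0.51 for the genetic matrix, e.g. MMF–AVGF
0.95 → 0.50); `TraitParameters` records the adjustment magnitude and the
repaired matrices are the targets every simulator-fidelity check uses.
Whether the published AVGF–TP = −0.84 is a sign error is undecidable from
the source; the repair makes no assumption either way.

## Synthetic population

`simulate_pedigree` builds overlapping generations of AI sires: founders
(100 males, 3,000 females by default), then four generations in which each
proven sire receives a daughter cohort of 28 ± 2.6 phenotyped cows and
~100 new males per generation are bred from the previous one. Males of
the terminal sire generation are *young test bulls* with first-crop
cohorts of 8 ± 2.6 daughters (configurable; `None` disables the
distinction). This heterogeneity is essential: with uniform 28-daughter
cohorts the multi-trait reliabilities of proven and young sires are
indistinguishable and a reliability-threshold training/validation split
degenerates. Daughters' dams are drawn from the previous generation's
cows, one daughter per dam where the pool allows.

Genotypes are gene-dropped through the pedigree as phased haplotypes:
founder alleles are Bernoulli draws at frequencies sampled from the
configured MAF range (assigned to either allele at random) and offspring
receive one gamete per parent. Loci segregate independently by default
(the relationship-matrix methods do not require LD); optional linkage uses
Haldane recombination fractions from the 29-autosome map.

True breeding values follow an infinitesimal + QTL model. By default 80 %
of the additive covariance is carried by 100 marker loci with
multivariate-normal effects; the realised founder QTL covariance is
rescaled to match the target exactly, so marker-based methods have a
well-defined signal at desk scale. The remaining 20 % is an infinitesimal
component transmitted as parent average plus a Mendelian-sampling
deviation with covariance `k·C_inf`, `k = 0.5 − 0.25(f_s + f_d)`.
Phenotypes are one record per cow: overall mean + contemporary-group
effect (groups of ~50 within generation, normal effects with variance
0.1) + TBV + multivariate-normal residual.

What the generator does *not* emulate: selection (matings are random, so
there is no selection-induced disequilibrium or inbreeding trend),
genotyping errors, real LD structure, permanent-environment or maternal
effects, and heterogeneous herd recording. Passing tests therefore show
the estimators are correct and the pipeline behaves as the methodology
predicts under its own assumptions — not that the absolute reliabilities
transfer to any real breed.

Every stage draws from an independent, label-derived substream of one
master seed; identical seeds give identical outputs.

## Marker QC

Filters run in the order call rate → MAF → Hardy–Weinberg, each on the
surviving set, with strict boundaries (removed iff call rate < 0.90, MAF
< 0.05, χ² > 300 on 1 d.f., no continuity correction). Frequencies and
the HWE statistic use non-missing calls only; each removed SNP gets the
first triggering reason. Surviving missing calls are imputed with the
mean dosage `2p`, which is linear and leaves column means — and hence the
centring of G — unchanged.

## Relationship matrices

* Inbreeding: memoised kinship recursion, exactly the tabular-method
  diagonal minus one.
* `A⁻¹`: Henderson's rules with inbreeding
  (`d_i = 0.5 − 0.25(f_s + f_d)`), assembled sparse.
* `A22`: columns of A obtained by sparse solves against `A⁻¹`
  (Colleau-style), so the full dense A is never formed at study scale.
* `G = ZZ′ / (2Σp(1−p))` with 0/1/2 codes centred by `2p`. The source
  text centres by subtracting `2(p−0.5)` from 0/1/2 codes, which does not
  zero-centre; the `2p` centring is the algebraic intent (it is identical
  to −1/0/1 coding minus `2(p−0.5)`).
* Blending: `G_w = wG + (1−w)A22`, default `w = 0.9` (0.5/0.7 runnable),
  applied before inversion; no ridge by default. With frequencies
  estimated from the genotyped animals themselves G is exactly singular
  (`G·1 = 0`), so the unblended inverse exists only with external
  frequencies.
* `H⁻¹ = A⁻¹ + [0 0; 0 G_w⁻¹ − A22⁻¹]`, genotyped block located by id.

## Multi-trait BLUP

The animal model fits a contemporary-group fixed effect per trait (the
overall mean is absorbed; a CG×trait cell without records raises a
confounding error), additive effects with `var(u) = G0 ⊗ K`, and
residuals `R0` restricted per record to its observed-trait pattern
(missing traits are handled by inverting `R0` within each pattern,
equivalent to absent records). Equations are ordered trait-major and
solved by sparse LU with a symmetric fill-reducing ordering. Prediction
error variances come from unit-vector solves against the factorisation
for the animals where reliabilities are requested (all animals up to
~30,000 equations, an explicit id list beyond that — at study scale the
genotyped sires and their parents); reliability is
`1 − SEP²/((1+f)σ²_a)`, clipped to [0, 1].

Single-step HBLUP is literally the same model refit with `H⁻¹` in place
of `A⁻¹`, same variance components, so the degeneracy checks (no
genotyped animals, or `G := A22`) recover pedigree BLUP to numerical
precision.

## Deregression and weights

Deregression removes parent-average information and shrinkage from a
proof by reconstructing the 2×2 information system in (PA, EBV): with
`λ = (1−h²)/h²`, `α = 1/(0.5−r²_PA)`, `δ = (0.5−r²_PA)/(1−r²_i)`,

    Z′Z_PA = λ(0.5α−4) + 0.5λ√(α²+16/δ)
    Z′Z_i  = δ·Z′Z_PA + 2λ(2δ−1)

the right-hand sides are `M·(PA, EBV)` with
`M = [[Z′Z_PA+4λ, −2λ], [−2λ, Z′Z_i+2λ]]`, and `dEBV = y_i/Z′Z_i`,
`aPA = y_PA/Z′Z_PA`, `r²_dEBV = Z′Z_i/(Z′Z_i+λ)`,
`r²_aPA = Z′Z_PA/(Z′Z_PA+4λ)`. The inverse map (rebuild the information
contents from the reliabilities, solve M) reproduces the EBV exactly;
this round trip is tested over the whole parameter domain. The domain
requires `r²_PA < 0.5` and `r²_i > r²_PA`; at study level sires violating
it for a trait (no information beyond parents) are dropped from that
trait with a record of who was dropped. Stage-two records are weighted by
`w = (1−h²)/((c + (1−r²_dEBV)/r²_dEBV)h²)` with `c = 0.4` (fraction of
genetic variance not captured by markers), capped at 1e6. Traits are
deregressed independently; the two-stage models are univariate.

## Two-stage genomic models

All three stage-two models take training-sire dEBV with residual variance
`σ²_e/w_i` per record.

* **GBLUP**: mixed-model equations over all genotyped animals with
  `var(u) = G_w σ²_a` (`σ²_a` from the configuration, i.e. the
  complete-data value); validation animals obtain predictions through
  their G ties. On any fixture with unblended, invertible G and
  homogeneous weights this is algebraically the ridge-regression
  marker-effect model, verified to 1e−6.
* **BayesA**: per-marker normal effects, variances
  `σ²_gi ~ scaled-inv-χ²(ν, s²)` with both hyperparameters estimated:
  `s²` from its gamma full conditional `Gamma(0.5pν+1, 0.5νΣ1/σ²_gi)`
  truncated to `s ≤ 100` by rejection (honouring the uniform prior on `s`
  over (0, 100]; the flat-on-`s²` shape is used for the conditional, the
  simplest consistent treatment), and `ν` by random-walk Metropolis on
  `log ν` with a Jacobian-corrected acceptance ratio, proposals outside
  the prior interval (0, 1] rejected, and the step tuned to 20–50 %
  acceptance during burn-in. The (0, 1] default implies very heavy-tailed
  effect distributions; it is configurable but not second-guessed.
  The residual variance has a scaled-inv-χ² prior with 4 d.f. and
  expectation equal to the pedigree-BLUP residual variance.
* **Bayesian LASSO**: marker variances `σ²_gi = σ²_e τ²_i` with
  `1/τ²_i ~ InvGaussian(√(λ²σ²_e/β_i²), λ²)` and
  `λ² ~ Gamma(p+0.05, Στ²/2+1)` under the essentially flat Gamma(0.05, 1)
  hyperprior — the standard residual-scaled parameterisation; a single λ
  (per-marker λ_i is not identifiable). The σ²_e update is kept identical
  to BayesA's (residual sum of squares plus prior), a common
  simplification that ignores the marker-variance scaling term.

Both samplers share the machinery: a numba-compiled single-site sweep
over marker effects on a column-major genotype matrix (normal deviates
drawn outside the kernel, so chains are bit-reproducible), vectorised
variance updates from one `numpy` Generator, and thinned post-burn-in
means as posterior summaries. Geweke z-scores are reported, never
enforced; there is no convergence auto-stopping. Desk-scale chain
defaults are 20,000/5,000/thin 10 (the reference study uses
10,000/2,500); production analyses of this kind typically run far longer
chains.

DGV are centred genotypes times posterior-mean effects (same centring as
G). GEBV blend DGV with the adjusted parent average by selection index on
reliabilities assuming independent information,
`r²_GEBV = r²_DGV + r²_aPA − r²_DGV·r²_aPA`; the DGV reliability entering
the blend is estimated on the *training* set with the same realised-
reliability formula, keeping the validation set untouched.

## Evaluation

Realised validation reliability uses
`r²_PG = cov(dEBV, GEBV)² / (σ²_a·var(GEBV))` (n−1 denominators, clipped
to [0, 1]), isolated in one function because the printed source formula is
typographically garbled and alternatives may be swapped in. Note
`r²_PG = corr(dEBV, pred)²·var(dEBV)/σ²_a`: the scale factor
`var(dEBV)/σ²_a` is shared by all methods, so rankings are meaningful,
but in simulation it exceeds 1 (deregression inflates variance), which is
why HBLUP — whose EBVs use all data, including validation sires' own
daughters, exactly as a single-step evaluation does in practice — clips
at 1.0. The report therefore carries four complementary views: the
deregression-theory reliabilities (aPA, dEBV columns), the realised
`r²_PG` for every prediction *including* aPA (`aPA_realized`, the
like-for-like baseline), regression slopes and Pearson correlations of
validation dEBV on each method's predictions, and — simulation-only,
clearly labelled — squared correlations with the true breeding values.

The training/validation split assigns sires with EBV reliability strictly
above a per-trait threshold to training. The published thresholds
(0.50 for TP, 0.60 elsewhere) are the defaults of
`split_training_validation`; at study level the default is `"auto"`,
which places each trait's threshold at the midpoint between the mean
reliabilities of proven and young sires. The published absolute values
presume the source data's reliability scale and degenerate on simulated
populations (everything trains for five traits, nothing for DT); the
auto rule preserves the split's stated purpose — separating proven from
young sires by reliability.

Statistical ties between methods are called by a paired bootstrap of the
`r²_PG` difference over validation sires.

## Problem sizes and numerical tolerances

The reference study (4×100 sires, ~9,000 cows, ~12,500 animals, 1,000
SNPs, chains 10,000/2,500) solves ~79,000 mixed-model equations sparse;
it completes in a few minutes on one core, and the packaged test suite
runs the whole study once. Algebraic equivalences are asserted at 1e−6
to 1e−8; Monte-Carlo moment checks at 2 %; simulator fidelity at ±0.05
on correlations and realised heritabilities at n = 20,000. Matrix
positive-definiteness failures raise immediately with a hint to blend;
reliabilities are clipped to [0, 1] to absorb rounding.

## Known limitations

* The `r²_PG` scale issue above: absolute reliabilities from the
  realised formula are not comparable across datasets with different
  `var(dEBV)/σ²_a`; within-study comparisons are.
* Direct inversion-based SEP limits "reliabilities for everyone" to
  moderate systems; beyond that an explicit id list is required.
* Two-stage models are univariate; part of the single-step advantage in
  any such comparison stems from its multi-trait structure and its use of
  cow phenotypes, and the synthetic study reproduces (rather than
  removes) that confounding, as the source methodology does.
* The QTL-backed genetic architecture makes marker methods informative by
  construction; with a purely infinitesimal architecture and unlinked
  markers their edge over parent averages shrinks at this panel size.
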