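# milkflow-gs

Genomic prediction of **milkability traits** (milk-flow and milking-time
measures) in dairy cattle, built for quantitative geneticists who want to
compare classical and genomic evaluation methods on a population they can
fully control. The package simulates a medium-sized progeny-testing breed
— genotyped AI sires, each with a cohort of phenotyped, non-genotyped
daughters, and six correlated traits (total milking time TMT, ascending
time AT, time of plateau TP, descending time DT, maximum milk flow MMF,
average milk flow AVGF) — and runs the complete comparison:

1. **PBLUP** — six-trait animal model `y = Xb + Zu + e`,
   `var(u) = G₀ ⊗ A`, solved by Henderson's mixed-model equations; EBV,
   prediction error variances, reliabilities
   `r² = 1 − SEP²/((1+f)σ²ₐ)` and parent averages.
2. **Deregression** — dEBV free of parent-average information with
   Garrick-style weights `w = (1−h²)/((c + (1−r²)/r²)h²)`, `c = 0.4`.
3. **Two-stage genomic models** on training-sire dEBV:
   **GBLUP** with `G = ZZ′/2Σpᵢ(1−pᵢ)`, and two MCMC marker models for
   `y = 1μ + Xβ + e` — **BayesA** (`σ²gᵢ ~ scaled-inv-χ²(ν, s²)` with ν
   and s² estimated, ν via a Metropolis step) and the **Bayesian LASSO**
   (`σ²gᵢ` exponential mixing, single λ with Gamma(0.05, 1) hyperprior).
   DGV = Σ marker effects; GEBV = selection-index blend of DGV and the
   adjusted parent average.
4. **Single-step HBLUP** — the same six-trait model with
   `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]` (G blended with A22, weight 0.9).
5. **Evaluation** — validation-set reliabilities
   `r²_PG = cov(dEBV, GEBV)²/(σ²ₐ·var(GEBV))`, regression slopes and
   Pearson correlations of validation dEBV on each method's predictions,
   and (simulation-only) squared correlations with true breeding values.

Marker QC (call rate ≥ 0.90, MAF ≥ 0.05, Hardy–Weinberg χ² ≤ 300) and a
gene-dropping simulator with the published heritabilities and
genetic/phenotypic correlations round out the pipeline. See
`docs/methods.md` for models, assumptions and design decisions.

## Worked example

```python
import milkflow_gs as m

cfg = m.StudyConfig(
    simulation=m.SimulationConfig(
        n_founder_sires=20, n_founder_dams=600, n_generations=3,
        n_sires_per_generation=20, n_snps=300, n_qtl=80),
    mcmc=m.MCMCConfig(n_iter=2000, burn_in=500, thin=5),
)
report = m.run_full_study(cfg, seed=7)
print(report.truth_r2.round(2).to_string())
```

prints (squared correlation of each method's validation-sire predictions
with the simulated true breeding values; ~20 young validation sires per
trait, so individual cells are noisy at this toy scale):

```
       aPA  aPA_realized  dEBV  GBLUP  BayesA  BayesianLASSO  HBLUP
TMT   0.55          0.55  0.61   0.60    0.62           0.60   0.76
AT    0.40          0.40  0.58   0.45    0.41           0.04   0.75
TP    0.27          0.27  0.28   0.26    0.38           0.22   0.46
DT    0.13          0.13  0.28   0.11    0.20           0.00   0.43
MMF   0.46          0.46  0.50   0.54    0.53           0.27   0.71
AVGF  0.41          0.41  0.54   0.36    0.36           0.36   0.72
```

Reading it: parent averages (aPA) explain 13–55 % of the true genetic
variation among young bulls depending on the trait; adding marker
information helps, and the single-step model (HBLUP), which uses all cow
phenotypes and the genomic ties jointly, is the most reliable for every
trait — the qualitative pattern this methodology is known for.
`report.reliability` holds the same comparison on the realised
`r²_PG`-against-dEBV scale, and `report.slopes` / `report.correlations`
the regression diagnostics.

The same study runs from the shell:

```bash
milkflow-gs run-all --config study.yaml --seed 7 --out-dir out/
milkflow-gs simulate --seed 1 --out-dir sim/     # just the data
milkflow-gs qc sim/genotypes.tsv --out-prefix qc # just the marker filters
```

Model objects are available individually (statsmodels-style — construct
with data, `fit()` returns a results object):

```python
res = m.MultiTraitBLUP(phenotypes, pedigree, m.TraitParameters()).fit()
res.ebv; res.reliability; res.summary()
post = m.BayesA(debv, weights, genotypes, sigma2_e).fit(m.MCMCConfig())
post.beta; post.dgv(genotypes); post.geweke()
```

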