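# metgs — multi-environment trial genomic selection

`metgs` is a toolkit for breeders of perennial crops (its defaults emulate a
two-population robusta coffee program) who need to select genotypes that
combine **high phenotypic performance** with **environmental stability**
across harvest years and locations, and who want to know whether those
targets can be predicted from genome-wide SNP data.

It covers the full analysis chain:

1. **Trial adjustment** — fixed-effects models for randomized complete block
   designs nested in location x year environments
   (`Y = mu + G_i + E_j + B_k|E_j + GE_ij + e`), yielding empirical BLUEs
   (adjusted genotype means) per scenario of year combinations, plus variance
   components and entry-mean heritability
   `H2 = sigma2_G / (sigma2_G + sigma2_GE/E + sigma2_e/(E*B))` by exact
   ANOVA/EMS for balanced data or EM-REML otherwise.
2. **Stability** — AMMI
   (`Y_ij = mu + g_i + e_j + sum_n lambda_n gamma_in delta_jn + rho_ij`, via
   SVD of the double-centered interaction) with SPC and the AMMI stability
   value `ASV_i = sqrt((SS1/SS2 * s_i1)^2 + s_i2^2)` (lower = more stable),
   F-tests for the number of retained components; and Finlay–Wilkinson
   two-step regression (`Y_ij = mu + g_i + (1 + b_i) h_j + e_ij`), whose
   slope deviation `b_i ~ 0` marks a stable genotype.
3. **Genomic prediction** — hand-written Gibbs samplers for Bayesian ridge
   regression (BRR) and BayesB (spike-and-slab) on `y = mu + X beta + e`,
   with marker QC (missingness > 50%, non-biallelic, MAF < 1%, mean
   imputation) and three population parameterizations: SP (per-population
   fits), AP (pooled, shared effects), and MP (shared + population-specific
   effects, `beta_p = b0 + b_p`).
4. **Validation** — year-increment forecasting (train on accumulating
   harvests, predict held-out seasons), stratified k-fold cross-validation
   (predictive ability = Pearson r between observed adjusted means and
   GEBVs), performance–stability correlations, and top-fraction co-selection
   overlaps.
5. **Synthetic trials** — a generator whose defaults mirror the study design
   (103 + 118 clones, 2 locations x 4 harvests, 3 blocks, 56k SNPs) with
   additive genetics, bilinear and regression-type G-by-E (both genetically
   controlled by default), and residual variance solved to hit a target
   heritability; the generating truth is returned for recovery tests.

## Worked example

```python
from metgs import (GenomicModelConfig, ammi_decompose, ammi_stability, estimate_h2,
                   fit_multi_year, fit_single_year, fw_fit, prepare_two_way, qc_filter,
                   run_cv, select_overlap, simulate_markers, simulate_phenotypes,
                   stability_table, validate_phenotypes)
from metgs.simulate import SimulationConfig

cfg = SimulationConfig(n_genotypes_per_pop=(60, 60), n_markers=400, seed=42,
                       missing_rate=0.05)
markers = simulate_markers(cfg)
pheno, truth = simulate_phenotypes(markers, cfg)
pheno = validate_phenotypes(pheno)

pop1 = pheno[pheno["population"] == "pop1"]
blues = fit_multi_year(pop1, "YIELD", [2007, 2008, 2009, 2010])
vc = estimate_h2(pop1, "YIELD")

env_means = {env: fit_single_year(sub, "YIELD", env.split(":")[1],
                                  location=env.split(":")[0])
             for env, sub in pop1.groupby("environment")}
table, _ = prepare_two_way(env_means)
ammi = ammi_decompose(table)
stab = stability_table(ammi_stability(ammi, 2), fw_fit(table), trait="YIELD")

clean, report = qc_filter(markers)
mk1 = clean.subset(genotypes=list(blues.eblues.index))
cv = run_cv(blues.eblues, mk1, GenomicModelConfig(n_iter=2000, burn_in=500, seed=1),
            k=10, reps=2)
sel = select_overlap(blues.eblues, stab, direction="higher")
```

Output for this run:

```
entry-mean H2 = 0.79  (sigma2_G=0.92, sigma2_GE=0.51, sigma2_e=4.22)
mean adjusted yield = 20.15 +- 1.07
PC1+PC2 share of GxE sum of squares = 0.55
mean FW slope deviation = +2.16e-15
QC: 400/400 loci retained, 2448 calls imputed
10-fold CV predictive ability (BRR, yield): 0.52 +- 0.09  (20 fits)
10-fold CV predictive ability (BRR, FW stability): 0.05 +- 0.01
top-10% performers also in top-20% stable: FW 3, ASV 2, both 0
```

Reading the numbers: the trial carries usable genetic signal (entry-mean
heritability 0.79 with plot residuals four times the genetic variance); the
first two interaction axes explain 55% of the G-by-E sum of squares; the FW
slope deviations average exactly zero, as they must on a complete balanced
table. Yield itself is predicted with r = 0.52 from 400 SNPs; the FW
stability index of this small 60-clone population is barely predictable at
this panel size — stability prediction needs the larger designs used in
`scripts/acceptance.py`. Three of the six top performers are also in the
most stable 20% by FW slope, two by ASV, none by both — co-selection of
performance and stability is possible but restrictive.

## Command line

Every stage is also a CLI subcommand over a YAML run configuration:

```bash
metgs all --config run.yaml --out results_dir --seed 7
metgs stability --phenotypes plots.tsv --out stab_dir
```

```yaml
# run.yaml
seed: 7
simulation:
  n_genotypes_per_pop: [103, 118]
  n_markers: 2000
genomic:
  n_iter: 5000
  burn_in: 1000
trait_directions:
  YIELD: higher
cv_folds: 10
cv_reps: 5
```

Outputs are tab-separated tables (eBLUEs, stability indices, predictive
abilities, AMMI biplot coordinates) plus JSON (variance components, QC
report, selection overlaps) and a `manifest.json` recording the config hash,
seeds, stage timings and file checksums, so any output can be regenerated
from the manifest alone.

Phenotypes are long-format TSV/CSV
(`genotype, population, location, year, block, trait, value`); markers are
VCF (GT field, biallelic SNPs) or a dosage TSV.

## Layout

| module              | contents                                             |
| ------------------- | ---------------------------------------------------- |
| `metgs.simulate`    | trial generator + generating-truth record            |
| `metgs.adjust`      | eBLUEs, variance components, heritability            |
| `metgs.stability`   | AMMI (SPC/ASV), Finlay–Wilkinson                     |
| `metgs.predict`     | marker QC, BRR/BayesB Gibbs samplers, SP/AP/MP, GEBV |
| `metgs.evaluate`    | CV, year-increment, correlations, co-selection       |
| `metgs.markers`/`io`/`cli` | containers, file formats, pipeline, CLI       |

See `docs/methods.md` for the statistical models, priors, numerical choices
and the generator's assumptions.
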