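# Methods

This note records the statistical models implemented in `metgs`, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic generator does and does not emulate.

## Trial adjustment (`metgs.adjust`)

Plot data from a randomized complete block design replicated over
location x harvest-year environments are adjusted with fixed-effects OLS:

* single environment: `Y_ikr = mu + G_i + B_k + e_ik`;
* multiple environments:
  `Y_ijkr = mu + G_i + E_j + B_k|E_j + GE_ij + e_ijk`.

Identifiability uses sum-to-zero contrasts for every factor, and the
reported eBLUE is `mu_hat + G_hat_i` — the genotype mean marginal over
blocks and environments, which matches the "adjusted mean / lsMEANS"
convention (on balanced complete data it equals the raw genotype mean).
Missing plots are handled by least squares on the observed cells only, with
`numpy.linalg.lstsq`; a rank-deficient design yields the minimum-norm
(generalized-inverse) solution. A genotype observed in no environment shared
with the rest of the data makes the design disconnected; this is detected by
union-find on the genotype-environment incidence and reported as an error
naming the genotypes, because its main effect would be confounded with the
environment effects. Genotypes entirely absent from a scenario are excluded
and listed in `AdjustedMeans.excluded` rather than silently dropped.

### Variance components and heritability

The random-effects counterpart (genotype, environment, block-in-environment,
G-by-E random; intercept fixed) is solved two ways:

* **balanced complete designs** — closed-form expected-mean-squares (ANOVA)
  estimators, which coincide with REML inside the parameter space at
  balance; this makes large designs (hundreds of genotypes) instantaneous
  and exact;
* **unbalanced designs** — EM-REML on the dense mixed-model equations.
  Each iteration solves the MME by Cholesky and updates
  `sigma2_i <- (u_i'u_i + sigma2_e * tr(C^ii)) / q_i`,
  `sigma2_e <- (y'y - sol'W'y) / (n - 1)`. The REML log-likelihood
  `-2l = (n - q - 1) log sigma2_e + sum_i q_i log sigma2_i + log|A| + y'Py`
  is tracked per iteration and is non-decreasing (a property test asserts
  this). Convergence: maximum absolute parameter change relative to the
  *total* variance below 1e-8 (default) or 5000 iterations. The total-
  variance scaling matters: a component decaying geometrically toward its
  zero boundary has constant per-component relative change and would never
  converge under a per-component criterion. Negative solutions are floored
  at ~0 and flagged. The dense implementation is intended for the modest
  trial sizes it serves; it is not a sparse REML engine.

Entry-mean heritability is
`H2 = sigma2_G / (sigma2_G + sigma2_GE/E + sigma2_e/(E*B))` with E
environments and B blocks. Other plausible formulas exist (plot basis,
Cullis); the choice is isolated in `estimate_h2` so it can be swapped.

## Stability (`metgs.stability`)

### AMMI

`Y_ij = mu + g_i + e_j + sum_{n<=N} lambda_n gamma_in delta_jn + rho_ij`.
Main effects are marginal mean deviations; the double-centered residual is
decomposed by SVD. Conventions:

* sign: each genotype-score column's largest-magnitude element is made
  positive (environment scores follow), so results are deterministic across
  LAPACK backends;
* a constant (or purely additive) table yields all `lambda_n = 0` with zero
  scores and no exception;
* IPCA scores are `s_in = lambda_n^0.5 * gamma_in`. Consequently every
  stability index scales by `sqrt(c)` when the table is scaled by `c`;
  rankings are scale-invariant.

Indices: `SPC_i = sum_{n<=N} |s_in|` — absolute values, because a signed sum
can cancel opposing interaction axes and would break the "lower = more
stable" reading; and the AMMI stability value
`ASV_i = sqrt((SS_PC1/SS_PC2 * s_i1)^2 + s_i2^2)` with `SS_PCn = lambda_n^2`.
If the second component is null the ASV degenerates to `|s_i1|` and the
result is flagged.

**Number of components.** The default test is the sequential-residual
("leftover") F-test: after fitting N components, compare
`(sum_{m>N} lambda_m^2 / df_left)` against the plot-error mean square on a
cell-mean basis; N grows while the leftover is significant. Its null
behavior is correct by construction (measured: N = 0 in ~98% of pure-noise
tables at alpha = 0.05). The classical Gollob per-component test
(`df_n = g + e - 1 - 2n`) is available via `method="gollob"` but is
anticonservative for leading components, because `lambda_1^2` is the
*largest* eigenvalue of a noise matrix, not an average chi-square (measured
type-I ~19% at nominal 5%). The retained number is capped at 2 by default so
SPC/ASV are computed on the same axes for every trait.

### Finlay–Wilkinson

Two-step estimator exactly as classically defined: (1)
`h_hat_j = environment mean - grand mean`; (2) per-genotype OLS of `Y_ij` on
`h_hat_j`. The reported quantity is the slope deviation
`b_hat_i = slope - 1`; `|b_hat_i| ~ 0` marks a stable genotype, and a
genotype with constant response (slope 0, `b = -1`) is flagged
non-responsive. On any complete table the genotype-mean of `b_hat_i` is
exactly 0, because the average row regression reproduces the environment
means — this identity is an acceptance-level test. A Bayesian/shrinkage FW
variant is deliberately not the default: the two-step OLS is the estimator
being characterized.

Incomplete genotype x environment tables are completed before analysis:
either by dropping genotypes with missing cells (default, reported) or by EM
imputation that iteratively fills missing cells with the additive prediction
`mu + g + e` plus, optionally, a low-rank SVD term.

## Genomic prediction (`metgs.predict`)

Marker QC removes loci with missingness > 0.50, non-biallelic records, and
MAF < 0.01 (in that order, counts reported), then mean-imputes remaining
missing dosages — imputation by the locus mean preserves the allele
frequency and adds no spurious association.

Both samplers are single-site Gibbs kernels compiled with numba and are
bit-reproducible for a fixed seed (single-threaded). Markers are column-
centered; population intercepts absorb the means.

* **BRR**: `beta_j | rest ~ N(rhs/c, sigma2_e/c)` with
  `c = x_j'x_j + sigma2_e/sigma2_beta`; `sigma2_beta` and `sigma2_e` carry
  scaled-inverse-chi-square priors (df 5). Prior scales are solved from
  `prior_r2 = 0.5`: the prior mode of the marker-effect variance accounts
  for half the phenotypic variance (split equally across effect groups when
  several are present), the residual scale for the rest. With
  `update_variances=False` the posterior mean equals the closed-form ridge
  solution — the acceptance suite verifies agreement to 0.02 on a 50 x 20
  problem.
* **BayesB**: per-locus indicator sampled with the effect integrated out
  given the locus variance; included effects are conditionally normal;
  per-locus variances have a scaled-inverse-chi-square prior (marginally a
  scaled-t effect); the inclusion probability is Beta-updated
  (prior mean 0.5, 10 prior counts) unless pinned. Pinning the exclusion
  probability at 0 collapses the mixture (all loci in; effect estimates then
  track BRR's closely on well-conditioned data).

Chain defaults are 30,000 iterations, 5,000 burn-in, thinning 5; tests and
the acceptance script use 1,200–3,000 iterations, which the ridge-equivalence
and recovery checks show is ample for posterior means at these problem
sizes. Diagnostics: stored post-burn-in variance samples and a split-half
(Geweke-style) z per run.

**Population parameterizations.** SP fits each population separately. AP
row-stacks the populations with shared effects and per-population
intercepts. MP adds block-diagonal population-specific blocks so
`beta_p = b0 + b_p` holds exactly, each block with its own variance. The
shared block is centered on combined column means, the specific blocks
within their own population — otherwise centering would leak a population's
specific effects into the other population's rows. MP is implemented for the
BRR sampler (grouped variances); a spike-and-slab MP would require per-group
mixture priors and is out of scope.

GEBVs are `mu_hat_pop + X_centered beta_hat_pop`, exactly reconstructable
from the stored posterior means.

## Validation designs (`metgs.evaluate`)

* **Year increment**: eBLUEs from accumulating training years (scenarios
  with 1..6 harvests) train marker effects that predict the eBLUEs of two
  held-out later seasons; predictive ability is Pearson r per population.
* **Cross-validation**: k-fold (default 10) with repetitions (default 5),
  folds stratified by population and re-drawn per repetition from the
  repetition seed; one fit is logged per fold. Predictive ability is the
  pooled correlation of held-out predictions with observations after
  centering both within fold. The centering matters: on null data the
  uncentered pooled correlation is biased negative because each fold's
  predictions track its own training mean, which anti-correlates with the
  held-out fold mean; within-fold centering removes the artifact and leaves
  genuine signal untouched.
* **Co-selection**: top `floor(n*frac)` (minimum 1) genotypes by
  performance (direction must be declared per trait — no silent default),
  by lowest ASV, and by smallest |FW slope deviation|; ties break on
  genotype id so selections are deterministic.
* Performance-stability correlations use the *signed* FW slope deviation
  (the index as defined) and the ASV; significance stars at 0.05/0.01/0.001.

## Synthetic trials (`metgs.simulate`)

Plot model:
`Y = mu + g_i + (1 + b_i) h_j + block_k|j + [Gamma L Delta']_ij + e`.

* Markers: per-locus allele frequencies uniform on `maf_range`
  (default (0.05, 0.5]), Hardy–Weinberg dosage sampling, frequencies shared
  between the two populations (related material from a common program);
  missing calls MCAR at `missing_rate`.
* Genetics: marker effects standard normal (or spike-and-slab with
  `pi_zero`); a fraction `prop_specific_effects` (default 0.5) of loci carry
  additional population-specific effects, so the cross-population effect
  correlation is about 2/3 — two recognizably related but distinct breeding
  populations. Effects are rescaled once so the genetic SD is 1 trait unit.
* G-by-E: a rank-`gxe_rank` (default 2) bilinear term with double-centered
  orthonormal scores and geometrically decaying singular values scaled to a
  per-cell SD `gxe_sd` (default 0.7), plus an FW term `b_i h_j` with slope-
  deviation SD 0.3. Both are exposed independently so each estimator can be
  validated against its matched generating process. By default
  (`genetic_stability=True`) the FW slopes and bilinear genotype scores are
  linear functions of the marker dosages with their own effect vectors —
  stability is genetically controlled, which is the premise the prediction
  stages test. With the flag off they are drawn independently of the genome
  and stability prediction is null by construction.
* Noise: residual variance is solved from the realized genetic variance to
  hit the plot-level ratio `h2_target` (default 0.2, i.e. residual variance
  4x the genetic variance); under the default 8 environments x 3 blocks this
  produces entry-mean H2 around 0.8, in the upper-middle of the range
  reported for real multi-harvest coffee trials. `residual_sd` overrides the
  solution (0 gives noiseless plots for exact-recovery tests);
  `h2_target = 0` without an explicit residual SD is rejected as
  contradictory. Environment effects are N(0, 1) (mean-centered), block
  effects N(0, 0.25), overall mean 20 trait units (a plausible yield scale
  in 60-kg bags/ha).
* Defaults mirror the emulated study: populations of 103 and 118 clones,
  2 locations x 4 harvest years (environments are the fully crossed cells,
  serialized `LOC:YEAR`), 3 blocks, 56k SNPs. Tests and the acceptance
  script run the same structure with a few hundred to ~800 markers and
  shorter MCMC chains; those sizes are stated where used and keep every
  check comfortably reproducible on a single core.

What the generator does **not** emulate: linkage disequilibrium and genome
structure (loci are independent), pedigree relationships beyond shared
allele frequencies, spatial field trends, non-Gaussian trait scales
(disease scores are ordinal in reality), missing-not-at-random genotype
calls, and weather-driven environmental covariates. Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the pipeline under its assumed model — not robustness of the models to the
messiness of real field data.

## Powered test regimes

Two validation checks deliberately run away from study-like dimensions:

* the MP-vs-AP comparison uses 150 genotypes/population with 100 markers and
  high heritability, because population-specific effects must be estimable
  for the parameterizations to separate; at n << p the two models tie (a
  finding the real-data analyses echo);
* the BayesB recovery check plants 5 large-effect loci among 500 — variable
  selection is only identifiable when the signal is sparse and strong.

## Known limitations

* EM-REML is dense and O((g*e)^3) per iteration; very large unbalanced
  trials need a sparse REML engine instead.
* ASV, being an absolute score length, is poorly predictable by *linear*
  genomic models even when the underlying scores are fully genetic; the
  package reports what the data give rather than transforming the index.
* The fixed-effects adjustment treats G-by-E as a nuisance when estimating
  genotype main effects; no factor-analytic or kernel G-by-E prediction
  model is included.
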