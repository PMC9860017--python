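# Methods

This note records the statistical models implemented in `genarch`, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Genotype and LD model

`simulate.simulate_ld_panel` draws, per individual, two independent latent
haplotype vectors; within a block of `block_size` SNPs the latent Gaussians
share a correlation rho, and each latent value is thresholded at the
allele-frequency quantile to produce a haplotype allele. Genotypes are the
sum of the two haplotypes, hence Hardy–Weinberg consistent with exact
per-SNP allele frequency. `rho` may be a `(low, high)` range, in which case
each block draws its own correlation — this LD heterogeneity is essential:
with uniform LD every SNP has the same LD score and the score column is
collinear with the regression intercept, exactly as a one-block genome
would be unanalysable in practice.

The double thresholding attenuates the latent correlation; the realized
genotype correlation is measured empirically (a regression test pins the
value 0.621 for latent rho = 0.9 at a fixed seed), never assumed.

Limitations: no coalescent realism, no allele-frequency/LD coupling, no
population structure in the genotypes themselves. Passing tests therefore
demonstrate correctness of the estimators under their own model
assumptions, not robustness to demographic confounding.

## Simulated GWAS and the confounding intercept

`simulate.simulate_gwas` uses the infinitesimal-within-annotation model:
beta_j ~ N(0, sum_c a_c(j) * tau_c) on standardized genotypes, so the
LD-score regression expectation holds by construction. The phenotype is
scaled to unit variance and marginal z-scores are sqrt(N) times the sample
correlation.

The confounding knob is specified directly as the expected additive chi2
inflation (the `N*b` term). It is implemented as a shared per-individual
score `s = X R^{-1} 1`, which has the same covariance with every SNP
regardless of its LD — a stylised stratification axis. A naive choice such
as the mean genotype would instead inflate chi2 proportionally to the LD
score and load on tau rather than on the intercept; this was verified
empirically during development.

## Partitioned regression

`ldsc.regress_partitioned` fits chi2 on `{N * l(j,c)}` plus a free
intercept by weighted least squares. Defaults:

- **LD scores** use squared correlations including self-LD. When estimated
  from a finite panel of n individuals the standard adjustment
  `r2 - (1 - r2)/(n - 2)` removes the finite-sample bias. An unsquared
  "literal" mode exists solely for unit tests.
- **Weights** (mode `ldsc`): `1 / (l_base * (1 + N * h2bar * l_base / M)^2)`
  from a first-pass unweighted fit — the usual heteroskedasticity and
  over-counting corrections. `ols` mode (unweighted) backs the exactness
  oracles.
- **Inference**: contiguous-block delete-one jackknife, 200 blocks by
  default (the field's convention). h2 and tau* are jackknifed through the
  same delete-block fits. One-sided upper-tail p-values are the default for
  enrichment-direction hypotheses; two-sided values are always available.
- **h2** is reported as `sum_c tau_c * M_c` with `M_c = sum_k a_c(k)`,
  which equals the sum of fitted per-SNP variances and therefore does not
  double-count overlapping annotations.
- **Enrichment** is defined for binary annotations only (for continuous
  annotations tau* is the supported effect size); on disjoint partitions
  the SNP-share-weighted enrichments sum to exactly 1.
- **Conditional models** refit one focus annotation jointly with the
  baseline, one focus at a time. Significance is judged on tau: tau* is
  tau times a positive factor whose jackknife can degenerate when a
  delete-block h2 estimate crosses zero, so the tau z-score is the stable
  test statistic.

Per-replicate enrichment is a ratio of noisy quantities whose denominator
(h2-hat) can approach zero in modest simulations; consistency checks
therefore average the fitted coefficients over replicates before forming
the ratio.

## Fine-mapping

`finemap.compute_cpp` enumerates causal configurations up to K causal
variants (caps: 50 SNPs, K = 3) and scores each configuration C by the
density of z under `N(0, A + s^2 R_C R_C')` with `A = R + 1e-4 I` (ridge
for invertibility) via a Woodbury low-rank update. Defaults: non-centrality
scale s = 5.2 (a conventional value, exposed in config; calibration tests
use the design value `sqrt(n * h2_cis)` of the simulated studies, which is
what a practitioner would supply from study design); per-SNP prior 1/m per
configuration slot, multi-causal priors multiplying. The 95% credible set
operates at configuration level: configurations are accumulated by
descending posterior (ties broken by ascending SNP index) until the level
is reached, and every SNP in a retained configuration is a member.

Gene-level fine-mapping (`twas.gene_pip`) reuses the same machinery with
the predicted-expression correlation matrix in place of SNP LD, enumerates
*all* subsets up to the region size (cap 15 genes) including the null
configuration under a Bernoulli inclusion prior (default 1/g, capped just
below 1 so single-gene regions retain a null), and builds the 90%-credible
gene set by descending-PIP accumulation.

MaxCPP takes the maximum CPP over genes whose credible set contains the
SNP; an optional gene subset (e.g. constraint-depleted genes) filters
before the maximum, and one annotation column is built per QTL dataset with
an optional across-dataset maximum.

## TWAS

- **cis-h2 screen**: Haseman–Elston regression (off-diagonal expression
  products on genotype relatedness); permutation p-value with 200
  label permutations by default; genes failing p < 0.01 are excluded from
  weight fitting. This moment estimator is fast, unbiased, and adequate for
  a screen; it is noisier than REML.
- **Weights**: `top_eqtl` (indicator of the largest marginal chi2) and
  `ridge` with 5-fold cross-validated shrinkage over a grid scaled by the
  SNP count (the BLUP-optimal lambda is m(1-h2)/h2, so the grid spans
  m * 10^[-1, 2.5]). Below 25 individuals ridge falls back to top_eqtl
  with a warning. These two members span the sparse and dense ends of the
  usual predictive-model menu while remaining closed-form checkable.
- **Association**: `Z = w'z / sqrt(w'Rw)`, invariant to rescaling of w.
- **Stouffer weights**: proportional to effective sample size
  `N_eff = 4/(1/N_cases + 1/N_controls)`. This choice reproduces the
  published two-stage combined Z values used as worked examples at two
  decimals; `sqrt(N_eff)` and total-N modes are selectable.
- **Multiple testing**: Bonferroni at 0.05/(genes x tissues) plus BH-FDR.

## Rare-variant burden

- Variant classes: disruptive (frame-shift, splice-site, exon loss, stop
  gained, start loss, transcription ablation), damaging (missense,
  unanimously deleterious over *whatever* algorithm flags are supplied —
  the algorithm count is a property of the input), missense (the rest of
  missense), other. Unknown consequence terms classify as "other" with a
  logged warning rather than being dropped.
- Masks: MAF < 0.01 or < 0.005 crossed with the nested class families.
  External (gnomAD-style) allele frequency is used for masking when
  present, cohort frequency otherwise.
- Burden counts variant *sites* with at least one alternate allele
  (homozygotes count once); a dosage mode is available behind a flag.
  Transcripts with fewer than five non-zero-burden individuals are flagged
  excluded.
- Firth regression maximises the Jeffreys-penalised likelihood by Newton
  iteration with the hat-matrix score correction and step-halving;
  convergence failure raises an error carrying diagnostics. The reported
  p-value is the penalised likelihood-ratio test (a Wald p is also
  computed); confidence intervals default to profile penalised likelihood
  with Wald selectable — the profile interval is markedly more accurate
  for sparse tables and under separation.
- Cohorts combine by fixed-effect IVW meta-analysis of log-ORs; a single
  cohort passes through with a warning.

The rare-cohort generator assigns each gene at least one disruptive site
(so qualifying burden is never structurally empty), draws carriers as
Binomial(2, MAF) per variant with MAF log-uniform below 0.01, simulates
per-algorithm deleteriousness as exchangeable Bernoulli flags, and draws
case status prospectively from a logistic model whose intercept is solved
so the expected case fraction matches the requested arm sizes — realized
arm counts are therefore binomial around their targets. Sex (with a small
real effect) and null principal components mirror the covariates a real
analysis would include; the PCs carry no structure, so covariate
adjustment is exercised but population stratification is not.

## Problem sizes and tolerances

The validation suite uses: 50 GWAS replicates on a 3,000-individual,
2,000-SNP panel for tau recovery (mean within 10%, 95% jackknife CI
coverage at least 90%); 100 genes at n = 1,000 for cis-h2 recovery
(within 0.1 of 0.8); 200 cohort replicates with odds ratio 5 and roughly
35 carriers for Firth recovery (mean log-OR within 0.35 of log 5); 2,000
multivariate-normal draws for TWAS null calibration and 500 simulated null
genes for burden-chain type-I error (both within the binomial CI of 0.05);
and 500 single-causal regions for 95%-credible-set coverage (at least
93%). These sizes were chosen as the smallest at which the Monte-Carlo
error of each summary is comfortably inside its tolerance. Exactness
checks (noiseless regression recovery to 1e-8, enrichment conservation,
oracle equivalences to 1e-8..1e-12) are deterministic.

## Known limitations

- All inference assumes the generators' own models; no robustness claims
  about real stratification, imputation error, or allele-coding mistakes
  (allele harmonisation is expected upstream; matching is exact on A1/A2
  with an optional swap that negates z).
- Fine-mapping is exact-enumeration only: no stochastic search, so regions
  are capped at 50 SNPs / 15 genes.
- The Haseman–Elston screen and the two predictive-model menu are
  deliberate reductions of their heavier counterparts (REML; five-model
  ensembles) — sufficient to exercise the downstream statistics, not
  replacements at biobank scale.
- Real-data heritability partitions depend on external baseline annotation
  files and cohort genotypes that this package does not ship; its claims
  are about the correctness of the machinery, validated synthetically and
  against published worked examples.
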