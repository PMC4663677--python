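# Methods

## Association model and the fast scan

All *P* values come from the linear model `E_g ~ intercept + dosage + X`,
with `E_g` normalized log2 expression and `X` the covariate block. The
engine (`associate.assoc_scan_fast`) residualizes expression and dosage
against `[1, X]` once, then computes per pair the residual correlation
*r*, `beta = cov(d, E) / var(d)`, and `t = r sqrt(df) / sqrt(1 - r2)` with
`df = n - k - 2` (k covariate columns beyond the intercept, one more
degree for the genotype). By the Frisch–Waugh–Lovell theorem this equals
the genotype coefficient's *t* in the full OLS fit; `assoc_ols_oracle`
implements that full fit by explicit normal equations and the suite
asserts agreement to |Δt| < 1e-8 on every fixture. Two-sided *P* values
from the t distribution; pairs whose residual genotype has (numerically)
zero variance are flagged untestable and excluded from both results and
the Bonferroni denominator. Significance is `p < alpha / n_tests` with
one denominator per stage, pooled across intervals (stage 1) or genes
(stage 2); the conditional analysis reuses the stage-2 threshold rather
than recomputing a per-gene denominator, matching the design in which a
single constant governs both.

Expression principal components are estimated from the data and then
treated as fixed covariates; the df accounting ignores their estimation,
as matrix-eQTL-style engines do. The null-calibration and FWER checks
(criteria exercised in `tests/test_acceptance.py`) confirm this is
harmless at the cohort sizes used.

## Quality control

SNP filters run in a fixed order — duplicate physical position (first
copy kept), call rate < 0.95, Hardy–Weinberg exact *P* < 1e-5, MAF <
0.01 — and each removed SNP records the first rule it violated, so
reasons partition removals and the filter is idempotent. The HWE test is
the exact conditional test: given n individuals and the rare-allele
count, heterozygote counts follow `P(h) ∝ n! 2^h / (a! h! b!)`, and the
two-sided *P* sums all configurations no more probable than the observed
one. The implementation works in log space (`gammaln`) with a 1e-9
relative tie guard; the test oracle recomputes the same distribution in
exact big-integer arithmetic, and the two agree to < 1e-12 over every
configuration with n ≤ 200.

Genotype PCA standardizes dosage columns by `sqrt(p(1-p))`, mean-imputes
missing calls, and tests leading eigenvalues sequentially with the
Tracy–Widom (beta = 1) distribution after Patterson-style
effective-marker normalization. The TW tail is evaluated with the
shifted-gamma approximation (shape 46.446, scale 0.18605, shift 9.84801),
accurate to ~1e-4 in the CDF — ample for a 0.05 screen. Missing dosages
everywhere else are per-SNP mean-imputed (configurable drop is not
provided; the synthetic cohorts are generated clean).

## Normalization

`normalize_counts` is a smooth-offset stand-in for conditional quantile
normalization: per sample, `log2(count + 0.5)` is regressed on
`[1, gc, gc², log length]` by Huber IRLS (c = 1.345, 8 iterations, MAD
scale) and the fit subtracted. The per-sample intercept absorbs
sequencing depth, so no separate library-size factor is needed; the
removed component, times ln 2, is returned as the offset the NB GLM
consumes. The transform is validated by contract: a planted quadratic GC
artifact with per-sample |r| > 0.3 against GC drops below 0.05 after
normalization, and doubling one sample's depth moves its well-expressed
genes (count ≥ 20) by < 0.03 log2 units — the residual motion at low
counts comes from the +0.5 pseudo-count and is inherent to the transform.

Two finite-size effects matter when the gene panel is small, and both are
reasons the synthetic cohorts embed signal genes among many effect-free
genes (as a real transcriptome does):

* a strong cis effect on one gene of a small panel can claim > 1% of
  total expression variance, so the PC step promotes the dosage direction
  itself to a covariate and destroys power; with ≥ ~200 genes per planted
  effect the share is far below the threshold;
* the per-sample normalization fit (4 parameters on n_genes
  observations) leaks strong planted effects into every other gene
  through the intercept when genes are few.

## Negative-binomial sensitivity model

`nb_glm_assoc` fits a log-link NB GLM (statsmodels) with the
normalization offsets. The dispersion alpha (variance mu + alpha mu²) is
method-of-moments on Poisson-fit residuals, refined once against the NB
fit, clipped to [1e-8, 10]. Wald *P* values are normal-based. Under the
null the rejection rate at 0.05 sits in [0.02, 0.08] over 400 simulated
genes; with planted effects the NB and linear betas agree in sign for
≥ 95% of clearly significant genes, and as alpha → 0 the Wald statistic
converges to the Poisson GLM's (< 1% at size 1e6).

## LD, intervals and windows

LD is the squared Pearson correlation of unphased dosages on the cohort
itself, symmetric and flip-invariant. LD expansion keeps SNPs with
*r*² **strictly** greater than 0.5 (the printed threshold is an open
bound) within a 2 Mb search flank — the expansion radius is not stated by
the source analysis, and 2 Mb comfortably covers the cis windows used.
Risk SNPs merge into one interval when their LD spans (min–max position
of the LD set) overlap or abut, transitively; the merge is verified
against a union-find oracle. All in-memory coordinates are 1-based
inclusive; BED output converts to 0-based half-open at the file boundary.
Stage-1 windows are interval span ± 1 Mb with gene-overlap membership;
stage-2 windows are gene TSS/TES span ± 1.1 Mb with inclusive SNP
membership.

## Conditional analysis and classification

One round of conditioning only: the peak SNP (smallest *P*; ties broken
by larger |t|, then smaller position) is appended to the covariates and
the gene's window rescanned. SNPs with *r*² > 0.99 to the peak are
flagged untestable rather than fitted. A gene is *single*-domain when no
conditional test passes the (stage-2) threshold, *multiple* otherwise,
with a flag for residual signals in high LD (*r*² > 0.5) with a member
risk SNP. LD groups use risk-vs-peak *r*²: group 1 strictly > 0.5,
group 2 the closed band [0.2, 0.5], group 3 < 0.2 — the boundary value
0.5 goes to group 2 by convention, since the prose bands overlap at the
endpoints.

The minimal candidate-regulatory region replaces a visual read of the
regional association plot with an explicit rule: the span of all SNPs
within `drop_log10` (default 2) units of the peak's −log10 *P* **and** at
*r*² > `r2_link` (default 0.5) with the peak. Both knobs are exposed.
Note the default drop is tight relative to strongly powered synthetic
signals (peak −log10 *P* of 50+), where even *r*² ≈ 0.9 proxies sit more
than 2 units below the peak and the span degenerates to the peak position;
the widening-never-shrinks monotonicity is tested over a threshold grid.

## Synthetic cohort generator

Genotypes: per LD block, 8 founder haplotypes are built by a Markov walk
along SNPs (start frequency U(0.2, 0.8), per-SNP flip probability =
`mutation_rate`); each cohort haplotype copies a founder with per-SNP
switch probability `switch_rate` and copy error `mutation_rate`. Founders,
assignments and frequencies are redrawn at block boundaries, so LD is
high within blocks and ~0 across. Defaults (`mutation_rate` 0.015,
`switch_rate` 0.03) give mean adjacent *r*² ≈ 0.68 and ~20 SNPs above
*r*² 0.5 around a mid-block marker — a realistic tag-SNP neighbourhood.
Columns falling under the MAF floor are repaired by redrawing that
column's founder alleles (bounded attempts), and the post-repair
generating frequency is recorded so moments are checkable.

Expression: `counts[g,s] ~ NB(mean = L_s * A_g * exp(b_g + Σ beta d +
Σ w F), size_g)` with library factors log-normal (sd 0.3, geometric mean
1), GC/length artifact `A_g = exp(4(gc-0.5) - 6(gc-0.5)² + 0.5 log(len/20kb))`
(strong enough that raw counts correlate with GC at |r| > 0.3, giving the
normalizer a removable, known artifact), gene baselines N(5, 1) on the
natural-log scale (median count ~150), per-gene NB size U(8, 40), and
K = 3 latent standard-normal sample factors with N(0, 0.3) loadings
emulating the hidden variation the PC covariates must absorb. Betas are
natural-log effects per minor allele; the mapping to the normalized
(log2) scale is ≈ 1/ln 2 with mild curvature attenuation, and tests that
need the exact constant calibrate it from a single high-n run.

Risk-SNP scenarios pick a tag at a controlled realized *r*² to a causal
SNP — group 1 the strongest non-causal proxy, group 2 the SNP nearest
*r*² 0.35, group 3 nearest 0.1 within the gene's cis window, null a SNP
on an effect-free gene — with the realized value recorded. Interior
targeting keeps scenario labels away from band edges so grouping recovery
reflects the design rather than boundary jitter. Deliberate limitations
of the generator: no sequence-level reads, no imputation-uncertainty
dosages, one chromosome, no trans effects, and confounder magnitude is
chosen for testability (the real study's hidden-variation share is not
emulated) — so passing tests certify the statistical machinery, not
robustness to artifacts the generator does not produce.

## Problem sizes and determinism

Every simulation is seeded through `numpy.random.default_rng`; identical
seeds give bit-identical cohorts and byte-identical output tables. The
verification suite uses cohorts of 300–400 samples, panels of 100–1,200
SNPs and 10–800 genes: large enough that planted effects are
unambiguously powered (|t| ≳ 15) and null calibration is tight, small
enough that the whole suite runs in a few minutes on one CPU. The
acceptance script's synthetic study uses 400 samples × 1,200 SNPs × 500
genes with ten planted effects; FWER is estimated over 100 null cohorts
of 2,000 tests each.
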