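# riskeqtl

Two-stage, risk-SNP-anchored *cis*-eQTL mapping for assigning candidate
target genes to GWAS risk loci, with a synthetic-cohort generator that
makes every stage verifiable against a planted ground truth.

GWAS tag SNPs rarely identify the gene they act through. Given genotypes,
gene-level RNA-seq counts and a list of disease-risk SNPs, this package
asks, for each risk locus: *which nearby genes' expression tracks the risk
allele, is the expression signal the same signal as the risk association,
and how many independent regulatory inputs does each gene have?* It is
written for statistical geneticists who want the full pipeline —
QC, normalization, covariate construction, LD-interval building, both scan
stages, conditional analysis and reporting — as importable, tested
functions rather than a collection of one-off scripts.

## The model

Every association in the pipeline is the linear model

```
E_g = beta * d_s + X gamma + eps
```

where `E_g` is normalized expression of gene *g* (log2 counts corrected
for depth, GC content and gene length), `d_s` is the minor-allele dosage
(0/1/2) of SNP *s*, and `X` holds the covariates: histology fractions (if
supplied) and the expression principal components that each explain > 1%
of variance. The engine residualizes `E` and `d` against `X` once and
converts the residual correlation *r* to `t = r * sqrt(df) / sqrt(1 - r2)`
with `df = n - k - 2`; by the Frisch–Waugh–Lovell identity this is exactly
the full-model OLS *t* for `beta`, which the test suite verifies against a
per-pair normal-equations oracle to 1e-8.

The pipeline stages:

1. **QC** — drop SNPs with duplicate positions, call rate < 95 %, exact
   Hardy–Weinberg *P* < 1e-5, or MAF < 1 %; drop genes with median count
   < 14; genotype PCA with Tracy–Widom screening of eigenvalues.
2. **LD expansion** — each risk SNP pulls in all SNPs with *r*² > 0.5
   (squared Pearson correlation of dosages) within 2 Mb; risk SNPs with
   overlapping LD spans merge into one *risk interval*.
3. **Stage 1** — every (LD-SNP, gene within interval ± 1 Mb) pair is
   tested; Bonferroni over all pairs. Genes with a significant pair are
   *target genes*.
4. **Stage 2** — every SNP within ± 1.1 Mb of a target gene's TSS/TES
   (excluding stage-1 SNPs) is tested against that gene.
5. **Conditional analysis** — rescan each target gene with its peak SNP
   (smallest *P*) added to the covariates; genes with no surviving signal
   have a single regulatory domain.
6. **Reporting** — LD groups (risk-vs-peak *r*² > 0.5 → group 1,
   [0.2, 0.5] → group 2, < 0.2 → group 3), peak distance to TSS/TES, and
   a minimal candidate-regulatory-region span per gene.

A negative-binomial GLM with the normalization constants as offsets is
available (`nb_glm_assoc`) as a sensitivity check on the linear results.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(400 samples, 1,200 SNPs, 500 genes, ten planted cis effects tagged by
twelve risk SNPs spanning all three LD scenarios):

```sh
python analysis/01_simulate_cohort.py 1
python analysis/02_qc_and_normalize.py
python analysis/03_ld_intervals.py
python analysis/04_two_stage_scan.py
python analysis/05_conditional_and_groups.py
```

which prints, for the default seed:

```
12 risk SNPs -> 11 unique risk intervals, 62 risk+LD SNPs (r2 > 0.5)
stage 1: 15907 tests, Bonferroni threshold 3.14e-06, 48 significant pairs
  7/11 intervals with a signal -> 7 target genes
stage 2: 4768 tests, threshold 1.05e-05, 75 significant pairs
7 target genes with a peak eQTL signal
  single regulatory domain: 7/7 (100%)
  peaks within 20 kb of TSS/TES: 6/7
  LD groups (risk vs peak r2 >0.5 / [0.2,0.5] / <0.2): g1=4 / g2=3 / g3=0
```

Reading: of the twelve tag SNPs, the seven whose LD sets overlap a true
causal variant (the group-1 and group-2 scenarios) light up their planted
gene; the group-3 tags — deliberately placed at *r*² < 0.2 to the causal
SNP — lack the power to recover their gene through stage 1 alone, which
is exactly the behaviour the two LD-group extremes are designed to
contrast. Each recovered gene is correctly classified as
single-regulatory-domain (one causal SNP was planted per gene), and the
group labels match the designed scenarios. All tables (association TSVs,
interval BED, peak/group tables, per-gene regional tables) land under
`results/`.

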