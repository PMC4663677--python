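#!/usr/bin/env python
"""Genotype QC, expression filtering/normalization, and covariate PCs.

Reads results/cohort/, applies the SNP filters (call rate >= 95%, HWE
P >= 1e-5, MAF >= 1%, duplicate positions dropped), removes genes with
median count < 14, normalizes counts for depth/GC/length, selects
expression PCs explaining > 1% of variance each, and screens them against
global transcript abundance. Writes results/prep/.
"""

from pathlib import Path

import riskeqtl as rq
from riskeqtl import io

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "prep"
OUT.mkdir(parents=True, exist_ok=True)

G = io.read_vcf(BASE / "cohort" / "genotypes.vcf", reorient_minor=True)
genes = io.read_gene_gff3(BASE / "cohort" / "genes.gff3")
E = io.read_counts_tsv(BASE / "cohort" / "counts.tsv", genes)

cfg = rq.ScanConfig()
prep = rq.prepare_cohort(G, E, histology=None, cfg=cfg)

prep.qc_report.to_csv(OUT / "snp_qc_report.tsv", sep="\t", index=False)
prep.removed_genes.to_csv(OUT / "removed_genes.tsv", sep="\t", index=False)
io.write_covariates_tsv(prep.covariates.table, OUT / "covariates.tsv")

n_removed = int((~prep.qc_report["kept"]).sum())
print(f"SNP QC: kept {prep.genotypes.n_snp}/{G.n_snp} ({n_removed} removed)")
print(prep.qc_report.loc[~prep.qc_report["kept"], "reason"].value_counts().to_string())
print(f"genes: kept {prep.expression.n_genes}/{E.n_genes} after median<{cfg.median_min} filter")
pcs = [c for c in prep.covariates.table.columns if c.startswith("PC")]
ve = prep.covariates.variance_explained
print(f"covariates: {len(pcs)} expression PCs > {cfg.pc_var_min:.0%} variance "
      f"(cumulative {sum(ve.get(c, 0) for c in pcs):.0%})")
screen = rq.screen_covariates(prep.expression, prep.covariates.table, 1e-5)
screen.to_csv(OUT / "covariate_screen.tsv", sep="\t", index=False)
print(f"{int(screen['associated'].sum())}/{len(screen)} covariates associated with "
      "global expression (min linear-regression P < 1e-5)")
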