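#!/usr/bin/env python
"""Simulate the synthetic study cohort and write it in standard formats.

Generates a 400-sample cohort: an LD-structured genotype panel (VCF),
gene annotation (GFF3), NB expression counts with ten planted cis effects
(counts TSV), the generative truth table, and a 12-SNP risk list covering
the three LD-grouping scenarios plus null tags.

Writes results/cohort/ and prints what was planted.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import riskeqtl as rq
from riskeqtl import io
from riskeqtl.synth import ExpressionTruthConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(SEED)
G = rq.simulate_genotypes(400, 1200, 20, maf_min=0.05, seed=SEED, mean_spacing_bp=2000)
chrom_len = int(G.snp_meta["pos"].max()) + 100_000
genes = rq.simulate_gene_annotation(500, chrom_len, seed=SEED)

causal_idx = np.linspace(5, 495, 10).astype(int)
effects = {}
for gi in causal_idx:
    row = genes.iloc[gi]
    mid = (int(row["start"]) + int(row["end"])) // 2
    j = int((G.snp_meta["pos"] - mid).abs().idxmin())
    effects[row["id"]] = [(G.snp_meta["id"].iloc[j], float(rng.choice([-0.6, 0.6])))]
E, truth = rq.simulate_expression(G, genes, ExpressionTruthConfig(causal_effects=effects), seed=SEED + 1)

plan = (
    [("group1", genes["id"].iloc[gi]) for gi in causal_idx[:4]]
    + [("group2", genes["id"].iloc[gi]) for gi in causal_idx[4:7]]
    + [("group3", genes["id"].iloc[gi]) for gi in causal_idx[7:]]
    + [("null", None), ("null", None)]
)
rows = []
for k, (scen, gid) in enumerate(plan):
    try:
        rows.append(rq.simulate_risk_snps(G, truth, scen, seed=SEED * 100 + k, gene_id=gid))
    except rq.errors.GenerationFailureError as exc:
        print(f"  skipped one {scen} tag: {exc}")
risk = pd.concat(rows, ignore_index=True).drop_duplicates("risk_snp_id")

io.write_vcf(G, OUT / "genotypes.vcf")
io.write_gene_gff3(genes, OUT / "genes.gff3")
io.write_gene_bed(genes, OUT / "genes.bed")
io.write_counts_tsv(E, OUT / "counts.tsv")
io.write_truth_tsv(truth, OUT / "truth.tsv")
io.write_risk_snps_tsv(risk, OUT / "risk_snps.tsv")

print(f"cohort: {G.n_samples} samples, {G.n_snp} SNPs, {len(genes)} genes -> {OUT}")
print(f"planted {len(effects)} cis effects; {len(risk)} risk SNPs:")
print(risk[["risk_snp_id", "pos", "scenario", "target_gene", "realized_r2"]].to_string(index=False))
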