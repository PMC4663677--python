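#!/usr/bin/env python
"""Expand risk SNPs into LD-SNP sets and merge them into risk intervals.

Each risk SNP is expanded to all SNPs with r2 > 0.5 within 2 Mb; risk
SNPs whose LD spans overlap are combined into a single risk interval.
Writes the interval BED and a per-interval summary to results/intervals/.
"""

from pathlib import Path

import pandas as pd

import riskeqtl as rq
from riskeqtl import io

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "intervals"
OUT.mkdir(parents=True, exist_ok=True)

G = io.read_vcf(BASE / "cohort" / "genotypes.vcf", reorient_minor=True)
G, _ = rq.apply_snp_qc(G)
risk = io.read_risk_snps_tsv(BASE / "cohort" / "risk_snps.tsv")

cfg = rq.ScanConfig()
ld_sets = {
    rs: rq.expand_ld_set(G, rs, cfg.r2_expand, cfg.ld_search_flank)
    for rs in risk["risk_snp_id"]
}
intervals = rq.build_risk_intervals(
    list(risk["risk_snp_id"]), ld_sets, G.snp_meta, flank=cfg.flank_stage1
)

with open(OUT / "risk_intervals.bed", "w") as fh:
    for iv in intervals:
        fh.write(f"{iv.chrom}\t{iv.span_start - 1}\t{iv.span_end}\t{iv.interval_id}\t"
                 f"{','.join(iv.member_risk_snps)}\n")
summary = pd.DataFrame(
    [
        {
            "interval_id": iv.interval_id, "chrom": iv.chrom,
            "span_start": iv.span_start, "span_end": iv.span_end,
            "n_risk_snps": len(iv.member_risk_snps), "n_ld_snps": len(iv.ld_snp_ids),
        }
        for iv in intervals
    ]
)
summary.to_csv(OUT / "interval_summary.tsv", sep="\t", index=False)

n_ld = len(set().union(*(iv.ld_snp_ids for iv in intervals)))
print(f"{len(risk)} risk SNPs -> {len(intervals)} unique risk intervals, "
      f"{n_ld} risk+LD SNPs (r2 > {cfg.r2_expand})")
print(summary.to_string(index=False))
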