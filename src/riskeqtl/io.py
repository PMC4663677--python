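"""Readers and writers for the standard on-disk formats.

Coordinates on disk follow each format's convention: VCF and GFF3 are
1-based inclusive (matching the in-memory containers); BED is 0-based
half-open and converted at this boundary. The VCF writer emits the
minimal columns the pipeline needs (CHROM POS ID REF ALT GT); reading
uses cyvcf2 when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionCounts, GenotypeMatrix
from .errors import InvalidArgumentError

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_gene_gff3",
    "read_gene_gff3",
    "write_gene_bed",
    "write_covariates_tsv",
    "read_covariates_tsv",
    "write_risk_snps_tsv",
    "read_risk_snps_tsv",
    "write_truth_tsv",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal uncompressed VCF 4.2 with GT genotypes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for j, row in G.snp_meta.iterrows():
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./." for d in G.dosage[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path, *, reorient_minor: bool = False) -> GenotypeMatrix:
    """Read GT dosages of the alternate allele from a VCF.

    With ``reorient_minor=True``, SNPs whose alternate-allele frequency
    exceeds 0.5 in this cohort are flipped (d -> 2 - d) so dosages count
    the cohort minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        gt = np.asarray(var.genotypes, dtype=object)
        d = np.empty(len(sample_ids))
        for i, call in enumerate(gt):
            a, b = call[0], call[1]
            d[i] = np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        rows.append(d)
    dosage = np.array(rows).T if rows else np.empty((len(sample_ids), 0))
    if reorient_minor and dosage.size:
        freq = np.nanmean(dosage, axis=0) / 2.0
        flip = freq > 0.5
        dosage[:, flip] = 2.0 - dosage[:, flip]
    meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return GenotypeMatrix(dosage=dosage, snp_meta=meta, sample_ids=sample_ids)


def write_counts_tsv(E: ExpressionCounts, path: str | Path) -> None:
    """Genes-in-rows count table, header row = sample ids."""
    frame = pd.DataFrame(E.counts, index=E.gene_meta["id"], columns=E.sample_ids)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path, gene_meta: pd.DataFrame) -> ExpressionCounts:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = gene_meta.set_index("id").loc[frame.index].reset_index(names="id")
    return ExpressionCounts(
        counts=frame.to_numpy(dtype=np.int64),
        gene_meta=meta,
        sample_ids=list(frame.columns),
    )


def write_gene_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """GFF3 gene records carrying gc_fraction in the attributes column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            attrs = f"ID={r['id']};gc_fraction={r['gc_fraction']:.6f}"
            fh.write(
                f"{r['chrom']}\triskeqtl\tgene\t{r['start']}\t{r['end']}\t.\t"
                f"{r['strand']}\t.\t{attrs}\n"
            )


def read_gene_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            if ftype != "gene":
                continue
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            rows.append(
                {
                    "id": kv["ID"],
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "gc_fraction": float(kv.get("gc_fraction", "nan")),
                    "length_bp": int(end) - int(start),
                }
            )
    if not rows:
        raise InvalidArgumentError(f"no gene records in {path}")
    return pd.DataFrame(rows)


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED6 gene spans (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for _, r in genes.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['id']}\t0\t{r['strand']}\n"
            )


def write_covariates_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_risk_snps_tsv(risk: pd.DataFrame, path: str | Path) -> None:
    risk.to_csv(path, sep="\t", index=False)


def read_risk_snps_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"risk_snp_id", "chrom", "pos"}
    if not required <= set(frame.columns):
        raise InvalidArgumentError(f"risk-SNP table needs columns {sorted(required)}")
    return frame


def write_truth_tsv(truth, path: str | Path) -> None:
    """Flat per-gene truth table (one row per gene, causal SNPs joined)."""
    rows = []
    for i, r in truth.gene_meta.iterrows():
        effects = truth.causal_effects.get(r["id"], [])
        rows.append(
            {
                "gene_id": r["id"],
                "baseline_log_mean": truth.baseline_log_mean[i],
                "dispersion_size": truth.dispersion_size[i],
                "causal_snp_ids": ",".join(s for s, _ in effects),
                "causal_betas": ",".join(f"{b:.6g}" for _, b in effects),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
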