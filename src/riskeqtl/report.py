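"""Target-gene LD grouping, peak position profiling, minimal-region
estimation and tabular output.

Group bands (risk SNP vs peak SNP r-squared): group 1 strictly > 0.5,
group 2 the closed band [0.2, 0.5], group 3 < 0.2. The minimal candidate
regulatory region is an explicit surrogate for reading a regional
association plot: the span of all SNPs both within ``drop_log10`` units
of the peak's -log10 P and in LD (r2 > ``r2_link``) with the peak.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ASSOC_COLUMNS,
    GenotypeMatrix,
    RiskInterval,
    ScanConfig,
    gene_tss_tes,
)
from .errors import InvalidArgumentError
from .ld import ld_r2_matrix

__all__ = [
    "classify_gene_group",
    "peak_distance_profile",
    "estimate_minimal_region",
    "build_gene_group_records",
    "write_results",
]


def classify_gene_group(r2_risk_peak: float) -> int:
    """LD group of a target gene from risk-SNP vs peak-SNP r-squared."""
    if not 0 <= r2_risk_peak <= 1:
        raise InvalidArgumentError("r2 must be in [0,1]")
    if r2_risk_peak > 0.5:
        return 1
    if r2_risk_peak >= 0.2:
        return 2
    return 3


def peak_distance_profile(
    peaks: pd.DataFrame, genes: pd.DataFrame, proximity_bp: int = 20_000
) -> pd.DataFrame:
    """Position of each peak SNP relative to its gene's TSS/TES.

    ``peaks`` needs columns gene_id, peak_snp_id, peak_pos. Reports the
    minimum absolute distance to either anchor, a proximity flag, and a
    normalized coordinate in which the gene body spans 0 (TSS) to 100
    (TES) regardless of its true length; positions outside the body are
    reported as negative bp upstream of the TSS or 100 + bp downstream of
    the TES.
    """
    gm = genes.set_index("id")
    tss_all, tes_all = gene_tss_tes(genes)
    tss_of = dict(zip(genes["id"], tss_all))
    tes_of = dict(zip(genes["id"], tes_all))
    rows = []
    for _, row in peaks.iterrows():
        gid = row["gene_id"]
        pos = int(row["peak_pos"])
        tss, tes = int(tss_of[gid]), int(tes_of[gid])
        d_tss, d_tes = pos - tss, pos - tes
        frac = (pos - tss) / (tes - tss) if tes != tss else 0.0
        if 0.0 <= frac <= 1.0:
            body = 100.0 * frac
        elif frac < 0.0:  # upstream of the TSS: flank in bp, negative
            body = -float(abs(d_tss))
        else:  # downstream of the TES: flank in bp past 100
            body = 100.0 + float(abs(d_tes))
        min_dist = min(abs(d_tss), abs(d_tes))
        rows.append(
            {
                "gene_id": gid,
                "peak_snp_id": row["peak_snp_id"],
                "peak_pos": pos,
                "dist_tss": d_tss if gm.loc[gid, "strand"] == "+" else -d_tss,
                "dist_tes": d_tes if gm.loc[gid, "strand"] == "+" else -d_tes,
                "min_dist": int(min_dist),
                "within_proximity": bool(min_dist <= proximity_bp),
                "normalized_coord": float(body),
            }
        )
    return pd.DataFrame(rows)


def estimate_minimal_region(
    results: pd.DataFrame,
    peak_snp: str,
    G: GenotypeMatrix,
    drop_log10: float = 2.0,
    r2_link: float = 0.5,
) -> tuple[int, int]:
    """Minimal genomic span of the peak signal for one gene.

    Covers every SNP whose -log10 P is within ``drop_log10`` of the
    peak's and whose r2 with the peak exceeds ``r2_link``; degenerates to
    the peak position when nothing else qualifies. Widening either
    threshold can only widen the span.
    """
    if drop_log10 < 0:
        raise InvalidArgumentError("drop_log10 must be >= 0")
    row = results[results["snp_id"] == peak_snp]
    if row.empty:
        raise InvalidArgumentError("peak SNP absent from results")
    peak_logp = -np.log10(float(row["p_value"].iloc[0]))
    peak_pos = int(row["snp_pos"].iloc[0])

    logp = -np.log10(results["p_value"].to_numpy(dtype=float))
    near_peak = logp >= peak_logp - drop_log10
    dosage = G.imputed_dosage()
    cols = [G.snp_index(s) for s in results["snp_id"]]
    r2 = ld_r2_matrix(dosage[:, cols], dosage[:, G.snp_index(peak_snp)])
    linked = np.nan_to_num(r2, nan=0.0) > r2_link
    qual = near_peak & linked
    positions = results["snp_pos"].to_numpy(dtype=int)[qual]
    positions = np.append(positions, peak_pos)
    return int(positions.min()), int(positions.max())


def build_gene_group_records(
    peaks: pd.DataFrame,
    gene_to_interval: dict[str, RiskInterval],
    combined_results: pd.DataFrame,
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Per-target-gene grouping table.

    For each gene: the member risk SNP of its originating interval with
    maximal r2 to the peak, the LD group from that r2, signed
    transcription-oriented distances of the peak to TSS/TES, and the
    minimal-region span.
    """
    cfg = cfg or ScanConfig()
    dosage = G.imputed_dosage()
    tss_all, tes_all = gene_tss_tes(genes)
    tss_of = dict(zip(genes["id"], tss_all))
    tes_of = dict(zip(genes["id"], tes_all))
    strand_of = dict(zip(genes["id"], genes["strand"]))
    rows = []
    for _, pk in peaks.iterrows():
        gid = pk["gene_id"]
        peak_snp = pk["peak_snp_id"]
        iv = gene_to_interval[gid]
        peak_col = dosage[:, G.snp_index(peak_snp)]
        risk_cols = [G.snp_index(s) for s in iv.member_risk_snps]
        r2 = np.nan_to_num(ld_r2_matrix(dosage[:, risk_cols], peak_col), nan=0.0)
        best = int(np.argmax(r2))
        best_risk = iv.member_risk_snps[best]
        r2_best = float(r2[best])
        sign = 1 if strand_of[gid] == "+" else -1
        peak_pos = int(pk["peak_pos"])
        gene_results = combined_results[combined_results["gene_id"] == gid]
        region = estimate_minimal_region(
            gene_results, peak_snp, G, cfg.minimal_region_drop_log10, cfg.minimal_region_r2_link
        )
        rows.append(
            {
                "gene_id": gid,
                "interval_id": iv.interval_id,
                "best_risk_snp_id": best_risk,
                "peak_snp_id": peak_snp,
                "r2_risk_peak": r2_best,
                "group": classify_gene_group(r2_best),
                "dist_risk_to_peak": abs(G.position(best_risk) - peak_pos),
                "dist_peak_to_tss": sign * (peak_pos - int(tss_of[gid])),
                "dist_peak_to_tes": sign * (peak_pos - int(tes_of[gid])),
                "region_start": region[0],
                "region_end": region[1],
            }
        )
    return pd.DataFrame(rows)


def write_results(
    outdir: str | Path,
    *,
    cfg: ScanConfig,
    seed: int,
    stage1: pd.DataFrame | None = None,
    stage2: pd.DataFrame | None = None,
    conditional: pd.DataFrame | None = None,
    intervals: list[RiskInterval] | None = None,
    peaks: pd.DataFrame | None = None,
    groups: pd.DataFrame | None = None,
    regional: dict[str, pd.DataFrame] | None = None,
) -> dict[str, str]:
    """Write every pipeline table and a run manifest; returns the manifest.

    Association TSVs are 1-based; the interval BED is converted to
    0-based half-open on disk. Re-running on identical inputs reproduces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {"config_hash": cfg.config_hash(), "seed": str(seed)}

    def _tsv(frame: pd.DataFrame, name: str, columns=None) -> None:
        path = outdir / name
        out = frame if columns is None else frame[columns]
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest[name] = str(path)

    for frame, name in ((stage1, "stage1_associations.tsv"), (stage2, "stage2_associations.tsv"),
                        (conditional, "conditional_associations.tsv")):
        if frame is not None:
            cols = [c for c in ASSOC_COLUMNS if c in frame.columns]
            _tsv(frame, name, cols if cols else None)
    if intervals is not None:
        path = outdir / "risk_intervals.bed"
        with open(path, "w") as fh:
            for iv in intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.span_start - 1}\t{iv.span_end}\t{iv.interval_id}\t"
                    f"{','.join(iv.member_risk_snps)}\n"
                )
        manifest["risk_intervals.bed"] = str(path)
    if peaks is not None:
        _tsv(peaks, "peaks.tsv")
    if groups is not None:
        _tsv(groups, "gene_groups.tsv")
    if regional:
        regdir = outdir / "regional"
        regdir.mkdir(exist_ok=True)
        for gid, frame in sorted(regional.items()):
            p = regdir / f"{gid}.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.10g")
            manifest[f"regional/{gid}.tsv"] = str(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
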