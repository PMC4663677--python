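"""End-to-end orchestration of the two-stage risk-SNP eQTL analysis.

Thin glue over the stage modules: cohort preparation (QC, filtering,
normalization, covariate PCs), LD-interval construction, the stage-1 and
stage-2 scans, and the peak-conditioned classification. Each step is also
usable on its own; these helpers fix the data flow the analysis scripts
and the acceptance checks share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associate import stage1_scan, stage2_scan
from .datatypes import (
    CovariateTable,
    ExpressionCounts,
    GenotypeMatrix,
    NormalizedExpression,
    PeakRecord,
    RiskInterval,
    ScanConfig,
)
from .errors import NoPeakError
from .expression import expression_pcs, filter_genes, make_covariate_table, normalize_counts
from .ld import Window, build_risk_intervals, expand_ld_set, snps_in_window
from .peaks import classify_domains, conditional_scan, find_peak
from .qc import QcThresholds, apply_snp_qc
from .report import build_gene_group_records, peak_distance_profile

__all__ = ["PreparedCohort", "TwoStageResult", "prepare_cohort", "run_two_stage", "run_conditional"]


@dataclass
class PreparedCohort:
    genotypes: GenotypeMatrix
    qc_report: pd.DataFrame
    expression: NormalizedExpression
    removed_genes: pd.DataFrame
    covariates: CovariateTable | None


@dataclass
class TwoStageResult:
    intervals: list[RiskInterval]
    stage1: pd.DataFrame
    interval_summary: pd.DataFrame
    target_genes: list[str]
    gene_to_interval: dict = field(default_factory=dict)
    stage2: pd.DataFrame | None = None

    def combined(self) -> pd.DataFrame:
        if self.stage2 is None or self.stage2.empty:
            return self.stage1
        return pd.concat([self.stage1, self.stage2], ignore_index=True)

    def stage2_threshold(self) -> float:
        if self.stage2 is not None and len(self.stage2):
            return float(self.stage2["threshold_used"].iloc[0])
        return float(self.stage1["threshold_used"].iloc[0]) if len(self.stage1) else np.nan


def prepare_cohort(
    G: GenotypeMatrix,
    E: ExpressionCounts,
    histology: pd.DataFrame | None = None,
    cfg: ScanConfig | None = None,
) -> PreparedCohort:
    """SNP QC, gene filtering, normalization and covariate assembly."""
    cfg = cfg or ScanConfig()
    thr = QcThresholds(
        call_rate_min=cfg.callrate_min, hwe_p_min=cfg.hwe_min, maf_min=cfg.maf_min
    )
    G_qc, qc_report = apply_snp_qc(G, thr)
    E_f, removed = filter_genes(E, cfg.median_min)
    N = normalize_counts(E_f)
    pcs, var_exp = expression_pcs(N, cfg.pc_var_min)
    hist = None
    if histology is not None:
        hist = histology.reset_index(drop=True)
        hist.index = pcs.index
    covars = make_covariate_table(hist, pcs, var_exp) if len(pcs.columns) or hist is not None else None
    return PreparedCohort(G_qc, qc_report, N, removed, covars)


def run_two_stage(
    G: GenotypeMatrix,
    N: NormalizedExpression,
    covars: CovariateTable | None,
    risk_snp_ids: list[str],
    cfg: ScanConfig | None = None,
) -> TwoStageResult:
    """LD expansion, interval construction, and both scan stages."""
    cfg = cfg or ScanConfig()
    ld_sets = {
        rs: expand_ld_set(G, rs, cfg.r2_expand, cfg.ld_search_flank) for rs in risk_snp_ids
    }
    intervals = build_risk_intervals(risk_snp_ids, ld_sets, G.snp_meta, flank=cfg.flank_stage1)
    stage1, summary = stage1_scan(G, N, covars, intervals, cfg)

    target_genes: list[str] = []
    gene_to_interval: dict[str, RiskInterval] = {}
    iv_by_id = {iv.interval_id: iv for iv in intervals}
    for _, row in summary.iterrows():
        for gid in row["target_genes"]:
            if gid not in gene_to_interval:
                target_genes.append(gid)
                gene_to_interval[gid] = iv_by_id[row["interval_id"]]

    result = TwoStageResult(
        intervals=intervals,
        stage1=stage1,
        interval_summary=summary,
        target_genes=target_genes,
        gene_to_interval=gene_to_interval,
    )
    if target_genes:
        stage1_snps = set().union(*(iv.ld_snp_ids for iv in intervals))
        result.stage2 = stage2_scan(G, N, covars, target_genes, stage1_snps, cfg)
    return result


def run_conditional(
    G: GenotypeMatrix,
    N: NormalizedExpression,
    covars: CovariateTable | None,
    two_stage: TwoStageResult,
    cfg: ScanConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Peak finding, peak-conditioned rescans and domain/group tables.

    Returns the peaks frame (with domain classification), the per-gene
    conditional result frames, and the gene-group table.
    """
    cfg = cfg or ScanConfig()
    combined = two_stage.combined()
    cond_threshold = two_stage.stage2_threshold()
    peak_rows = []
    conditional: dict[str, pd.DataFrame] = {}
    for gid in two_stage.target_genes:
        gene_results = combined[combined["gene_id"] == gid]
        try:
            peak_snp = find_peak(gene_results)
        except NoPeakError:
            continue
        peak_row = gene_results[gene_results["snp_id"] == peak_snp].iloc[0]
        iv = two_stage.gene_to_interval[gid]
        gm = N.gene_meta.set_index("id").loc[gid]
        lo = min(int(gm["start"]), int(gm["end"])) - cfg.flank_stage2
        hi = max(int(gm["start"]), int(gm["end"])) + cfg.flank_stage2
        win = Window(str(gm["chrom"]), max(1, lo), hi, gid)
        window_snps = list(snps_in_window(G.snp_meta, win)["id"])
        cond = conditional_scan(
            G, N, covars, gid, peak_snp, window_snps, cfg,
            conditional_threshold=cond_threshold,
        )
        conditional[gid] = cond
        rec = PeakRecord(
            gene_id=gid,
            peak_snp_id=peak_snp,
            peak_p=float(peak_row["p_value"]),
            peak_beta=float(peak_row["beta"]),
            conditional_threshold=cond_threshold,
        )
        rec = classify_domains(cond, rec, iv.member_risk_snps, G)
        peak_rows.append(
            {
                "gene_id": gid,
                "peak_snp_id": peak_snp,
                "peak_pos": int(peak_row["snp_pos"]),
                "peak_p": rec.peak_p,
                "peak_beta": rec.peak_beta,
                "conditional_threshold": cond_threshold,
                "residual_significant_snps": rec.residual_significant_snps,
                "domain_class": rec.domain_class,
                "residual_high_ld_with_risk": rec.residual_high_ld_with_risk,
            }
        )
    peaks = pd.DataFrame(peak_rows)
    groups = pd.DataFrame()
    if len(peaks):
        groups = build_gene_group_records(
            peaks, two_stage.gene_to_interval, combined, G, N.gene_meta, cfg
        )
        profile = peak_distance_profile(peaks, N.gene_meta, cfg.peak_proximity_bp)
        peaks = peaks.merge(
            profile[["gene_id", "min_dist", "within_proximity", "normalized_coord"]],
            on="gene_id",
        )
    return peaks, conditional, groups
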