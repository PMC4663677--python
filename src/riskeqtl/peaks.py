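"""Peak eQTL identification, peak-conditioned rescans, and regulatory-domain
classification.

The peak signal for a gene is its smallest-P significant SNP across the
combined stage-1/stage-2 results. Conditioning appends the peak SNP's
dosage to the covariate matrix and rescans the gene's window; any SNP
that stays Bonferroni-significant marks an independent regulatory domain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .associate import assoc_scan_fast, residualize, with_intercept
from .datatypes import (
    ASSOC_COLUMNS,
    CovariateTable,
    GenotypeMatrix,
    NormalizedExpression,
    PeakRecord,
    ScanConfig,
)
from .errors import InvalidArgumentError, NoPeakError
from .ld import ld_r2_matrix

__all__ = ["find_peak", "conditional_scan", "classify_domains"]


def find_peak(results: pd.DataFrame) -> str:
    """Most strongly associated significant SNP for one gene.

    Smallest P wins; ties are broken by larger |t|, then by smaller
    genomic position, so the choice is deterministic and invariant to
    input order.
    """
    if results["gene_id"].nunique() > 1:
        raise InvalidArgumentError("find_peak expects results for a single gene")
    sig = results[results["significant"]]
    if sig.empty:
        raise NoPeakError("gene has no significant association")
    ranked = sig.assign(abs_t=sig["t_stat"].abs()).sort_values(
        ["p_value", "abs_t", "snp_pos"], ascending=[True, False, True], kind="stable"
    )
    return str(ranked.iloc[0]["snp_id"])


def conditional_scan(
    G: GenotypeMatrix,
    N: NormalizedExpression,
    C: CovariateTable | None,
    gene_id: str,
    peak_snp: str,
    window_snp_ids: list[str],
    cfg: ScanConfig | None = None,
    *,
    conditional_threshold: float,
) -> pd.DataFrame:
    """Rescan a gene's window with the peak SNP added as a covariate.

    SNPs nearly collinear with the peak (r2 > ``cfg.peak_collinear_r2``)
    are flagged untestable and excluded; the peak itself is never tested.
    The significance threshold is the (globally reused) stage-2 Bonferroni
    threshold, passed in as ``conditional_threshold``.
    """
    cfg = cfg or ScanConfig()
    peak_col = G.dosage[:, G.snp_index(peak_snp)]
    if np.nanvar(peak_col) == 0:
        raise InvalidArgumentError("peak SNP has zero dosage variance")
    snp_ids = [s for s in window_snp_ids if s != peak_snp]
    if not snp_ids:
        return pd.DataFrame(columns=ASSOC_COLUMNS + ["snp_col", "gene_col"])
    cols = [G.snp_index(s) for s in snp_ids]
    dosage = G.imputed_dosage()

    r2_peak = ld_r2_matrix(dosage[:, cols], dosage[:, G.snp_index(peak_snp)])
    keep = np.nan_to_num(r2_peak, nan=1.0) <= cfg.peak_collinear_r2
    cols = [c for c, k in zip(cols, keep) if k]
    if not cols:
        return pd.DataFrame(columns=ASSOC_COLUMNS + ["snp_col", "gene_col"])

    base = with_intercept(C, G.n_samples)
    peak_imputed = dosage[:, G.snp_index(peak_snp)]
    design = np.column_stack([base, peak_imputed])
    n_cov = design.shape[1] - 1
    G_res = residualize(dosage[:, cols], design)
    e = N.gene_values(gene_id)
    E_res = residualize(e[:, None], design)

    pairs = np.column_stack([np.arange(len(cols)), np.zeros(len(cols), dtype=int)])
    frame, _ = assoc_scan_fast(G_res, E_res, n_cov, pairs)
    frame["snp_id"] = [G.snp_meta.loc[c, "id"] for c in (cols[i] for i in frame["snp_col"])]
    frame["chrom"] = [G.snp_meta.loc[c, "chrom"] for c in (cols[i] for i in frame["snp_col"])]
    frame["snp_pos"] = [int(G.snp_meta.loc[c, "pos"]) for c in (cols[i] for i in frame["snp_col"])]
    frame["gene_id"] = gene_id
    frame["stage"] = "conditional"
    frame["threshold_used"] = conditional_threshold
    frame["significant"] = frame["p_value"] < conditional_threshold
    frame["snp_col"] = [cols[i] for i in frame["snp_col"]]
    return frame[ASSOC_COLUMNS + ["snp_col", "gene_col"]]


def classify_domains(
    conditional_results: pd.DataFrame,
    peak: PeakRecord,
    risk_snp_ids: list[str],
    G: GenotypeMatrix,
) -> PeakRecord:
    """Complete a PeakRecord from the conditional rescan.

    ``single`` when no conditional result passes the conditional
    threshold, ``multiple`` otherwise; flags whether any residual
    significant SNP is in high LD (r2 > 0.5) with a member risk SNP of
    the gene's originating interval.
    """
    sig = (
        conditional_results[conditional_results["significant"]]
        if len(conditional_results)
        else conditional_results
    )
    n_sig = int(len(sig))
    peak.residual_significant_snps = n_sig
    peak.domain_class = "multiple" if n_sig > 0 else "single"
    peak.residual_high_ld_with_risk = False
    if n_sig and risk_snp_ids:
        dosage = G.imputed_dosage()
        sig_cols = [G.snp_index(s) for s in sig["snp_id"]]
        for rs in risk_snp_ids:
            r2 = ld_r2_matrix(dosage[:, sig_cols], dosage[:, G.snp_index(rs)])
            if np.nan_to_num(r2, nan=0.0).max() > 0.5:
                peak.residual_high_ld_with_risk = True
                break
    return peak
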