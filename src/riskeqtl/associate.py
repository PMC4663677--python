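"""The association engine: residualization, fast matrix scans, Bonferroni
control, the two-stage cis scans, and the negative-binomial sensitivity model.

The fast scan reproduces the residualize-then-correlate computation used
by matrix eQTL engines: genotype dosage and normalized expression are both
residualized against the covariates, the per-pair residual correlation r
is converted to t = r * sqrt(df) / sqrt(1 - r^2) with df = n - k - 2
(k covariate columns beyond the intercept), which by the
Frisch–Waugh–Lovell identity equals the genotype t-statistic of the full
OLS fit with all covariates included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datatypes import (
    ASSOC_COLUMNS,
    AssociationResult,
    CovariateTable,
    GenotypeMatrix,
    NormalizedExpression,
    RiskInterval,
    ScanConfig,
)
from .errors import CollinearityError, ConvergenceError, InvalidArgumentError
from .ld import genes_in_window, make_windows, snps_in_window

__all__ = [
    "residualize",
    "assoc_scan_fast",
    "assoc_ols_oracle",
    "bonferroni_threshold",
    "stage1_scan",
    "stage2_scan",
    "nb_glm_assoc",
]

_VAR_EPS = 1e-12


def _check_full_rank(C: np.ndarray) -> None:
    q, r = np.linalg.qr(C)
    diag = np.abs(np.diag(r))
    bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        raise CollinearityError(
            f"covariate matrix is rank deficient at columns {bad.tolist()}", columns=bad
        )


def residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out covariates column-wise: M - C (C'C)^-1 C'M.

    ``C`` must include the intercept and be full column rank; rows align
    with ``M``. Idempotent, and the residual columns are orthogonal to
    every covariate column.
    """
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    if M.shape[0] != C.shape[0]:
        raise InvalidArgumentError("M and C must have aligned rows")
    _check_full_rank(C)
    beta = np.linalg.lstsq(C, M, rcond=None)[0]
    return M - C @ beta


def with_intercept(C: CovariateTable | np.ndarray | None, n: int) -> np.ndarray:
    """Covariate design matrix with a leading intercept column."""
    ones = np.ones((n, 1))
    if C is None:
        return ones
    mat = C.matrix() if isinstance(C, CovariateTable) else np.asarray(C, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] != n:
        raise InvalidArgumentError("covariate rows must match sample count")
    return np.hstack([ones, mat])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise InvalidArgumentError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0,1)")
    return alpha / n_tests


def assoc_scan_fast(
    G_resid: np.ndarray,
    E_resid: np.ndarray,
    n_covariates: int,
    pairs: np.ndarray,
    *,
    chunk: int = 50_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Vectorized per-pair association on residualized matrices.

    Parameters
    ----------
    G_resid, E_resid
        Samples x SNPs and samples x genes matrices, both residualized
        against the same covariates (intercept included).
    n_covariates
        Number of covariate columns beyond the intercept; the residual
        degrees of freedom are ``n - n_covariates - 2``.
    pairs
        Integer array (n_pairs, 2) of (snp column, gene column) indices.

    Returns a frame with beta (expression change per allele), se, t and
    two-sided P per testable pair, and the boolean mask of untestable
    pairs (zero-variance residual genotype), which are excluded from the
    frame and from any test count.
    """
    G_resid = np.asarray(G_resid, dtype=float)
    E_resid = np.asarray(E_resid, dtype=float)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    n = G_resid.shape[0]
    df = n - n_covariates - 2
    if df < 1:
        raise InvalidArgumentError("residual degrees of freedom must be >= 1")

    Sgg = np.einsum("ij,ij->j", G_resid, G_resid)
    See = np.einsum("ij,ij->j", E_resid, E_resid)
    untestable = Sgg[pairs[:, 0]] <= _VAR_EPS * n

    beta = np.empty(len(pairs))
    se = np.empty(len(pairs))
    t = np.empty(len(pairs))
    for lo in range(0, len(pairs), chunk):
        sl = slice(lo, lo + chunk)
        si, gi = pairs[sl, 0], pairs[sl, 1]
        Sge = np.einsum("ij,ij->j", G_resid[:, si], E_resid[:, gi])
        sgg = Sgg[si]
        see = See[gi]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = Sge / np.sqrt(sgg * see)
            r = np.clip(r, -1.0, 1.0)
            b = Sge / sgg
            one_m_r2 = np.maximum(1.0 - r**2, 1e-300)
            tt = r * np.sqrt(df) / np.sqrt(one_m_r2)
            s = np.sqrt(see / sgg) * np.sqrt(one_m_r2 / df)
        beta[sl], se[sl], t[sl] = b, s, tt
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)

    ok = ~untestable
    frame = pd.DataFrame(
        {
            "snp_col": pairs[ok, 0],
            "gene_col": pairs[ok, 1],
            "beta": beta[ok],
            "se": se[ok],
            "t_stat": t[ok],
            "p_value": p[ok],
            "n_samples": n,
        }
    )
    return frame, untestable


def assoc_ols_oracle(
    g: np.ndarray, e: np.ndarray, C: np.ndarray | None = None
) -> AssociationResult:
    """Full-design OLS association for one SNP-gene pair.

    Fits e ~ intercept + g + C by normal equations with residual df
    n - k - 2 (k covariate columns) and returns the genotype
    coefficient's beta/se/t/P. Serves as the independent verification
    path for the fast scan.
    """
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    n = g.shape[0]
    cov = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = np.column_stack([np.ones(n), g, cov])
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise CollinearityError("design matrix singular (genotype collinear with covariates)")
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ e)
    resid = e - X @ coef
    df = n - cov.shape[1] - 2
    if df < 1:
        raise InvalidArgumentError("not enough residual degrees of freedom")
    sigma2 = (resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(max(2 * stats.t.sf(abs(t), df), np.finfo(float).tiny))
    return AssociationResult(
        snp_id="", gene_id="", beta=beta, se=se, t_stat=float(t),
        p_value=p, n_samples=n, stage="oracle",
    )


def _attach_meta(
    frame: pd.DataFrame,
    snp_meta: pd.DataFrame,
    gene_ids: pd.Series,
    stage: str,
) -> pd.DataFrame:
    frame = frame.copy()
    frame["snp_id"] = snp_meta["id"].to_numpy()[frame["snp_col"]]
    frame["chrom"] = snp_meta["chrom"].to_numpy()[frame["snp_col"]]
    frame["snp_pos"] = snp_meta["pos"].to_numpy()[frame["snp_col"]]
    frame["gene_id"] = gene_ids.to_numpy()[frame["gene_col"]]
    frame["stage"] = stage
    return frame


def _finalize(frame: pd.DataFrame, threshold: float) -> pd.DataFrame:
    frame = frame.copy()
    frame["threshold_used"] = threshold
    frame["significant"] = frame["p_value"] < threshold
    return frame[ASSOC_COLUMNS + ["snp_col", "gene_col"]]


def stage1_scan(
    G: GenotypeMatrix,
    N: NormalizedExpression,
    C: CovariateTable | None,
    intervals: list[RiskInterval],
    cfg: ScanConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary risk-interval scan: LD-SNPs x genes in the interval window.

    Tests every (LD-SNP, expressed gene overlapping the interval's
    ±flank_stage1 window) pair; deduplicated across intervals for the
    Bonferroni denominator, which counts only testable pairs. Returns the
    association frame (stage=1) and a per-interval summary with its
    significant target genes.
    """
    cfg = cfg or ScanConfig()
    design = with_intercept(C, G.n_samples)
    n_cov = design.shape[1] - 1
    G_res = residualize(G.imputed_dosage(), design)
    E_res = residualize(N.values.T, design)  # samples x genes
    gene_ids = N.gene_meta["id"]

    pair_set: dict[tuple[int, int], None] = {}
    interval_pairs: dict[str, list[tuple[int, int]]] = {}
    windows = make_windows(intervals, "stage1", cfg.flank_stage1)
    for iv, win in zip(intervals, windows):
        snp_cols = [G.snp_index(s) for s in iv.ld_snp_ids]
        genes = genes_in_window(N.gene_meta, win)
        cols = list(genes.index)
        plist = [(sc, gc) for sc in snp_cols for gc in cols]
        interval_pairs[iv.interval_id] = plist
        for pr in plist:
            pair_set[pr] = None

    pairs = np.array(list(pair_set), dtype=int).reshape(-1, 2)
    if len(pairs) == 0:
        empty = pd.DataFrame(columns=ASSOC_COLUMNS + ["snp_col", "gene_col"])
        summary = pd.DataFrame(
            {
                "interval_id": [iv.interval_id for iv in intervals],
                "n_tests": 0,
                "any_significant": False,
                "target_genes": [[] for _ in intervals],
            }
        )
        return empty, summary

    frame, untestable = assoc_scan_fast(G_res, E_res, n_cov, pairs)
    n_tests = int((~untestable).sum())
    threshold = bonferroni_threshold(cfg.alpha, max(n_tests, 1))
    frame = _attach_meta(frame, G.snp_meta, gene_ids, stage="1")
    frame = _finalize(frame, threshold)

    sig_pairs = set(
        zip(frame.loc[frame["significant"], "snp_col"], frame.loc[frame["significant"], "gene_col"])
    )
    rows = []
    for iv in intervals:
        plist = interval_pairs[iv.interval_id]
        sig = [pr for pr in plist if pr in sig_pairs]
        target_genes = sorted({gene_ids.iloc[gc] for _, gc in sig})
        rows.append(
            {
                "interval_id": iv.interval_id,
                "n_tests": len(plist),
                "any_significant": bool(sig),
                "target_genes": target_genes,
            }
        )
    return frame, pd.DataFrame(rows)


def stage2_scan(
    G: GenotypeMatrix,
    N: NormalizedExpression,
    C: CovariateTable | None,
    target_genes: list[str],
    stage1_snp_ids: set[str],
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Gene-centric second-stage scan around each target gene.

    For each target gene, tests every SNP within ±flank_stage2 of the
    gene's TSS/TES span that was not part of the stage-1 LD-SNP analysis;
    one Bonferroni threshold over the total stage-2 test count.
    """
    cfg = cfg or ScanConfig()
    if not target_genes:
        raise InvalidArgumentError("target_genes must be nonempty")
    design = with_intercept(C, G.n_samples)
    n_cov = design.shape[1] - 1
    G_res = residualize(G.imputed_dosage(), design)
    E_res = residualize(N.values.T, design)
    gene_ids = N.gene_meta["id"]
    excluded = set(stage1_snp_ids)

    genes = N.gene_meta[N.gene_meta["id"].isin(target_genes)]
    windows = make_windows(genes, "stage2", cfg.flank_stage2)
    pairs = []
    for win in windows:
        gc = int(N.gene_meta.index[N.gene_meta["id"] == win.ref_id][0])
        snps = snps_in_window(G.snp_meta, win)
        for idx, sid in zip(snps.index, snps["id"]):
            if sid not in excluded:
                pairs.append((int(idx), gc))
    if not pairs:
        return pd.DataFrame(columns=ASSOC_COLUMNS + ["snp_col", "gene_col"])
    pairs = np.array(pairs, dtype=int)
    frame, untestable = assoc_scan_fast(G_res, E_res, n_cov, pairs)
    n_tests = int((~untestable).sum())
    threshold = bonferroni_threshold(cfg.alpha, max(n_tests, 1))
    frame = _attach_meta(frame, G.snp_meta, gene_ids, stage="2")
    return _finalize(frame, threshold)


def nb_glm_assoc(
    counts_g: np.ndarray,
    g: np.ndarray,
    C: np.ndarray | None,
    offsets: np.ndarray,
    *,
    max_alpha: float = 10.0,
) -> AssociationResult:
    """Negative-binomial GLM sensitivity fit for one gene.

    Log-link NB with the normalization constants as an offset; the
    overdispersion alpha (variance mu + alpha mu^2) is estimated by
    method of moments on Poisson-fit residuals and refined once against
    the NB fit. Returns the genotype coefficient's Wald beta/se/P.
    """
    y = np.asarray(counts_g, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise InvalidArgumentError("counts must be non-negative integers")
    off = np.asarray(offsets, dtype=float)
    if not np.isfinite(off).all():
        raise InvalidArgumentError("offsets must be finite")
    n = y.shape[0]
    cov = np.empty((n, 0)) if C is None else np.asarray(C, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    X = np.column_stack([np.ones(n), np.asarray(g, dtype=float), cov])
    k = X.shape[1]

    trace = []
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        mu = pois.fittedvalues
        alpha = _mom_alpha(y, mu, n - k, max_alpha)
        trace.append(("poisson", float(alpha)))
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=off).fit()
        alpha2 = _mom_alpha(y, fit.fittedvalues, n - k, max_alpha)
        trace.append(("nb-refine", float(alpha2)))
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha2), offset=off).fit()
    except Exception as exc:  # statsmodels raises several flavours on failure
        raise ConvergenceError(f"NB GLM failed: {exc}", trace=trace) from exc
    if not getattr(fit, "converged", True):
        raise ConvergenceError("NB GLM did not converge", trace=trace)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se if se > 0 else np.inf
    p = float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return AssociationResult(
        snp_id="", gene_id="", beta=beta, se=se, t_stat=float(z),
        p_value=p, n_samples=n, stage="nb",
    )


def _mom_alpha(y: np.ndarray, mu: np.ndarray, df: int, max_alpha: float) -> float:
    num = np.sum(((y - mu) ** 2 - mu) / mu**2)
    return float(np.clip(num / max(df, 1), 1e-8, max_alpha))
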