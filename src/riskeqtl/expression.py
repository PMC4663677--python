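"""Expression filtering, depth/GC/length normalization, and covariate PCs.

Normalization is a CQN-style smooth-offset transform: per sample, a
robust (Huber) regression of log2 counts on GC fraction (linear +
quadratic) and log gene length is fitted; the fitted surface — which
absorbs sequencing depth through its intercept — is subtracted, and is
also returned on the natural-log scale for reuse as a count-GLM offset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateTable, ExpressionCounts, NormalizedExpression
from .errors import (
    DecompositionError,
    FilterEmptyError,
    InvalidArgumentError,
)

__all__ = [
    "filter_genes",
    "normalize_counts",
    "expression_pcs",
    "screen_covariates",
    "make_covariate_table",
]


def filter_genes(
    E: ExpressionCounts, median_min: int = 14
) -> tuple[ExpressionCounts, pd.DataFrame]:
    """Drop undetectable and low-median genes.

    Genes with zero counts in every sample are reported as
    ``undetectable``; genes whose per-gene median count across samples is
    strictly below ``median_min`` are reported as ``low_median``. Gene
    order is preserved; filtering twice changes nothing.
    """
    if median_min < 0:
        raise InvalidArgumentError("median_min must be >= 0")
    med = np.median(E.counts, axis=1)
    all_zero = (E.counts == 0).all(axis=1)
    low = (med < median_min) & ~all_zero
    keep = ~(all_zero | low)
    if not keep.any():
        raise FilterEmptyError("no gene survived expression filtering")
    removed = pd.DataFrame(
        {
            "gene_id": E.gene_meta.loc[~keep, "id"],
            "median_count": med[~keep],
            "reason": np.where(all_zero[~keep], "undetectable", "low_median"),
        }
    ).reset_index(drop=True)
    kept = ExpressionCounts(
        counts=E.counts[keep],
        gene_meta=E.gene_meta[keep].reset_index(drop=True),
        sample_ids=list(E.sample_ids),
    )
    return kept, removed


def _huber_fit(Z: np.ndarray, y: np.ndarray, max_iter: int = 8, c: float = 1.345) -> np.ndarray:
    """Huber IRLS regression coefficients (plain least squares to start)."""
    beta = np.linalg.lstsq(Z, y, rcond=None)[0]
    for _ in range(max_iter):
        r = y - Z @ beta
        scale = np.median(np.abs(r - np.median(r))) * 1.4826
        if scale <= 0:
            break
        u = np.abs(r / scale)
        w = np.minimum(1.0, c / np.maximum(u, 1e-12))
        sw = np.sqrt(w)
        beta_new = np.linalg.lstsq(Z * sw[:, None], y * sw, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def normalize_counts(E: ExpressionCounts, *, max_iter: int = 8) -> NormalizedExpression:
    """Remove depth, GC-content and gene-length effects from counts.

    For each sample s, fits log2(count + 0.5) ~ 1 + gc + gc^2 + log(length)
    by Huber regression across genes and subtracts the fit. The intercept
    absorbs library size, so the transform is invariant to uniform depth
    changes; the removed component is returned (natural-log scale) as the
    NB-GLM offset.
    """
    if (E.counts.sum(axis=0) <= 0).any():
        raise InvalidArgumentError("every sample must have a positive library size")
    gc = E.gene_meta["gc_fraction"].to_numpy(dtype=float)
    ll = np.log(E.gene_meta["length_bp"].to_numpy(dtype=float))
    gcc = gc - gc.mean()
    llc = ll - ll.mean()
    Z = np.column_stack([np.ones_like(gcc), gcc, gcc**2, llc])

    y = np.log2(E.counts + 0.5)
    fitted = np.empty_like(y, dtype=float)
    for s in range(E.n_samples):
        beta = _huber_fit(Z, y[:, s], max_iter=max_iter)
        fitted[:, s] = Z @ beta
    values = y - fitted
    offsets = fitted * np.log(2.0)
    return NormalizedExpression(
        values=values,
        offsets=offsets,
        gene_meta=E.gene_meta,
        sample_ids=list(E.sample_ids),
    )


def expression_pcs(
    N: NormalizedExpression, var_min: float = 0.01
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space principal components of normalized expression.

    Genes are centred before decomposition. Returns the PC score columns
    whose individual variance-explained fraction strictly exceeds
    ``var_min`` (ordered by decreasing eigenvalue) and the full
    variance-explained vector.
    """
    if N.n_samples < 3:
        raise InvalidArgumentError("need at least 3 samples for expression PCs")
    X = N.values - N.values.mean(axis=1, keepdims=True)  # centre per gene
    if not np.any(X):
        raise DecompositionError("expression matrix has no variation")
    U, s, Vt = np.linalg.svd(X.T, full_matrices=False)  # rows = samples
    var_exp = s**2 / (s**2).sum()
    k = int((var_exp > var_min).sum())
    scores = U[:, :k] * s[:k]
    cols = pd.DataFrame(
        scores, index=list(N.sample_ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return cols, var_exp


def screen_covariates(
    N: NormalizedExpression, candidates: pd.DataFrame, p_min: float = 1e-5
) -> pd.DataFrame:
    """Screen candidate covariates for association with global expression.

    Each candidate column is regressed (simple linear model) against every
    gene's normalized expression; the minimum P across genes is reported
    and candidates with min P < ``p_min`` are flagged as associated with
    global transcript abundance. Constant columns are flagged
    non-testable.
    """
    if len(candidates) != N.n_samples:
        raise InvalidArgumentError("candidate rows must align with samples")
    n = N.n_samples
    Y = N.values - N.values.mean(axis=1, keepdims=True)
    sy = np.sqrt((Y**2).sum(axis=1))
    rows = []
    for name in candidates.columns:
        x = candidates[name].to_numpy(dtype=float)
        xc = x - x.mean()
        sx = np.sqrt(xc @ xc)
        if sx == 0:
            rows.append({"covariate": name, "min_p": np.nan, "testable": False, "associated": False})
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Y @ xc) / (sy * sx)
        r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        min_p = float(p.min())
        rows.append(
            {
                "covariate": name,
                "min_p": min_p,
                "testable": True,
                "associated": bool(min_p < p_min),
            }
        )
    return pd.DataFrame(rows)


def make_covariate_table(
    histology: pd.DataFrame | None,
    pcs: pd.DataFrame,
    variance_explained: np.ndarray | None = None,
) -> CovariateTable:
    """Assemble histology columns and expression PCs into one table."""
    parts = [df for df in (histology, pcs) if df is not None and len(df.columns)]
    if not parts:
        raise InvalidArgumentError("no covariates supplied")
    table = pd.concat(parts, axis=1)
    ve = {}
    if variance_explained is not None:
        ve = {f"PC{i + 1}": float(v) for i, v in enumerate(variance_explained[: len(pcs.columns)])}
    return CovariateTable(table=table, variance_explained=ve)
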