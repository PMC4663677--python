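"""Linkage disequilibrium, LD-SNP expansion, risk intervals and cis windows.

LD is the squared Pearson correlation of unphased allele dosages, computed
on the cohort itself (composite r-squared). Risk SNPs whose LD spans
overlap or abut are merged transitively into a single risk interval.
All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, RiskInterval, gene_tss_tes
from .errors import InvalidArgumentError, UndefinedLdError

__all__ = [
    "ld_r2",
    "ld_r2_matrix",
    "expand_ld_set",
    "build_risk_intervals",
    "Window",
    "make_windows",
    "genes_in_window",
    "snps_in_window",
]


def _impute(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.isnan(v).any():
        m = np.nanmean(v)
        v = np.where(np.isnan(v), m, v)
    return v


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Missing entries are mean-imputed per vector. Symmetric and invariant
    to allele flips (d -> 2 - d).
    """
    g1, g2 = _impute(g1), _impute(g2)
    if g1.shape != g2.shape:
        raise InvalidArgumentError("dosage vectors must have equal length")
    x = g1 - g1.mean()
    y = g2 - g2.mean()
    vx, vy = x @ x, y @ y
    if vx == 0 or vy == 0:
        raise UndefinedLdError("zero-variance dosage vector")
    r = (x @ y) / np.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def ld_r2_matrix(cols: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """r-squared of each column of ``cols`` against a reference vector.

    Zero-variance columns get r2 = NaN rather than raising, so callers can
    screen candidate sets in bulk.
    """
    ref = _impute(ref)
    X = np.asarray(cols, dtype=float)
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = mu[idx[1]]
    Xc = X - X.mean(axis=0)
    yc = ref - ref.mean()
    vy = yc @ yc
    vx = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / np.sqrt(vx * vy)
    r2 = r * r
    r2[vx == 0] = np.nan
    if vy == 0:
        raise UndefinedLdError("zero-variance reference vector")
    return np.minimum(r2, 1.0)


def expand_ld_set(
    G: GenotypeMatrix,
    risk_snp: str,
    r2_min: float = 0.5,
    search_flank: int = 2_000_000,
) -> set[str]:
    """All SNPs within ``search_flank`` of a risk SNP at r2 strictly above
    ``r2_min``, always including the risk SNP itself."""
    if not 0 < r2_min <= 1:
        raise InvalidArgumentError("r2_min must be in (0, 1]")
    j = G.snp_index(risk_snp)
    meta = G.snp_meta
    pos0 = int(meta.loc[j, "pos"])
    chrom0 = meta.loc[j, "chrom"]
    near = np.flatnonzero(
        (meta["chrom"].to_numpy() == chrom0)
        & (np.abs(meta["pos"].to_numpy() - pos0) <= search_flank)
    )
    r2 = ld_r2_matrix(G.dosage[:, near], G.dosage[:, j])
    keep = near[np.nan_to_num(r2, nan=0.0) > r2_min]
    out = set(meta.loc[keep, "id"])
    out.add(risk_snp)
    return out


def build_risk_intervals(
    risk_snps: list[str],
    ld_sets: dict[str, set[str]],
    snp_meta: pd.DataFrame,
    *,
    flank: int = 1_000_000,
    chrom_length: int | None = None,
) -> list[RiskInterval]:
    """Merge risk SNPs with overlapping/abutting LD spans into intervals.

    Each risk SNP's LD span is the [min, max] position of its LD-SNP set;
    same-chromosome spans that overlap or touch (end + 1 >= next start)
    are merged transitively. Returned intervals are coordinate-sorted with
    pooled LD-SNP sets and scan windows of ``span ± flank`` clipped to the
    chromosome.
    """
    pos_of = dict(zip(snp_meta["id"], snp_meta["pos"].astype(int)))
    chrom_of = dict(zip(snp_meta["id"], snp_meta["chrom"]))
    spans = []
    for rs in risk_snps:
        if rs not in ld_sets:
            raise InvalidArgumentError(f"risk SNP {rs!r} has no LD set")
        members = ld_sets[rs] | {rs}
        unknown = [s for s in members if s not in pos_of]
        if unknown:
            raise InvalidArgumentError(f"SNPs {unknown} missing coordinates")
        ps = [pos_of[s] for s in members]
        spans.append((chrom_of[rs], min(ps), max(ps), rs, members))

    spans.sort(key=lambda t: (str(t[0]), t[1], t[2]))
    merged: list[list] = []
    for chrom, lo, hi, rs, members in spans:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], hi)
            merged[-1][3].append(rs)
            merged[-1][4] |= members
        else:
            merged.append([chrom, lo, hi, [rs], set(members)])

    intervals = []
    for k, (chrom, lo, hi, members_rs, ld_ids) in enumerate(merged):
        w_lo = max(1, lo - flank)
        w_hi = hi + flank
        if chrom_length is not None:
            w_hi = min(w_hi, chrom_length)
        intervals.append(
            RiskInterval(
                interval_id=f"ri{k:03d}",
                chrom=str(chrom),
                span_start=int(lo),
                span_end=int(hi),
                member_risk_snps=sorted(members_rs),
                ld_snp_ids=sorted(ld_ids),
                window_start=int(w_lo),
                window_end=int(w_hi),
            )
        )
    return intervals


@dataclass
class Window:
    """A cis scan window tied to its source interval or gene."""

    chrom: str
    start: int
    end: int
    ref_id: str


def make_windows(features, mode: str, flank: int, *, chrom_length: int | None = None):
    """Build stage-1 (interval ± flank) or stage-2 (gene span ± flank) windows.

    ``mode='stage1'`` takes RiskInterval objects; ``mode='stage2'`` takes a
    gene_meta frame and flanks the [min(TSS,TES), max(TSS,TES)] span.
    Windows are clipped at 1 (and at ``chrom_length`` when given).
    """
    if flank <= 0:
        raise InvalidArgumentError("flank must be positive")
    out = []
    if mode == "stage1":
        for iv in features:
            lo = max(1, iv.span_start - flank)
            hi = iv.span_end + flank
            if chrom_length is not None:
                hi = min(hi, chrom_length)
            out.append(Window(iv.chrom, int(lo), int(hi), iv.interval_id))
    elif mode == "stage2":
        genes = features
        tss, tes = gene_tss_tes(genes)
        lo = np.maximum(1, np.minimum(tss, tes) - flank)
        hi = np.maximum(tss, tes) + flank
        if chrom_length is not None:
            hi = np.minimum(hi, chrom_length)
        for i, row in genes.reset_index(drop=True).iterrows():
            out.append(Window(str(row["chrom"]), int(lo[i]), int(hi[i]), row["id"]))
    else:
        raise InvalidArgumentError("mode must be 'stage1' or 'stage2'")
    return out


def genes_in_window(genes: pd.DataFrame, window: Window) -> pd.DataFrame:
    """Genes whose [start, end] span overlaps the window (inclusive)."""
    mask = (
        (genes["chrom"].astype(str) == window.chrom)
        & (genes["end"].to_numpy() >= window.start)
        & (genes["start"].to_numpy() <= window.end)
    )
    return genes[mask]


def snps_in_window(snp_meta: pd.DataFrame, window: Window) -> pd.DataFrame:
    """SNPs whose position lies inside the window (inclusive)."""
    mask = (
        (snp_meta["chrom"].astype(str) == window.chrom)
        & (snp_meta["pos"].to_numpy() >= window.start)
        & (snp_meta["pos"].to_numpy() <= window.end)
    )
    return snp_meta[mask]
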