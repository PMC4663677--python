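"""SNP-level genotype quality control and genotype PCA with Tracy–Widom screening.

QC removes, in order: duplicate physical positions (first-listed copy
kept), call rate below threshold, Hardy–Weinberg exact-test P below
threshold, and minor-allele frequency below threshold. Each removed SNP
is annotated with the first rule it violated, so removal reasons
partition the removed set and re-applying the filter is a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .datatypes import GenotypeMatrix
from .errors import InvalidArgumentError, QcEmptyError, UndefinedStatisticError

__all__ = [
    "snp_maf",
    "hwe_exact_test",
    "hwe_pvalues_all",
    "QcThresholds",
    "apply_snp_qc",
    "genotype_pca_tw",
    "tracy_widom_sf",
]

_LN2 = np.log(2.0)


def snp_maf(dosages: np.ndarray) -> float:
    """Minor-allele frequency from a dosage vector, ignoring missing calls."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedStatisticError("MAF undefined: all dosages missing")
    f = d.sum() / (2 * d.size)
    return float(min(f, 1 - f))


def hwe_pvalues_all(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE P for every attainable heterozygote count.

    Given ``n`` diploid individuals and ``n_rare`` copies of the rarer
    allele, the heterozygote count h ranges over values of the same parity
    as ``n_rare`` with h <= min(n_rare, 2n - n_rare). Returns the support
    and, for each h, the two-sided exact P: the total conditional
    probability of configurations no more probable than h.
    """
    if n < 1 or n_rare < 0 or n_rare > n:
        raise InvalidArgumentError("need n >= 1 and 0 <= n_rare <= n (rare <= common)")
    h = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    a = (n_rare - h) // 2  # rare homozygotes
    b = n - h - a  # common homozygotes
    logw = (
        gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(h + 1)
        - gammaln(b + 1)
        + h * _LN2
    )
    w = np.exp(logw - logw.max())
    total = w.sum()
    # P(h_obs) = sum of probabilities <= that of h_obs (tiny relative
    # tolerance guards float ties in otherwise exactly-equal weights)
    order = np.argsort(w, kind="stable")
    csum = np.cumsum(w[order])
    p = np.empty_like(w)
    sorted_w = w[order]
    for rank, idx in enumerate(order):
        hi = np.searchsorted(sorted_w, w[idx] * (1 + 1e-9), side="right")
        p[idx] = csum[hi - 1] / total
    return h, np.minimum(p, 1.0)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test from genotype counts.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote configurations at most as probable as the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise InvalidArgumentError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise InvalidArgumentError("need at least one genotyped individual")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    support, pvals = hwe_pvalues_all(n, n_rare)
    return float(pvals[np.searchsorted(support, n_Aa)])


@dataclass
class QcThresholds:
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-5
    maf_min: float = 0.01


def apply_snp_qc(
    G: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter a genotype panel; returns the kept panel and a QC report.

    The report has one row per input SNP with its call rate, MAF, HWE P,
    kept flag and (for removals) the first triggering reason among
    ``duplicate_position``, ``call_rate``, ``hwe``, ``maf``.
    """
    thr = thresholds or QcThresholds()
    d = G.dosage
    n = G.n_samples
    nonmiss = (~np.isnan(d)).sum(axis=0)
    call_rate = nonmiss / n

    maf = np.full(G.n_snp, np.nan)
    hwe_p = np.full(G.n_snp, np.nan)
    for j in range(G.n_snp):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        f = col.sum() / (2 * col.size)
        maf[j] = min(f, 1 - f)
        counts = np.bincount(col.astype(int), minlength=3)
        hwe_p[j] = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))

    reason = np.array([""] * G.n_snp, dtype=object)
    dup = G.snp_meta.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    reason[dup] = "duplicate_position"
    fail_cr = (reason == "") & (call_rate < thr.call_rate_min)
    reason[fail_cr] = "call_rate"
    fail_hwe = (reason == "") & (np.nan_to_num(hwe_p, nan=1.0) < thr.hwe_p_min)
    reason[fail_hwe] = "hwe"
    fail_maf = (reason == "") & (np.nan_to_num(maf, nan=0.0) < thr.maf_min)
    reason[fail_maf] = "maf"

    kept = reason == ""
    report = pd.DataFrame(
        {
            "snp_id": G.snp_meta["id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": kept,
            "reason": reason,
        }
    )
    if not kept.any():
        raise QcEmptyError("quality control removed every SNP")
    return G.subset_snps(np.flatnonzero(kept)), report


# Tracy–Widom F1 via the shifted-gamma approximation (accurate to ~1e-4
# in the CDF over the relevant range).
_TW1_K = 46.44604884387787
_TW1_THETA = 0.18605402228279682
_TW1_ALPHA = 9.848007781128567


def tracy_widom_sf(x: np.ndarray) -> np.ndarray:
    """Upper-tail probability of the Tracy–Widom (beta=1) law."""
    return stats.gamma.sf(np.asarray(x, dtype=float) + _TW1_ALPHA, _TW1_K, scale=_TW1_THETA)


def genotype_pca_tw(
    G: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype PCA with per-eigenvalue Tracy–Widom significance.

    Missing dosages are mean-imputed; each SNP column is centred and
    scaled by sqrt(p(1-p)) with p the allele frequency (constant columns
    are dropped with a warning). Returns sample scores (n x k),
    eigenvalues of the sample covariance (non-increasing) and a TW P per
    returned eigenvalue, computed sequentially with effective-marker
    (Patterson-style) eigenvalue normalization.
    """
    n = G.n_samples
    if n < n_components + 2:
        raise InvalidArgumentError("need n_samples >= n_components + 2")
    d = G.imputed_dosage()
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant SNPs from PCA", stacklevel=2)
    d = d[:, keep]
    p = p[keep]
    X = (d - 2 * p) / np.sqrt(p * (1 - p))
    m_snp = X.shape[1]

    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / m_snp  # eigenvalues of X X^T / n_snp
    eigvals = eigvals[: n - 1]  # drop the null direction from centring-by-frequency
    k = min(n_components, eigvals.size)
    scores = U[:, :k] * s[:k]

    tw_p = np.empty(k)
    for i in range(k):
        lam = eigvals[i:]
        m = lam.size
        if m < 3 or lam.sum() <= 0:
            tw_p[i] = 1.0
            continue
        a, b = lam.sum(), (lam**2).sum()
        denom = (m - 1) * b - a**2
        n_eff = ((m + 1) * a**2 / denom) if denom > 0 else float(m_snp)
        n_eff = max(n_eff, 3.0)
        ell = m * lam[0] / a
        sq = np.sqrt(n_eff - 1) + np.sqrt(m)
        mu = sq**2 / n_eff
        sigma = (sq / n_eff) * (1 / np.sqrt(n_eff - 1) + 1 / np.sqrt(m)) ** (1 / 3)
        tw_p[i] = float(tracy_widom_sf((ell - mu) / sigma))
    return scores, eigvals, tw_p
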