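"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they verify: the HWE oracle uses
exact big-integer enumeration, the interval oracle is a union-find over
pairwise span overlaps, and the window/LD oracles are naive all-pairs
scans.
"""

from __future__ import annotations

from math import factorial

import numpy as np

_SCALE = 10**25  # integer-scaled division keeps ~25 exact digits


def hwe_oracle_pvalues(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-sided HWE P for every heterozygote count, by enumeration.

    Conditional weight of h heterozygotes given n individuals and n_rare
    rare-allele copies is n! * 2^h / (a! h! b!) with a rare and b common
    homozygotes; all arithmetic is exact integer, converted to float only
    at the end.
    """
    support = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    fact = [factorial(i) for i in range(n + 1)]
    fn = fact[n]
    weights = []
    for h in support:
        a = (n_rare - h) // 2
        b = n - h - a
        weights.append(fn * (1 << h) // (fact[a] * fact[h] * fact[b]))
    total = sum(weights)
    pvals = []
    for w_obs in weights:
        s = sum(w for w in weights if w <= w_obs)
        pvals.append((s * _SCALE // total) / _SCALE)
    return np.array(support), np.array(pvals)


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    support, pvals = hwe_oracle_pvalues(n, n_rare)
    return float(pvals[list(support).index(n_Aa)])


def merge_spans_oracle(spans: list[tuple[str, int, int]]) -> list[set[int]]:
    """Union-find over risk-SNP LD spans: groups indices whose spans
    (chrom, lo, hi) overlap or abut, transitively."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            ci, li, hi_ = spans[i]
            cj, lj, hj = spans[j]
            if ci == cj and li <= hj + 1 and lj <= hi_ + 1:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: min(g))


def ld_set_oracle(dosage: np.ndarray, snp_meta, risk_idx: int, r2_min: float, flank: int) -> set[str]:
    """Naive all-pairs LD expansion."""
    out = {snp_meta["id"].iloc[risk_idx]}
    pos0 = snp_meta["pos"].iloc[risk_idx]
    chrom0 = snp_meta["chrom"].iloc[risk_idx]
    g0 = dosage[:, risk_idx]
    for j in range(dosage.shape[1]):
        if snp_meta["chrom"].iloc[j] != chrom0 or abs(snp_meta["pos"].iloc[j] - pos0) > flank:
            continue
        g = dosage[:, j]
        if g.std() == 0 or g0.std() == 0:
            continue
        r = np.corrcoef(g, g0)[0, 1]
        if r * r > r2_min:
            out.add(snp_meta["id"].iloc[j])
    return out


def residualize_oracle(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-column least squares via explicit normal equations."""
    out = np.empty_like(M, dtype=float)
    CtC_inv = np.linalg.inv(C.T @ C)
    for j in range(M.shape[1]):
        beta = CtC_inv @ (C.T @ M[:, j])
        out[:, j] = M[:, j] - C @ beta
    return out
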