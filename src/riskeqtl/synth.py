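"""Synthetic cohort generator with recoverable ground truth.

Generates LD-structured genotype panels, gene annotations, and
negative-binomial expression counts with planted cis effects, latent
confounders and GC/length/depth artifacts — the statistical structure the
downstream eQTL stages assume — so every stage can be verified against a
known truth table.

The genotype model is a haplotype-mosaic (Li–Stephens-flavoured) copier:
a small pool of founder haplotypes is built per LD block by a Markov walk
along SNPs, and each cohort haplotype copies a founder with occasional
switching and per-SNP copy error. Within a block adjacent markers are in
strong LD; correlation decays to ~0 across block boundaries, where founder
assignments and founder allele frequencies are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionCounts, GenotypeMatrix
from .errors import GenerationFailureError, InvalidArgumentError
from .ld import ld_r2

__all__ = [
    "ExpressionTruthConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_gene_annotation",
    "simulate_expression",
    "simulate_risk_snps",
]

_LEN_REF_BP = 20_000.0  # reference gene length for the multiplicative length effect


def simulate_genotypes(
    n_samples: int,
    n_snp: int,
    block_len: int,
    maf_min: float = 0.05,
    seed: int = 0,
    *,
    n_founders: int = 8,
    mutation_rate: float = 0.015,
    switch_rate: float = 0.03,
    chrom: str = "1",
    start_pos: int = 1,
    mean_spacing_bp: int = 1_000,
    max_maf_attempts: int = 100,
) -> GenotypeMatrix:
    """Simulate a diploid dosage panel with block LD structure.

    Parameters
    ----------
    n_samples, n_snp
        Cohort and panel size. ``n_samples >= 4``.
    block_len
        SNPs per LD block. Founders and their allele frequencies are
        redrawn at every block boundary, so LD decays across blocks.
    maf_min
        Guaranteed minimum sample minor-allele frequency; columns falling
        below it are resampled (bounded attempts).
    mutation_rate
        Per-SNP flip probability in both the founder Markov walk and the
        copying step. Zero makes every column within a block identical.
    switch_rate
        Per-SNP probability that a haplotype switches founder template
        within a block.
    """
    if n_samples < 4 or n_snp < 2 or block_len < 1:
        raise InvalidArgumentError("need n_samples >= 4, n_snp >= 2, block_len >= 1")
    if not 0 < maf_min < 0.5:
        raise InvalidArgumentError("maf_min must be in (0, 0.5)")
    rng = np.random.default_rng(seed)

    n_hap = 2 * n_samples
    hap = np.empty((n_hap, n_snp), dtype=np.int8)
    founder_of = np.empty(n_hap, dtype=np.int64)
    founders = np.empty(n_founders, dtype=np.int8)

    block_start = True
    founder_cols = np.empty((n_founders, n_snp), dtype=np.int8)
    for j in range(n_snp):
        if j % block_len == 0:
            block_start = True
        if block_start:
            f0 = rng.uniform(0.2, 0.8)
            founders = (rng.random(n_founders) < f0).astype(np.int8)
            founder_of = rng.integers(0, n_founders, size=n_hap)
            block_start = False
        else:
            flips = rng.random(n_founders) < mutation_rate
            founders = founders ^ flips
            switch = rng.random(n_hap) < switch_rate
            if switch.any():
                founder_of = np.where(
                    switch, rng.integers(0, n_founders, size=n_hap), founder_of
                )
        founder_cols[:, j] = founders
        copy_err = rng.random(n_hap) < mutation_rate
        hap[:, j] = founders[founder_of] ^ copy_err

    dosage = (hap[0::2] + hap[1::2]).astype(float)
    # marginal allele-1 frequency given the realized founder pool (haplotype
    # assignments are uniform and independent, plus symmetric copy error)
    fm = founder_cols.mean(axis=0)
    gen_freq = fm * (1 - mutation_rate) + (1 - fm) * mutation_rate

    # Enforce the MAF floor: resample founder alleles at offending columns,
    # keeping founder assignments so local LD survives the repair.
    for j in range(n_snp):
        maf = _column_maf(dosage[:, j], n_samples)
        attempt = 0
        while maf < maf_min:
            attempt += 1
            if attempt > max_maf_attempts:
                raise GenerationFailureError(
                    f"could not reach maf_min={maf_min} at SNP index {j}"
                )
            f_new = rng.uniform(0.3, 0.7)
            founders = (rng.random(n_founders) < f_new).astype(np.int8)
            # re-derive this column's haplotypes from the last assignment used
            assign = rng.integers(0, n_founders, size=n_hap)
            copy_err = rng.random(n_hap) < mutation_rate
            col = founders[assign] ^ copy_err
            hap[:, j] = col
            dosage[:, j] = (col[0::2] + col[1::2]).astype(float)
            maf = _column_maf(dosage[:, j], n_samples)
            fm_j = founders.mean()
            gen_freq[j] = fm_j * (1 - mutation_rate) + (1 - fm_j) * mutation_rate

    gaps = rng.integers(max(1, mean_spacing_bp // 2), mean_spacing_bp * 2, size=n_snp)
    positions = start_pos + np.cumsum(gaps) - gaps[0]

    snp_meta = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(n_snp)],
            "chrom": chrom,
            "pos": positions.astype(int),
            "ref": "A",
            "alt": "G",
            "gen_freq": gen_freq,
        }
    )
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_ids=sample_ids)


def _column_maf(col: np.ndarray, n_samples: int) -> float:
    f = col.sum() / (2 * n_samples)
    return min(f, 1 - f)


def simulate_gene_annotation(
    n_genes: int,
    chrom_length: int,
    seed: int = 0,
    *,
    chrom: str = "1",
    min_length_bp: int = 5_000,
    max_length_bp: int = 100_000,
) -> pd.DataFrame:
    """Place genes on a chromosome with strand, GC fraction and length.

    Returns a gene_meta frame (``id, chrom, start, end, strand,
    gc_fraction, length_bp``) with 1-based inclusive genomic start < end.
    Gene lengths are log-uniform in ``[min_length_bp, max_length_bp]``;
    genes may overlap, as real annotations do.
    """
    if n_genes < 1:
        raise InvalidArgumentError("n_genes must be >= 1")
    chrom_length = int(chrom_length)
    if chrom_length < min_length_bp + 1:
        raise GenerationFailureError("chromosome too short to place any gene")
    rng = np.random.default_rng(seed)

    lengths = np.exp(
        rng.uniform(np.log(min_length_bp), np.log(min(max_length_bp, chrom_length - 1)), n_genes)
    ).astype(int)
    max_start = chrom_length - lengths
    if (max_start < 1).any():
        raise GenerationFailureError("gene longer than chromosome")
    starts = rng.integers(1, max_start + 1)
    ends = starts + lengths
    if (ends > chrom_length).any():
        raise GenerationFailureError("gene placement exceeded chromosome length")
    return pd.DataFrame(
        {
            "id": [f"gene{g:04d}" for g in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "strand": rng.choice(["+", "-"], size=n_genes),
            "gc_fraction": rng.uniform(0.3, 0.7, size=n_genes),
            "length_bp": lengths,
        }
    )


@dataclass
class ExpressionTruthConfig:
    """Generative settings for synthetic expression.

    ``causal_effects`` maps gene id -> list of ``(snp_id, beta)`` with beta
    the natural-log change in expected count per copy of the counted
    allele. Latent factors emulate unmodelled sample-level variation that
    the covariate-PC stage is expected to absorb.
    """

    causal_effects: dict = field(default_factory=dict)
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    dispersion_size_range: tuple[float, float] = (8.0, 40.0)
    n_latent_factors: int = 3
    factor_loading_sd: float = 0.3
    library_size_log_sd: float = 0.3
    gc_linear: float = 4.0
    gc_quadratic: float = -6.0
    length_coef: float = 0.5


@dataclass
class TruthTable:
    """Every generative parameter of a synthetic expression matrix."""

    gene_meta: pd.DataFrame
    causal_effects: dict  # gene_id -> list[(snp_id, beta)]
    baseline_log_mean: np.ndarray  # per gene
    dispersion_size: np.ndarray  # per gene, > 0
    library_size_factor: np.ndarray  # per sample, > 0
    latent_factors: np.ndarray  # (K, n_samples)
    factor_loadings: np.ndarray  # (n_genes, K)

    def __post_init__(self) -> None:
        if (self.dispersion_size <= 0).any():
            raise InvalidArgumentError("dispersion sizes must be > 0")
        if (self.library_size_factor <= 0).any():
            raise InvalidArgumentError("library size factors must be > 0")

    def causal_snps(self, gene_id: str) -> list[str]:
        return [s for s, _ in self.causal_effects.get(gene_id, [])]

    def genes_with_effects(self) -> list[str]:
        return [g for g, eff in self.causal_effects.items() if eff]


def gc_length_log_effect(
    gc_fraction: np.ndarray,
    length_bp: np.ndarray,
    config: ExpressionTruthConfig,
) -> np.ndarray:
    """Natural-log multiplicative artifact: quadratic in GC, log-linear in length."""
    g = np.asarray(gc_fraction) - 0.5
    return (
        config.gc_linear * g
        + config.gc_quadratic * g**2
        + config.length_coef * (np.log(np.asarray(length_bp)) - np.log(_LEN_REF_BP))
    )


def simulate_expression(
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    config: ExpressionTruthConfig | None = None,
    seed: int = 0,
) -> tuple[ExpressionCounts, TruthTable]:
    """Draw NB counts with planted cis effects, confounders and artifacts.

    The expected count for gene g in sample s is

        mu[g,s] = L[s] * A[g] * exp(b[g] + sum_c beta_c d[s,c] + sum_k w[g,k] F[k,s])

    with L the library size factor, A the GC/length artifact, b the gene
    baseline, d the dosage of each planted causal SNP and F latent
    standard-normal sample factors. Counts are NB with per-gene size
    (variance mu + mu^2/size).
    """
    config = config or ExpressionTruthConfig()
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    n_samples = G.n_samples

    for gene_id, effects in config.causal_effects.items():
        if gene_id not in set(genes["id"]):
            raise InvalidArgumentError(f"causal gene {gene_id!r} not in annotation")
        for snp_id, _ in effects:
            G.snp_index(snp_id)  # raises UnknownSnpError -> surfaced as-is

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    lo, hi = config.dispersion_size_range
    size = rng.uniform(lo, hi, n_genes)
    lib = np.exp(rng.normal(0.0, config.library_size_log_sd, n_samples))
    lib /= np.exp(np.mean(np.log(lib)))  # geometric mean 1
    K = config.n_latent_factors
    factors = rng.standard_normal((K, n_samples)) if K else np.zeros((0, n_samples))
    loadings = (
        rng.normal(0.0, config.factor_loading_sd, (n_genes, K))
        if K
        else np.zeros((n_genes, 0))
    )

    log_mu = baseline[:, None] + loadings @ factors
    log_mu += gc_length_log_effect(
        genes["gc_fraction"].to_numpy(), genes["length_bp"].to_numpy(), config
    )[:, None]
    gene_row = {g: i for i, g in enumerate(genes["id"])}
    dosage = G.imputed_dosage()
    for gene_id, effects in config.causal_effects.items():
        for snp_id, beta in effects:
            log_mu[gene_row[gene_id]] += beta * dosage[:, G.snp_index(snp_id)]
    mu = lib[None, :] * np.exp(log_mu)
    if (mu <= 0).any() or not np.isfinite(mu).all():
        raise RuntimeError("internal error: non-positive or non-finite NB mean")

    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p).astype(np.int64)

    truth = TruthTable(
        gene_meta=genes.reset_index(drop=True),
        causal_effects={g: list(v) for g, v in config.causal_effects.items()},
        baseline_log_mean=baseline,
        dispersion_size=size,
        library_size_factor=lib,
        latent_factors=factors,
        factor_loadings=loadings,
    )
    expr = ExpressionCounts(
        counts=counts, gene_meta=genes.reset_index(drop=True), sample_ids=list(G.sample_ids)
    )
    return expr, truth


_GROUP_BANDS = {
    "group1": (0.5, 1.0000001),  # realized r2 strictly > 0.5
    "group2": (0.2, 0.5),  # closed band [0.2, 0.5]
    "group3": (0.0, 0.2),  # r2 < 0.2, inside the causal gene's cis window
}


def simulate_risk_snps(
    G: GenotypeMatrix,
    truth: TruthTable,
    scenario: str,
    seed: int = 0,
    *,
    cis_flank: int = 1_000_000,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Pick a risk (tag) SNP at a controlled r-squared to a causal SNP.

    Scenarios mirror the LD-grouping of a risk SNP against the eventual
    peak eQTL signal: ``group1`` tags the causal variant tightly
    (r2 > 0.5), ``group2`` moderately (r2 in [0.2, 0.5]), ``group3``
    weakly (r2 < 0.2) but still inside the causal gene's cis window, and
    ``null`` tags a gene with no planted effect. Returns a one-row frame
    with the realized r2 recorded.
    """
    if scenario not in {"group1", "group2", "group3", "null"}:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    dosage = G.imputed_dosage()
    pos = G.snp_meta["pos"].to_numpy()
    chrom = G.snp_meta["chrom"].to_numpy()

    if scenario == "null":
        null_genes = [
            g for g in truth.gene_meta["id"] if not truth.causal_effects.get(g)
        ]
        if gene_id is not None:
            if truth.causal_effects.get(gene_id):
                raise InvalidArgumentError(f"{gene_id!r} has planted effects; not a null gene")
        elif not null_genes:
            raise GenerationFailureError("no effect-free gene available for a null risk SNP")
        else:
            gene_id = null_genes[int(rng.integers(len(null_genes)))]
        row = truth.gene_meta.set_index("id").loc[gene_id]
        tss, tes = sorted((int(row["start"]), int(row["end"])))
        in_win = (chrom == row["chrom"]) & (pos >= tss - cis_flank) & (pos <= tes + cis_flank)
        cand = np.flatnonzero(in_win)
        if cand.size == 0:
            raise GenerationFailureError("no SNP inside the null gene's cis window")
        j = int(rng.choice(cand))
        return _risk_row(G, j, scenario, gene_id, causal_snp=None, r2=np.nan)

    causal_genes = truth.genes_with_effects()
    if not causal_genes:
        raise InvalidArgumentError(f"scenario {scenario} requires at least one causal SNP")
    if gene_id is None:
        gene_id = causal_genes[int(rng.integers(len(causal_genes)))]
    elif gene_id not in causal_genes:
        raise InvalidArgumentError(f"{gene_id!r} has no planted causal SNP")
    causal_snp = truth.causal_snps(gene_id)[0]
    c_idx = G.snp_index(causal_snp)
    c_col = dosage[:, c_idx]

    r2 = np.array(
        [
            ld_r2(dosage[:, j], c_col) if dosage[:, j].var() > 0 else 0.0
            for j in range(G.n_snp)
        ]
    )
    lo, hi = _GROUP_BANDS[scenario]
    if scenario == "group1":
        mask = (r2 > lo) & (np.arange(G.n_snp) != c_idx)
        target = 1.0
    elif scenario == "group2":
        mask = (r2 >= lo) & (r2 <= hi)
        target = 0.35
    else:  # group3
        row = truth.gene_meta.set_index("id").loc[gene_id]
        tss, tes = sorted((int(row["start"]), int(row["end"])))
        in_win = (chrom == row["chrom"]) & (pos >= tss - cis_flank) & (pos <= tes + cis_flank)
        mask = (r2 < hi) & in_win & (np.arange(G.n_snp) != c_idx)
        target = 0.1
    if scenario == "group1" and not mask.any():
        mask = r2 > lo  # fall back to the causal SNP itself (r2 = 1)
    if not mask.any():
        raise GenerationFailureError(
            f"no SNP with r2 in the {scenario} band [{lo}, {hi}) available"
        )
    cand = np.flatnonzero(mask)
    j = int(cand[np.argmin(np.abs(r2[cand] - target))])
    return _risk_row(G, j, scenario, gene_id, causal_snp=causal_snp, r2=float(r2[j]))


def _risk_row(G, j, scenario, gene_id, causal_snp, r2) -> pd.DataFrame:
    meta = G.snp_meta.iloc[j]
    return pd.DataFrame(
        [
            {
                "risk_snp_id": meta["id"],
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "scenario": scenario,
                "target_gene": gene_id,
                "causal_snp_id": causal_snp,
                "realized_r2": r2,
            }
        ]
    )
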