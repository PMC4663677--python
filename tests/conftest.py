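from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import riskeqtl as rq
from riskeqtl.synth import ExpressionTruthConfig


@pytest.fixture(scope="session")
def small_panel():
    """120 samples x 80 SNPs in 20-SNP LD blocks."""
    return rq.simulate_genotypes(120, 80, 20, maf_min=0.05, seed=11)


@pytest.fixture(scope="session")
def small_genes(small_panel):
    length = int(small_panel.snp_meta["pos"].max()) + 50_000
    return rq.simulate_gene_annotation(12, length, seed=11)


def plant_cohort(
    seed: int,
    *,
    n_samples: int = 400,
    n_snp: int = 300,
    block_len: int = 25,
    n_genes: int = 40,
    causal: list[tuple[int, float]] | None = None,
    n_latent: int = 3,
    spacing: int = 2_000,
    dispersion=(8.0, 40.0),
):
    """Simulate a cohort with causal effects planted on chosen genes.

    ``causal`` is a list of (gene index, beta) pairs; each gene gets one
    causal SNP, the panel SNP closest to the gene midpoint.
    """
    G = rq.simulate_genotypes(
        n_samples, n_snp, block_len, maf_min=0.05, seed=seed, mean_spacing_bp=spacing
    )
    chrom_len = int(G.snp_meta["pos"].max()) + 100_000
    genes = rq.simulate_gene_annotation(n_genes, chrom_len, seed=seed)
    effects: dict[str, list[tuple[str, float]]] = {}
    for gi, beta in causal or []:
        row = genes.iloc[gi]
        mid = (int(row["start"]) + int(row["end"])) // 2
        j = int((G.snp_meta["pos"] - mid).abs().idxmin())
        # a second effect on the same gene lands two LD blocks away so the
        # two causal SNPs are (nearly) independent
        prior = len(effects.get(row["id"], []))
        j = (j + prior * 2 * block_len) % n_snp
        effects.setdefault(row["id"], []).append((G.snp_meta["id"].iloc[j], beta))
    cfg = ExpressionTruthConfig(causal_effects=effects, n_latent_factors=n_latent,
                                dispersion_size_range=dispersion)
    E, truth = rq.simulate_expression(G, genes, cfg, seed=seed + 1)
    return G, genes, E, truth


def quick_covariates(E, n_pcs_min_var=0.01):
    """Normalized expression + expression-PC covariates for a cohort."""
    Ef, _ = rq.filter_genes(E, 0)
    N = rq.normalize_counts(Ef)
    pcs, var_exp = rq.expression_pcs(N, n_pcs_min_var)
    from riskeqtl.expression import make_covariate_table

    covars = make_covariate_table(None, pcs, var_exp) if len(pcs.columns) else None
    return N, covars
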