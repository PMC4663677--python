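"""Generator contracts: LD structure, annotation geometry, NB law, truth closure."""

import numpy as np
import pytest
from scipy import stats

import riskeqtl as rq
from riskeqtl.errors import GenerationFailureError, InvalidArgumentError
from riskeqtl.synth import ExpressionTruthConfig

from conftest import plant_cohort


class TestSimulateGenotypes:
    def test_maf_floor_and_dosage_domain(self):
        G = rq.simulate_genotypes(100, 50, 50, maf_min=0.05, seed=1)
        assert np.isin(G.dosage, (0, 1, 2)).all()
        mafs = np.array([rq.snp_maf(G.dosage[:, j]) for j in range(G.n_snp)])
        assert (mafs >= 0.05).all()

    def test_determinism(self):
        a = rq.simulate_genotypes(60, 40, 10, seed=7)
        b = rq.simulate_genotypes(60, 40, 10, seed=7)
        assert np.array_equal(a.dosage, b.dosage)
        assert a.snp_meta.equals(b.snp_meta)

    def test_zero_mutation_gives_perfect_ld_within_block(self):
        G = rq.simulate_genotypes(
            80, 10, 10, maf_min=0.05, seed=3, mutation_rate=0.0, switch_rate=0.0
        )
        for j in range(1, G.n_snp):
            assert rq.ld_r2(G.dosage[:, 0], G.dosage[:, j]) == pytest.approx(1.0)

    def test_block_ld_exceeds_cross_block_ld(self):
        # 20 seeded replicates; adjacent within-block pairs vs block-boundary pairs
        within, across = [], []
        for seed in range(20):
            G = rq.simulate_genotypes(300, 40, 10, maf_min=0.05, seed=seed)
            for j in range(1, 40):
                r2 = rq.ld_r2(G.dosage[:, j - 1], G.dosage[:, j])
                (across if j % 10 == 0 else within).append(r2)
        assert np.mean(within) > 0.5
        assert np.mean(across) < 0.15
        assert np.mean(within) > np.mean(across) + 0.3

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rq.simulate_genotypes(2, 50, 10, seed=0)
        with pytest.raises(InvalidArgumentError):
            rq.simulate_genotypes(10, 50, 10, maf_min=0.7, seed=0)

    def test_sample_freq_tracks_generating_frequency(self):
        # at n=5000 the sample allele frequency sits within 4 binomial SEs
        # of the generating frequency implied by the realized founder pool
        G = rq.simulate_genotypes(5000, 20, 10, maf_min=0.05, seed=5)
        gen = G.snp_meta["gen_freq"].to_numpy()
        f = G.dosage.mean(axis=0) / 2
        se = np.sqrt(gen * (1 - gen) / (2 * 5000))
        assert (np.abs(f - gen) < 4 * se).all()


class TestSimulateGeneAnnotation:
    def test_single_gene_within_bounds(self):
        genes = rq.simulate_gene_annotation(1, 1_000_000, seed=7)
        row = genes.iloc[0]
        assert 1 <= row["start"] < row["end"] <= 1_000_000

    def test_minus_strand_tss_convention(self):
        genes = rq.simulate_gene_annotation(50, 5_000_000, seed=2)
        from riskeqtl.datatypes import gene_tss_tes

        tss, tes = gene_tss_tes(genes)
        minus = (genes["strand"] == "-").to_numpy()
        assert (tss[minus] > tes[minus]).all()  # transcription order
        assert (genes["start"] < genes["end"]).all()  # genomic order

    def test_no_gene_extends_past_chromosome(self):
        genes = rq.simulate_gene_annotation(200, 10_000_000, seed=9)
        assert (genes["end"] <= 10_000_000).all()
        assert (genes["start"] >= 1).all()
        assert genes["gc_fraction"].between(0.3, 0.7).all()

    def test_capacity_failure(self):
        with pytest.raises(GenerationFailureError):
            rq.simulate_gene_annotation(1, 100, seed=0)


class TestSimulateExpression:
    def test_null_model_mean(self):
        # no effects, no confounders, equal library sizes: sample mean of
        # counts approximates the NB mean within 4 SEs at n=1000
        G = rq.simulate_genotypes(1000, 10, 10, seed=4)
        genes = rq.simulate_gene_annotation(5, 1_000_000, seed=4)
        cfg = ExpressionTruthConfig(
            n_latent_factors=0, library_size_log_sd=0.0,
            gc_linear=0.0, gc_quadratic=0.0, length_coef=0.0,
            baseline_log_sd=0.0, baseline_log_mean=4.0,
        )
        E, truth = rq.simulate_expression(G, genes, cfg, seed=8)
        mu = np.exp(4.0)
        for g in range(5):
            size = truth.dispersion_size[g]
            var = mu + mu**2 / size
            se = np.sqrt(var / 1000)
            assert abs(E.counts[g].mean() - mu) < 4 * se

    def test_nb_variance_moment(self):
        # one gene, 50k samples: sample variance matches mu + mu^2/size
        G = rq.simulate_genotypes(50_000, 2, 2, seed=6)
        genes = rq.simulate_gene_annotation(1, 1_000_000, seed=6)
        cfg = ExpressionTruthConfig(
            n_latent_factors=0, library_size_log_sd=0.0,
            gc_linear=0.0, gc_quadratic=0.0, length_coef=0.0,
            baseline_log_sd=0.0, baseline_log_mean=4.0,
            dispersion_size_range=(10.0, 10.0),
        )
        E, truth = rq.simulate_expression(G, genes, cfg, seed=3)
        y = E.counts[0].astype(float)
        mu = np.exp(4.0)
        var_expected = mu + mu**2 / 10.0
        # SE of the sample variance of an NB via the fourth moment, conservatively
        kurt = stats.kurtosis(y, fisher=True)
        se_var = var_expected * np.sqrt((kurt + 2) / len(y))
        assert abs(y.var(ddof=1) - var_expected) < 4 * se_var

    def test_library_size_scales_expected_counts(self):
        # per-sample mean over 4000 effect-free genes tracks the library
        # factor: a sample with twice the factor shows twice the counts
        G = rq.simulate_genotypes(10, 2, 2, seed=2)
        genes = rq.simulate_gene_annotation(4000, 50_000_000, seed=2)
        cfg = ExpressionTruthConfig(
            n_latent_factors=0, library_size_log_sd=0.6,
            gc_linear=0.0, gc_quadratic=0.0, length_coef=0.0,
            baseline_log_sd=0.0, baseline_log_mean=4.0,
            dispersion_size_range=(20.0, 20.0),
        )
        E, truth = rq.simulate_expression(G, genes, cfg, seed=9)
        sample_mean = E.counts.mean(axis=0)
        ratio = sample_mean / truth.library_size_factor
        assert ratio.std() / ratio.mean() < 0.05  # constant up to NB noise

    def test_unknown_causal_snp_rejected(self, small_panel, small_genes):
        cfg = ExpressionTruthConfig(
            causal_effects={small_genes["id"].iloc[0]: [("nope", 0.5)]}
        )
        with pytest.raises(KeyError):
            rq.simulate_expression(small_panel, small_genes, cfg, seed=0)

    def test_truth_closure(self):
        G, genes, E, truth = plant_cohort(21, n_samples=50, n_snp=60, n_genes=10,
                                          causal=[(2, 0.4), (7, -0.3)])
        panel_ids = set(G.snp_meta["id"])
        for gid, effects in truth.causal_effects.items():
            assert gid in set(genes["id"])
            for sid, _ in effects:
                assert sid in panel_ids
        assert truth.library_size_factor.shape == (50,)
        assert (truth.dispersion_size > 0).all()


class TestSimulateRiskSnps:
    def test_null_scenario_targets_effect_free_gene(self):
        G, genes, E, truth = plant_cohort(31, n_samples=100, n_snp=80, n_genes=10,
                                          causal=[(0, 0.5)])
        risk = rq.simulate_risk_snps(G, truth, "null", seed=1)
        assert not truth.causal_effects.get(risk["target_gene"].iloc[0])

    def test_group1_prefers_duplicate_proxy(self):
        # duplicate the causal column: the tag SNP must be that perfect proxy
        G, genes, E, truth = plant_cohort(41, n_samples=100, n_snp=80, n_genes=10,
                                          causal=[(3, 0.5)])
        causal = truth.causal_snps(truth.genes_with_effects()[0])[0]
        j = G.snp_index(causal)
        dup = (j + 1) % G.n_snp
        G.dosage[:, dup] = G.dosage[:, j]
        risk = rq.simulate_risk_snps(G, truth, "group1", seed=5)
        assert risk["risk_snp_id"].iloc[0] == G.snp_meta["id"].iloc[dup]
        assert risk["realized_r2"].iloc[0] == pytest.approx(1.0)

    def test_group2_band_respected_over_seeds(self):
        G, genes, E, truth = plant_cohort(51, n_samples=300, n_snp=200, n_genes=10,
                                          causal=[(4, 0.5)])
        for seed in range(50):
            risk = rq.simulate_risk_snps(G, truth, "group2", seed=seed)
            assert 0.2 <= risk["realized_r2"].iloc[0] <= 0.5

    def test_group3_inside_cis_window(self):
        G, genes, E, truth = plant_cohort(61, n_samples=200, n_snp=200, n_genes=10,
                                          causal=[(5, 0.5)])
        risk = rq.simulate_risk_snps(G, truth, "group3", seed=2)
        assert risk["realized_r2"].iloc[0] < 0.2
        gid = risk["target_gene"].iloc[0]
        row = genes.set_index("id").loc[gid]
        lo, hi = sorted((int(row["start"]), int(row["end"])))
        assert lo - 1_000_000 <= risk["pos"].iloc[0] <= hi + 1_000_000

    def test_scenario_requires_causal(self):
        G, genes, E, truth = plant_cohort(71, n_samples=50, n_snp=40, n_genes=5)
        with pytest.raises(InvalidArgumentError):
            rq.simulate_risk_snps(G, truth, "group1", seed=0)


class TestHaplotypePanel:
    def test_invariants_and_dosage_collapse(self):
        import numpy as np
        from riskeqtl.datatypes import HaplotypePanel
        from riskeqtl.errors import InvalidArgumentError

        hp = HaplotypePanel(
            haplotypes=np.array([[0, 1], [1, 1], [0, 0], [1, 0]]),
            positions=np.array([100, 200]),
        )
        assert hp.n_hap == 4 and hp.n_snp == 2
        assert np.array_equal(hp.to_dosage(), [[1, 2], [1, 0]])
        with pytest.raises(InvalidArgumentError):
            HaplotypePanel(np.array([[0, 2], [1, 1], [0, 0], [1, 0]]), np.array([100, 200]))
        with pytest.raises(InvalidArgumentError):
            HaplotypePanel(np.zeros((4, 2), dtype=int), np.array([200, 100]))
        with pytest.raises(InvalidArgumentError):
            HaplotypePanel(np.zeros((3, 2), dtype=int), np.array([100, 200]))
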