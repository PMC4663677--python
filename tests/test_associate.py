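"""Association engine: residualization, fast-scan/OLS equivalence, scans, NB GLM."""

import numpy as np
import pytest

import riskeqtl as rq
from riskeqtl.associate import with_intercept
from riskeqtl.errors import CollinearityError, InvalidArgumentError
from riskeqtl.synth import ExpressionTruthConfig

from conftest import plant_cohort, quick_covariates
from oracles import residualize_oracle


class TestResidualize:
    def test_intercept_only_centres(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((30, 4))
        R = rq.residualize(M, np.ones((30, 1)))
        assert np.allclose(R, M - M.mean(axis=0), atol=1e-12)

    def test_idempotent_on_orthogonal_input(self):
        rng = np.random.default_rng(1)
        C = with_intercept(rng.standard_normal((40, 3)), 40)
        M = rq.residualize(rng.standard_normal((40, 5)), C)
        R = rq.residualize(M, C)
        assert np.abs(R - M).max() < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((50, 10))
        C = with_intercept(rng.standard_normal((50, 4)), 50)
        assert np.abs(rq.residualize(M, C) - residualize_oracle(M, C)).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        C = with_intercept(rng.standard_normal((60, 5)), 60)
        R = rq.residualize(rng.standard_normal((60, 8)), C)
        assert np.abs(C.T @ R).max() < 1e-8

    def test_rank_deficient_raises(self):
        x = np.random.default_rng(4).standard_normal(20)
        C = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(CollinearityError):
            rq.residualize(np.ones((20, 1)), C)


class TestAssocScanFast:
    def test_perfect_fit_edge(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, 50).astype(float)
        C = np.ones((50, 1))
        g_res = rq.residualize(g[:, None], C)
        frame, _ = rq.assoc_scan_fast(g_res, g_res, 0, [(0, 0)])
        assert frame["beta"].iloc[0] == pytest.approx(1.0)
        assert frame["p_value"].iloc[0] <= np.finfo(float).tiny * 2

    def test_matches_full_ols_oracle(self):
        rng = np.random.default_rng(6)
        n, n_cov = 200, 8
        cov = rng.standard_normal((n, n_cov))
        C = with_intercept(cov, n)
        Gm = rng.binomial(2, rng.uniform(0.1, 0.5, 40), (n, 40)).astype(float)
        Em = rng.standard_normal((n, 25)) + Gm[:, :25] * 0.2
        pairs = np.column_stack(
            [rng.integers(0, 40, 500), rng.integers(0, 25, 500)]
        )
        frame, untest = rq.assoc_scan_fast(
            rq.residualize(Gm, C), rq.residualize(Em, C), n_cov, pairs
        )
        assert not untest.any()
        for _, row in frame.sample(60, random_state=0).iterrows():
            want = rq.assoc_ols_oracle(Gm[:, int(row["snp_col"])], Em[:, int(row["gene_col"])], cov)
            assert row["t_stat"] == pytest.approx(want.t_stat, abs=1e-8)
            assert row["beta"] == pytest.approx(want.beta, rel=1e-8)
            assert row["se"] == pytest.approx(want.se, rel=1e-8)
            assert row["p_value"] == pytest.approx(want.p_value, rel=1e-6)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        n = 150
        C = with_intercept(rng.standard_normal((n, 3)), n)
        Gm = rng.binomial(2, 0.3, (n, 100)).astype(float)
        Em = rng.standard_normal((n, 100))
        pairs = np.column_stack([np.repeat(np.arange(100), 100), np.tile(np.arange(100), 100)])
        frame, _ = rq.assoc_scan_fast(rq.residualize(Gm, C), rq.residualize(Em, C), 3, pairs)
        frac = (frame["p_value"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_zero_variance_genotype_flagged(self):
        n = 30
        C = np.ones((n, 1))
        g = np.zeros((n, 1))
        e = np.random.default_rng(8).standard_normal((n, 1))
        frame, untest = rq.assoc_scan_fast(rq.residualize(g, C), rq.residualize(e, C), 0, [(0, 0)])
        assert untest.all() and frame.empty


class TestAssocOlsOracle:
    def test_noiseless_limit_recovers_beta(self):
        rng = np.random.default_rng(9)
        g = rng.binomial(2, 0.4, 100).astype(float)
        e = 2.0 * g + rng.normal(0, 1e-8, 100)
        res = rq.assoc_ols_oracle(g, e, None)
        assert res.beta == pytest.approx(2.0, abs=1e-6)

    def test_collinear_covariate_raises(self):
        g = np.random.default_rng(10).binomial(2, 0.4, 50).astype(float)
        with pytest.raises(CollinearityError):
            rq.assoc_ols_oracle(g, np.random.default_rng(1).standard_normal(50), g[:, None])


class TestBonferroni:
    def test_values_and_monotonicity(self):
        assert rq.bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert rq.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        for n in (1, 5, 100):
            assert rq.bonferroni_threshold(0.05, n) > rq.bonferroni_threshold(0.05, n + 1)
        with pytest.raises(InvalidArgumentError):
            rq.bonferroni_threshold(0.05, 0)


def _scan_setup(seed, beta=0.6, n_samples=300, n_genes=150):
    G, genes, E, truth = plant_cohort(
        seed, n_samples=n_samples, n_snp=200, n_genes=n_genes, causal=[(10, beta)]
    )
    N, covars = quick_covariates(E)
    risk = rq.simulate_risk_snps(G, truth, "group1", seed=seed)
    return G, genes, E, truth, N, covars, risk


class TestStageScans:
    def test_degenerate_single_pair_equals_oracle(self):
        G, genes, E, truth, N, covars, risk = _scan_setup(100)
        gid = truth.genes_with_effects()[0]
        rs = risk["risk_snp_id"].iloc[0]
        from riskeqtl.datatypes import RiskInterval

        iv = RiskInterval("ri0", "1", G.position(rs), G.position(rs), [rs], [rs])
        gene_row = N.gene_meta[N.gene_meta["id"] == gid]
        cfg = rq.ScanConfig()
        results, summary = rq.stage1_scan(G, N, covars, [iv], cfg)
        sub = results[(results["snp_id"] == rs) & (results["gene_id"] == gid)]
        want = rq.assoc_ols_oracle(
            G.dosage[:, G.snp_index(rs)],
            N.gene_values(gid),
            covars.matrix(),
        )
        assert sub["t_stat"].iloc[0] == pytest.approx(want.t_stat, abs=1e-8)

    def test_stage1_finds_planted_gene(self):
        hits = 0
        for seed in range(10):
            G, genes, E, truth, N, covars, risk = _scan_setup(200 + seed)
            ts = rq.run_two_stage(G, N, covars, list(risk["risk_snp_id"]))
            if truth.genes_with_effects()[0] in ts.target_genes:
                hits += 1
        assert hits >= 9

    def test_stage_pair_sets_disjoint(self):
        G, genes, E, truth, N, covars, risk = _scan_setup(300)
        ts = rq.run_two_stage(G, N, covars, list(risk["risk_snp_id"]))
        s1 = set(zip(ts.stage1["snp_id"], ts.stage1["gene_id"]))
        s2 = set(zip(ts.stage2["snp_id"], ts.stage2["gene_id"])) if ts.stage2 is not None else set()
        assert not (s1 & s2)

    def test_stage2_excluded_set_respected(self):
        G, genes, E, truth, N, covars, risk = _scan_setup(400)
        all_snps = set(G.snp_meta["id"])
        gid = truth.genes_with_effects()[0]
        out = rq.stage2_scan(G, N, covars, [gid], all_snps)
        assert out.empty


class TestNbGlm:
    def _null_counts(self, n, n_genes, seed):
        G = rq.simulate_genotypes(n, 4, 4, seed=seed)
        genes = rq.simulate_gene_annotation(n_genes, 10_000_000, seed=seed)
        cfg = ExpressionTruthConfig(n_latent_factors=0, baseline_log_mean=4.0,
                                    baseline_log_sd=0.5)
        E, truth = rq.simulate_expression(G, genes, cfg, seed=seed + 1)
        return G, genes, E, truth

    def test_null_wald_calibration(self):
        G, genes, E, truth = self._null_counts(250, 400, 20)
        N = rq.normalize_counts(E)
        g = G.dosage[:, 0]
        rejections = 0
        for gi in range(E.n_genes):
            res = rq.nb_glm_assoc(E.counts[gi], g, None, N.offsets[gi])
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / E.n_genes <= 0.08

    def test_concordance_with_linear_model(self):
        # planted effects: NB and linear betas agree in sign where the
        # linear model is clearly significant
        G, genes, E, truth = plant_cohort(
            30, n_samples=300, n_snp=40, n_genes=60, n_latent=0,
            causal=[(i, b) for i, b in zip(range(20), np.linspace(-0.5, 0.5, 20))],
        )
        N = rq.normalize_counts(E)
        agree = total = 0
        for gid, effects in truth.causal_effects.items():
            snp_id, beta = effects[0]
            gi = int(N.gene_meta.index[N.gene_meta["id"] == gid][0])
            g = G.dosage[:, G.snp_index(snp_id)]
            lin = rq.assoc_ols_oracle(g, N.values[gi], None)
            if lin.p_value < 1e-4:
                nb = rq.nb_glm_assoc(E.counts[gi], g, None, N.offsets[gi])
                total += 1
                agree += np.sign(nb.beta) == np.sign(lin.beta)
        assert total >= 5
        assert agree / total >= 0.95

    def test_poisson_limit(self):
        # dispersion -> 0: NB Wald statistic approaches the Poisson GLM one
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        n = 400
        g = rng.binomial(2, 0.4, n).astype(float)
        mu = np.exp(3.0 + 0.2 * g)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), g])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        z_pois = pois.params[1] / pois.bse[1]
        nb = rq.nb_glm_assoc(y, g, None, np.zeros(n))
        assert nb.t_stat == pytest.approx(z_pois, rel=0.01)
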