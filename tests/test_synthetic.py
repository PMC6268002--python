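"""The generators must have exactly the statistical structure the models assume."""

import numpy as np
import pytest
from scipy import stats as sps

from finelocus.finemap import CausalConfig
from finelocus.ldtools import LDMatrix, ld_from_haplotypes
from finelocus.synthetic import (
    DEFAULT_MIXING_LOG2,
    SimScenario,
    marginal_stats,
    sim_annotations,
    sim_gwas_z,
    sim_haplotypes,
    sim_pair_scenario,
    sim_qpcr_series,
)


class TestHaplotypes:
    def test_rho_zero_gives_independent_sites(self):
        panel = sim_haplotypes(10_000, 6, rho=0.0, seed=1)
        r = ld_from_haplotypes(panel).r
        adj = np.array([r[j, j + 1] ** 2 for j in range(5)])
        assert adj.mean() < 0.01

    def test_same_seed_identical(self):
        a = sim_haplotypes(200, 10, 0.5, seed=7)
        b = sim_haplotypes(200, 10, 0.5, seed=7)
        assert np.array_equal(a.alleles, b.alleles)
        c = sim_haplotypes(200, 10, 0.5, seed=8)
        assert not np.array_equal(a.alleles, c.alleles)

    def test_adjacent_correlation_matches_rho(self):
        # equal target frequencies make the copy probability the correlation
        panel = sim_haplotypes(50_000, 2, rho=0.95, maf_range=(0.3, 0.3), seed=3)
        r = np.corrcoef(panel.alleles[:, 0], panel.alleles[:, 1])[0, 1]
        assert abs(r - 0.95) < 0.02

    def test_invalid_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            sim_haplotypes(10, 3, 0.5, maf_range=(0.0, 0.6), seed=0)

    def test_panel_invariants(self):
        panel = sim_haplotypes(100, 8, 0.7, seed=5)
        assert np.isin(panel.alleles, (0, 1)).all()
        assert np.all(np.diff(panel.positions) > 0)
        np.testing.assert_allclose(panel.allele_freqs, panel.alleles.mean(axis=0))


class TestGwasZ:
    def test_null_config_marginally_standard_normal(self):
        ld = LDMatrix(np.eye(3), ["a", "b", "c"])
        cfg = CausalConfig(c=np.zeros(3, dtype=int))
        rng = np.random.default_rng(0)
        draws = np.array([sim_gwas_z(ld, cfg, rng=rng) for _ in range(10_000)])
        assert np.max(np.abs(draws.mean(axis=0))) < 0.04
        assert np.max(np.abs(draws.std(axis=0) - 1.0)) < 0.04

    def test_identity_ld_mean_equals_lambda(self):
        ld = LDMatrix(np.eye(3), ["a", "b", "c"])
        cfg = CausalConfig.from_indices(3, [0], [5.0])
        rng = np.random.default_rng(1)
        draws = np.array([sim_gwas_z(ld, cfg, rng=rng) for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), [5.0, 0.0, 0.0], atol=0.05)

    def test_ld_propagates_noncentrality(self):
        # E[z_2] = r_12 * lambda = 0.8 * 5 = 4
        r = np.array([[1.0, 0.8], [0.8, 1.0]])
        ld = LDMatrix(r, ["a", "b"])
        cfg = CausalConfig.from_indices(2, [0], [5.0])
        rng = np.random.default_rng(2)
        draws = np.array([sim_gwas_z(ld, cfg, rng=rng) for _ in range(10_000)])
        assert abs(draws.mean(axis=0)[1] - 4.0) < 0.05

    def test_sample_covariance_converges_to_sigma(self):
        r = np.array(
            [
                [1.0, 0.7, 0.5, 0.3, 0.1],
                [0.7, 1.0, 0.7, 0.5, 0.3],
                [0.5, 0.7, 1.0, 0.7, 0.5],
                [0.3, 0.5, 0.7, 1.0, 0.7],
                [0.1, 0.3, 0.5, 0.7, 1.0],
            ]
        )
        ld = LDMatrix(r, list("abcde"))
        cfg = CausalConfig(c=np.zeros(5, dtype=int))
        rng = np.random.default_rng(3)
        draws = np.array([sim_gwas_z(ld, cfg, rng=rng) for _ in range(100_000)])
        emp = np.cov(draws, rowvar=False)
        assert np.linalg.norm(emp - r, "fro") < 0.05

    def test_dimension_mismatch(self):
        ld = LDMatrix(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            sim_gwas_z(ld, CausalConfig(c=np.zeros(3, dtype=int)), seed=0)


class TestPairScenario:
    def test_null_scenario_calibrated(self):
        panel = sim_haplotypes(1000, 10, 0.5, seed=4)
        scen = SimScenario("null", 0, 0, 0.0, 0.0, 50_000, 500)
        hits = total = 0
        for rep in range(200):
            gwas, _ = sim_pair_scenario(panel, scen, seed=rep)
            hits += (np.abs(gwas.z) > 1.96).sum()
            total += gwas.m
        assert abs(hits / total - 0.05) < 0.015

    def test_pleiotropy_top_eqtl_is_causal(self):
        panel = sim_haplotypes(2000, 10, 0.5, seed=5)
        scen = SimScenario("pleiotropy", 4, 4, 6.0, 8.0, 50_000, 500)
        hit = sum(
            int(np.argmax(np.abs(sim_pair_scenario(panel, scen, seed=rep)[1].z)) == 4)
            for rep in range(100)
        )
        assert hit > 90

    def test_linkage_leakage_via_ld(self):
        # E[z_gwas at the eQTL-causal SNP] = r(causal_g, causal_e) * lambda_g
        panel = sim_haplotypes(5000, 6, 0.85, maf_range=(0.3, 0.3), seed=6)
        ld = ld_from_haplotypes(panel)
        r = ld.r[1, 2]
        scen = SimScenario("linkage", 1, 2, 6.0, 8.0, 50_000, 500)
        zs = np.array(
            [sim_pair_scenario(panel, scen, seed=rep)[0].z[2] for rep in range(2000)]
        )
        assert abs(zs.mean() - r * 6.0) < 0.1

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            SimScenario("pleiotropy", 1, 2, 5.0, 5.0, 100, 100)
        with pytest.raises(ValueError):
            SimScenario("linkage", 1, 1, 5.0, 5.0, 100, 100)
        with pytest.raises(ValueError):
            SimScenario("null", 1, 1, 3.0, 5.0, 100, 100)


class TestAnnotations:
    def test_no_effect_independent_of_causal_status(self):
        cfg = CausalConfig(c=(np.arange(10_000) < 5000).astype(int))
        ann = sim_annotations(cfg, gamma0=-1.0, gamma1=0.0, seed=1)[:, 0]
        table = np.array(
            [
                [(ann[cfg.c == 1] == 1).sum(), (ann[cfg.c == 1] == 0).sum()],
                [(ann[cfg.c == 0] == 1).sum(), (ann[cfg.c == 0] == 0).sum()],
            ]
        )
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.01

    def test_logistic_rate_at_causal(self):
        # gamma0 + gamma1 = 0 -> causal SNPs annotated with probability 0.5
        cfg = CausalConfig(c=np.ones(10_000, dtype=int), lam=np.ones(10_000))
        ann = sim_annotations(cfg, gamma0=-3.0, gamma1=3.0, seed=2)[:, 0]
        assert abs(ann.mean() - 0.5) < 0.02

    def test_seed_reproducible(self):
        cfg = CausalConfig(c=np.array([1, 0, 1, 0]), lam=np.array([1.0, 0, 1.0, 0]))
        a = sim_annotations(cfg, -2.0, 2.0, seed=9)
        b = sim_annotations(cfg, -2.0, 2.0, seed=9)
        assert np.array_equal(a, b)

    def test_empirical_log_odds_recovers_gamma1(self):
        cfg = CausalConfig(c=(np.arange(10_000) < 2000).astype(int))
        ann = sim_annotations(cfg, gamma0=-2.0, gamma1=2.0, seed=3)[:, 0]
        p1 = ann[cfg.c == 1].mean()
        p0 = ann[cfg.c == 0].mean()
        emp = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
        assert abs(emp - 2.0) < 0.3


class TestQpcrSeries:
    def test_identity_noise_free(self):
        df = sim_qpcr_series(noise_sd=0.0, slope=1.0, intercept=0.0, seed=0)
        np.testing.assert_array_equal(
            df["measured_log2_ratio"], df["true_log2_ratio"]
        )

    def test_default_mixing_series(self):
        # 4:1, 2:1, 1:1, 1:2, 1:4 on the log2 scale
        np.testing.assert_array_equal(DEFAULT_MIXING_LOG2, [2, 1, 0, -1, -2])

    def test_linear_evaluation(self):
        df = sim_qpcr_series(slope=0.9, intercept=0.1, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(
            df["measured_log2_ratio"], 0.1 + 0.9 * df["true_log2_ratio"]
        )


class TestMarginalStats:
    def test_self_regression_maximal(self, rng):
        geno = rng.integers(0, 3, size=(50, 3)).astype(float)
        res = marginal_stats(geno, geno[:, 1])
        assert res["p"][1] < 1e-30
        assert res["z"][1] == np.inf

    def test_permuted_phenotype_uniform_p(self, rng):
        geno = rng.binomial(2, 0.3, size=(100, 10_000)).astype(float)
        pheno = rng.standard_normal(100)
        res = marginal_stats(geno, pheno)
        _, ks_p = sps.kstest(res["p"], "uniform")
        assert ks_p > 0.01

    def test_matches_closed_form_ols(self):
        x = np.array([0.0, 1, 2, 0, 1, 2])
        y = np.array([0.3, 1.1, 2.2, 0.1, 0.9, 2.0])
        res = marginal_stats(x[:, None], y)
        lr = sps.linregress(x, y)
        assert abs(res["slope"][0] - lr.slope) < 1e-12
        assert abs(res["se"][0] - lr.stderr) < 1e-12
        assert abs(res["p"][0] - lr.pvalue) < 1e-12

    def test_monomorphic_flagged(self):
        geno = np.column_stack([np.ones(6), np.arange(6.0)])
        res = marginal_stats(geno, np.arange(6.0))
        assert res["z"][0] == 0.0
        assert np.isinf(res["se"][0])
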