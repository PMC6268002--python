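"""Bayes-factor configuration posteriors: closed forms, enumeration, search."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from finelocus.finemap import (
    CausalConfig,
    config_log_bf,
    credible_set,
    posterior_exhaustive,
    posterior_sss,
)
from finelocus.ldtools import LDMatrix
from finelocus.synthetic import sim_locus

from conftest import make_locus


def closed_form_single(z: float, s: float) -> float:
    """1-D marginal likelihood ratio: (1+s^2)^{-1/2} exp(z^2 s^2 / (2(1+s^2)))."""
    return -0.5 * np.log(1 + s**2) + z**2 * s**2 / (2 * (1 + s**2))


class TestConfigLogBF:
    def test_null_config_exactly_zero(self):
        ld = LDMatrix(np.eye(4), list("abcd"))
        cfg = CausalConfig(c=np.zeros(4, dtype=int))
        assert config_log_bf(np.array([1.0, 2, 3, 4]), ld, cfg) == 0.0

    @pytest.mark.parametrize("z", [0.0, 0.5, 2.0, 5.0, 8.0])
    @pytest.mark.parametrize("s", [0.5, 3.0])
    def test_identity_ld_single_causal_closed_form(self, z, s):
        ld = LDMatrix(np.eye(3), list("abc"))
        cfg = CausalConfig.from_indices(3, [0])
        zvec = np.array([z, 0.7, -1.2])
        lbf = config_log_bf(zvec, ld, cfg, prior_sd=s)
        assert abs(lbf - closed_form_single(z, s)) < 1e-10

    def test_zero_z_shrinks_below_one(self):
        ld = LDMatrix(np.eye(2), list("ab"))
        cfg = CausalConfig.from_indices(2, [0])
        lbf = config_log_bf(np.array([0.0, 0.0]), ld, cfg, prior_sd=2.0)
        assert abs(lbf - (-0.5 * np.log(5.0))) < 1e-12
        assert lbf < 0

    def test_matches_generic_mvn_density_ratio(self, rng):
        # independent oracle: scipy multivariate_normal on the two covariances
        from conftest import random_corr

        m, s = 5, 2.5
        sigma = random_corr(rng, m)
        ld = LDMatrix(sigma, [f"s{i}" for i in range(m)])
        z = rng.standard_normal(m) * 2
        cfg = CausalConfig.from_indices(m, [1, 3])
        sc = sigma[:, [1, 3]]
        expect = multivariate_normal.logpdf(
            z, np.zeros(m), sigma + s**2 * sc @ sc.T
        ) - multivariate_normal.logpdf(z, np.zeros(m), sigma)
        assert abs(config_log_bf(z, ld, cfg, prior_sd=s) - expect) < 1e-10

    def test_sign_flip_invariance(self):
        ld = LDMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]), list("ab"))
        cfg = CausalConfig.from_indices(2, [0])
        z = np.array([3.0, 2.0])
        assert (
            abs(config_log_bf(z, ld, cfg) - config_log_bf(-z, ld, cfg)) < 1e-12
        )

    def test_monotone_in_abs_z(self):
        ld = LDMatrix(np.eye(2), list("ab"))
        cfg = CausalConfig.from_indices(2, [0])
        vals = [
            config_log_bf(np.array([z, 0.0]), ld, cfg) for z in (0.0, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(vals) > 0)


class TestExhaustive:
    def test_single_snp_null_beats_causal_at_zero_z(self):
        locus = make_locus(np.eye(1), [0.0])
        res = posterior_exhaustive(locus, k_max=1)
        p_null = res.posterior[res.configs.index(())]
        p_causal = res.posterior[res.configs.index((0,))]
        assert p_null > p_causal

    def test_duplicate_snps_equal_pips(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        locus = make_locus(r, [4.0, 4.0])
        res = posterior_exhaustive(locus, k_max=2)
        assert abs(res.pip[0] - res.pip[1]) < 1e-9

    def test_hand_summed_normalization(self):
        # brute-force oracle over all 7 non-null configs + null, m=3 k_max=2
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        z = np.array([4.5, 3.0, 1.0])
        locus = make_locus(r, z)
        s = 3.0
        res = posterior_exhaustive(locus, k_max=2, prior_sd=s)
        log_unnorm = {}
        from math import comb

        for cfg in res.configs:
            k = len(cfg)
            if k == 0:
                lbf = 0.0
            else:
                sc = r[:, list(cfg)]
                lbf = multivariate_normal.logpdf(
                    z, np.zeros(3), r + s**2 * sc @ sc.T
                ) - multivariate_normal.logpdf(z, np.zeros(3), r)
            log_unnorm[cfg] = lbf + np.log(1 / 3) - np.log(comb(3, k))
        norm = logsumexp(list(log_unnorm.values()))
        for cfg, post in zip(res.configs, res.posterior):
            assert abs(post - np.exp(log_unnorm[cfg] - norm)) < 1e-12

    def test_posteriors_sum_to_one(self):
        locus, _ = sim_locus(m_snp=10, seed=4)
        res = posterior_exhaustive(locus, k_max=3)
        assert abs(res.posterior.sum() - 1.0) < 1e-9
        assert np.all((res.pip >= 0) & (res.pip <= 1 + 1e-12))

    def test_enumeration_guard(self):
        locus, _ = sim_locus(m_snp=26, seed=5, n_hap=200)
        with pytest.raises(ValueError, match="posterior_sss"):
            posterior_exhaustive(locus)


class TestSSS:
    def test_matches_exhaustive_on_moderate_locus(self):
        locus, _ = sim_locus(m_snp=12, seed=6)
        ex = posterior_exhaustive(locus, k_max=3)
        ss = posterior_sss(locus, k_max=3, n_iter=500, seed=0)
        assert np.max(np.abs(ex.pip - ss.pip)) < 1e-6

    def test_kmax_zero_returns_null(self):
        locus, _ = sim_locus(m_snp=5, seed=7)
        res = posterior_sss(locus, k_max=0, n_iter=10, seed=0)
        assert res.configs == [()]
        assert res.posterior[0] == 1.0

    def test_same_seed_same_visited_set(self):
        locus, _ = sim_locus(m_snp=12, seed=8)
        a = posterior_sss(locus, k_max=2, n_iter=50, seed=3)
        b = posterior_sss(locus, k_max=2, n_iter=50, seed=3)
        assert a.configs == b.configs
        np.testing.assert_array_equal(a.posterior, b.posterior)

    def test_sss_posterior_sums_to_one(self):
        locus, _ = sim_locus(m_snp=12, seed=9)
        res = posterior_sss(locus, k_max=2, n_iter=100, seed=1)
        assert abs(res.posterior.sum() - 1.0) < 1e-9


class TestCredibleSet:
    def test_dominant_snp_singleton(self):
        locus = make_locus(np.eye(2), [8.0, 0.1])
        res = posterior_exhaustive(locus, k_max=1)
        assert res.pip[0] > 0.95
        assert credible_set(res, 0.95) == ["s1"]

    def test_level_one_includes_all_positive(self):
        locus, _ = sim_locus(m_snp=6, seed=10)
        res = posterior_exhaustive(locus, k_max=2)
        cs = credible_set(res, 1.0)
        assert set(cs) == {i for i, p in zip(res.variant_ids, res.pip) if p > 0}

    def test_cumulative_rule(self):
        from finelocus.finemap import FinemapResult

        res = FinemapResult(
            variant_ids=["snp1", "snp2", "snp3"],
            configs=[(0,), (1,), (2,)],
            log_bf=np.zeros(3),
            posterior=np.array([0.5, 0.3, 0.2]),
            pip=np.array([0.5, 0.3, 0.2]),
            k_max=1,
            prior_sd=3.0,
            p_k=np.array([0.5, 0.5]),
            mode="exhaustive",
        )
        assert credible_set(res, 0.75) == ["snp1", "snp2"]

    def test_all_zero_pips_warns_empty(self):
        from finelocus.finemap import FinemapResult

        res = FinemapResult(
            variant_ids=["a"], configs=[()], log_bf=np.zeros(1),
            posterior=np.ones(1), pip=np.zeros(1), k_max=0, prior_sd=3.0,
            p_k=np.ones(1), mode="exhaustive",
        )
        with pytest.warns(UserWarning):
            assert credible_set(res, 0.5) == []
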