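"""Transition matrix, genotype priors, truncated-normal MAF model, emissions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tapcnv import hmm
from tapcnv.hmm import (
    CellObservations,
    ChainLayout,
    HmmParams,
    _GenotypeTables,
    _emission_logprobs,
    emission_logprob,
    expected_maf,
    genotype_priors,
    transition_matrix,
    truncnorm_maf_density,
)


class TestTransitionMatrix:
    def test_default_epsilon_values(self):
        T = transition_matrix(1e-3, 5)
        assert np.allclose(np.diag(T), 0.999)
        assert np.allclose(T[0, 1], 0.00025)

    def test_two_state_example(self):
        np.testing.assert_allclose(transition_matrix(0.8, 2), [[0.2, 0.8], [0.8, 0.2]])

    @given(st.floats(1e-6, 1 - 1e-6), st.integers(2, 8))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one(self, eps, K):
        assert np.allclose(transition_matrix(eps, K).sum(axis=1), 1.0)

    def test_rejects_bad_epsilon(self):
        for eps in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                transition_matrix(eps, 5)


class TestExpectedMaf:
    @pytest.mark.parametrize(
        "m,k,value",
        [(1, 3, 1 / 3), (2, 4, 1 / 2), (1, 4, 1 / 4), (0, 1, 0.0), (0, 5, 0.0), (5, 5, 0.0)],
    )
    def test_known_values(self, m, k, value):
        assert expected_maf(m, k) == pytest.approx(value)

    def test_rejects_m_above_k(self):
        with pytest.raises(ValueError):
            expected_maf(3, 2)


class TestGenotypePriors:
    def test_diploid_matches_het_rate(self):
        gp = genotype_priors(2, 0.6)
        np.testing.assert_allclose(gp.prior, [0.2, 0.6, 0.2])
        np.testing.assert_allclose(gp.expected_maf, [0.0, 0.5, 0.0])

    def test_triploid_full_het(self):
        gp = genotype_priors(3, 1.0)
        np.testing.assert_allclose(gp.prior, [0.0, 0.5, 0.5, 0.0])
        assert gp.expected_maf[1] == gp.expected_maf[2] == pytest.approx(1 / 3)

    def test_diploid_zero_het(self):
        gp = genotype_priors(2, 0.0)
        np.testing.assert_allclose(gp.prior, [0.5, 0.0, 0.5])

    def test_monosomy_splits_evenly(self):
        gp = genotype_priors(1, 0.7)  # no heterozygote exists at one copy
        np.testing.assert_allclose(gp.prior, [0.5, 0.5])
        np.testing.assert_allclose(gp.expected_maf, [0.0, 0.0])

    @given(st.integers(1, 5), st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_priors_sum_to_one_and_mafs_bounded(self, k, h):
        gp = genotype_priors(k, h)
        assert np.isclose(gp.prior.sum(), 1.0)
        assert np.all((gp.expected_maf >= 0) & (gp.expected_maf <= 0.5))


class TestTruncnormMafDensity:
    def test_symmetry_about_mean(self):
        assert truncnorm_maf_density(0.2, 0.25, 0.07) == pytest.approx(
            truncnorm_maf_density(0.3, 0.25, 0.07)
        )

    @pytest.mark.parametrize("mu,sigma", [(0.0, 0.05), (0.25, 0.1), (0.5, 0.02), (1 / 3, 0.09)])
    def test_integrates_to_one(self, mu, sigma):
        val, _ = integrate.quad(lambda b: truncnorm_maf_density(b, mu, sigma), 0.0, 0.5)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_truncnorm(self):
        mu, sigma = 0.3, 0.08
        a, b = (0.0 - mu) / sigma, (0.5 - mu) / sigma
        grid = np.linspace(0.0, 0.5, 11)
        ours = truncnorm_maf_density(grid, mu, sigma)
        ref = stats.truncnorm.pdf(grid, a, b, loc=mu, scale=sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_large_sigma_limit_is_uniform(self):
        vals = [truncnorm_maf_density(b, 0.25, 1e4) for b in (0.0, 0.1, 0.25, 0.5)]
        np.testing.assert_allclose(vals, 2.0, rtol=1e-4)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            truncnorm_maf_density(0.2, 0.25, 0.0)


def _params(sigma_b=0.05, sigma_d2=0.1, het=(1.0,)):
    return HmmParams(
        mu=np.arange(1, 6) / 2.0,
        sigma_d2=sigma_d2,
        sigma_b=sigma_b,
        epsilon=1e-3,
        het_rates=np.array(het),
    )


def _brute_force_baf_loglik(mafs, k, h, sigma_b):
    """Independent oracle: explicit sum over minor-copy counts."""
    gp = genotype_priors(k, h)
    total = 0.0
    for p, mu in zip(gp.prior, gp.expected_maf):
        if p == 0:
            continue
        lik = p
        for b in mafs:
            lik *= truncnorm_maf_density(b, mu, sigma_b)
        total += lik
    return np.log(total)


class TestEmissionLogprob:
    def test_no_variants_reduces_to_depth_gaussian(self):
        p = _params()
        val = emission_logprob(1.0, [], 2, p, 1.0)
        expected = stats.norm.logpdf(1.0, 1.0, np.sqrt(p.sigma_d2))
        assert val == pytest.approx(expected)

    def test_both_missing_is_uninformative(self):
        assert emission_logprob(None, [], 3, _params(), 1.0) == 0.0

    def test_het_genotype_dominates_at_half(self):
        # diploid state, full heterozygosity, MAF exactly 0.5: the AB genotype
        # carries essentially all the mixture mass relative to homozygous
        p = _params(sigma_b=0.05)
        full = emission_logprob(None, [0.5], 2, p, 1.0)
        manual = _brute_force_baf_loglik([0.5], 2, 1.0, 0.05)
        assert full == pytest.approx(manual)
        het_only = np.log(truncnorm_maf_density(0.5, 0.5, 0.05))
        assert full == pytest.approx(het_only, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_brute_force_genotype_enumeration(self, k):
        rng = np.random.default_rng(k)
        mafs = rng.uniform(0, 0.5, size=3)
        h = 0.6
        p = _params(sigma_b=0.08)
        got = emission_logprob(None, mafs, k, p, h)
        want = _brute_force_baf_loglik(mafs, k, h, 0.08)
        assert got == pytest.approx(want, rel=1e-10)

    def test_joint_term_is_product_inside_genotype_sum(self):
        # with two variants the genotype sum of products differs from the
        # product of per-variant sums whenever 0 < h < 1
        p = _params(sigma_b=0.08)
        b1, b2, h = 0.45, 0.05, 0.5
        joint = emission_logprob(None, [b1, b2], 2, p, h)
        factored = emission_logprob(None, [b1], 2, p, h) + emission_logprob(None, [b2], 2, p, h)
        assert joint != pytest.approx(factored)
        assert joint == pytest.approx(_brute_force_baf_loglik([b1, b2], 2, h, 0.08), rel=1e-10)


class TestBatchedEmissions:
    def test_batch_matches_scalar_reference(self, small_panel):
        """The vectorized emission kernel agrees with the scalar implementation."""
        layout = ChainLayout.from_panel(small_panel)
        rng = np.random.default_rng(3)
        depth = rng.uniform(0.3, 2.5, size=(4, layout.n_amplicons))
        depth[0, 1] = np.nan
        maf = rng.uniform(0, 0.5, size=(4, 1))
        maf[2, 0] = np.nan
        het = np.array([0.7, 0.0, 0.3, 1.0])
        params = HmmParams(np.arange(1, 6) / 2, 0.09, 0.07, 1e-3, het)
        tables = _GenotypeTables(het, 5)
        emit = _emission_logprobs(
            np.nan_to_num(depth), np.isfinite(depth), np.nan_to_num(maf), np.isfinite(maf),
            np.tile(params.mu, (4, 1)), np.full(4, 0.09), np.full(4, 0.07), layout, tables,
        )
        for c in range(4):
            for i in range(layout.n_amplicons):
                mafs = maf[c, layout.variant_amp == i]
                for k in range(1, 6):
                    want = emission_logprob(depth[c, i], mafs, k, params, het[i])
                    assert emit[c, i, k - 1] == pytest.approx(want, rel=1e-9, abs=1e-9)
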