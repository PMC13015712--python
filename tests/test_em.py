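"""Baum-Welch properties: likelihood ascent, parameter recovery, decoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapcnv.hmm import (
    CallerConfig,
    CellObservations,
    ChainLayout,
    HmmParams,
    aggregate_segments,
    baum_welch,
    call_cells,
    genotype_priors,
    transition_matrix,
    viterbi_paths,
)
from tapcnv.io import AmpliconPanel, BafTable, CountMatrix, ReferenceSpec
from tapcnv.simulate import make_panel


def _layout(n_chr=4, amps=4, vars_per_amp=2) -> ChainLayout:
    return ChainLayout.from_panel(make_panel(n_chr, amps, vars_per_amp))


def sample_from_model(layout, params, states_per_chr, rng):
    """Generate observations from the emission model given true chromosome states."""
    n_amp = layout.n_amplicons
    states = np.array([states_per_chr[layout.chrom_index[i]] for i in range(n_amp)])
    depth = rng.normal(states / 2.0, np.sqrt(params.sigma_d2))
    maf = np.empty(len(layout.variant_ids))
    for v, amp in enumerate(layout.variant_amp):
        k = states[amp]
        gp = genotype_priors(k, params.het_rates[amp])
        mu = rng.choice(gp.expected_maf, p=gp.prior)
        a, b = (0 - mu) / params.sigma_b, (0.5 - mu) / params.sigma_b
        maf[v] = stats.truncnorm.rvs(a, b, loc=mu, scale=params.sigma_b, random_state=rng)
    return CellObservations(layout, depth, maf), states


def _baseline_params(layout, sigma_d2=0.09, sigma_b=0.06, het=1.0):
    return HmmParams(
        mu=np.arange(1, 6) / 2.0,
        sigma_d2=sigma_d2,
        sigma_b=sigma_b,
        epsilon=1e-3,
        het_rates=np.full(layout.n_amplicons, het),
    )


class TestLikelihoodAscent:
    def test_monotone_loglik_on_seeded_random_datasets(self):
        """EM log-likelihood never decreases, across 50 randomized problems.

        Datasets are drawn from the emission model with randomized karyotypes
        and noise levels (the sigma_b update follows the model's approximate
        M-step, so ascent is guaranteed only in the model's regime).
        """
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_chr = int(rng.integers(2, 6))
            layout = _layout(n_chr=n_chr, amps=int(rng.integers(2, 6)), vars_per_amp=int(rng.integers(0, 4)))
            truth = _baseline_params(
                layout,
                sigma_d2=float(rng.uniform(0.02, 0.3)),
                sigma_b=float(rng.uniform(0.03, 0.12)),
                het=float(rng.uniform(0.3, 1.0)),
            )
            states = rng.choice([1, 2, 2, 2, 3, 4, 5], size=n_chr)
            obs, _ = sample_from_model(layout, truth, states, rng)
            p0 = _baseline_params(layout, sigma_d2=0.2, sigma_b=0.08, het=float(truth.het_rates[0]))
            _, _, hist = baum_welch(obs, p0, max_iter=25)
            diffs = np.diff(hist)
            assert np.all(diffs >= -1e-8), f"seed {seed}: loglik decreased by {diffs.min()}"


class TestParameterRecovery:
    def test_mu_and_sigma_b_recovered_from_model_data(self):
        layout = _layout(n_chr=22, amps=4, vars_per_amp=3)
        truth = _baseline_params(layout, sigma_d2=0.09, sigma_b=0.06)
        rng = np.random.default_rng(42)
        # a karyotype touching states 1, 2 and 3
        states_per_chr = np.full(22, 2)
        states_per_chr[:4] = 3
        states_per_chr[4:7] = 1
        obs, _ = sample_from_model(layout, truth, states_per_chr, rng)
        fitted, _, _ = baum_welch(obs, truth)
        present = [0, 1, 2]  # states with data
        for k in present:
            assert abs(fitted.mu[k] - (k + 1) / 2.0) < 0.15
        assert abs(fitted.sigma_b - 0.06) / 0.06 < 0.30

    def test_zero_het_keeps_mu_at_prior(self):
        layout = _layout(n_chr=6, amps=4, vars_per_amp=0)
        params = _baseline_params(layout, het=0.0)
        rng = np.random.default_rng(5)
        obs, _ = sample_from_model(layout, params, np.full(6, 2), rng)
        fitted, _, _ = baum_welch(obs, params)
        # regularization pins the depth means near k/2 when heterozygosity is 0
        np.testing.assert_allclose(fitted.mu, np.arange(1, 6) / 2.0, atol=0.1)

    def test_epsilon_stays_small_for_single_state_truth(self):
        layout = _layout(n_chr=8, amps=5, vars_per_amp=2)
        params = _baseline_params(layout)
        rng = np.random.default_rng(9)
        obs, _ = sample_from_model(layout, params, np.full(8, 2), rng)
        fitted, _, _ = baum_welch(obs, params)
        assert fitted.epsilon <= 1e-2


class TestDecoding:
    def test_viterbi_recovers_trisomy_at_low_noise(self):
        layout = _layout(n_chr=1, amps=20, vars_per_amp=2)
        params = _baseline_params(layout, sigma_d2=0.04, sigma_b=0.04)
        rng = np.random.default_rng(1)
        obs, states = sample_from_model(layout, params, np.array([3]), rng)
        fitted, _, _ = baum_welch(obs, params)
        path = viterbi_paths(obs, fitted)
        assert np.mean(path == 3) >= 0.9

    def test_strong_monosomy_signal_gives_all_ones(self):
        layout = _layout(n_chr=2, amps=5, vars_per_amp=1)
        params = _baseline_params(layout, sigma_d2=0.01, sigma_b=0.02)
        rng = np.random.default_rng(2)
        obs, _ = sample_from_model(layout, params, np.array([1, 1]), rng)
        path = viterbi_paths(obs, params)
        assert np.all(path == 1)


class TestAggregation:
    @pytest.mark.parametrize(
        "path,expected",
        [
            ([3, 3, 3, 2], 3),       # plain mode
            ([1, 1, 3, 3], 1),       # tie: both distance 1 from diploid, lower wins
            ([2, 2, 2, 2], 2),
            ([1, 1, 2, 2], 2),       # tie: diploid beats distance-1 state
            ([3, 3, 4, 4], 3),       # tie: nearest to diploid wins
        ],
    )
    def test_modal_call_with_tie_breaks(self, path, expected):
        layout = ChainLayout.from_panel(make_panel(1, len(path), 0))
        assert aggregate_segments(np.array(path), layout)[0] == expected


class TestCallCells:
    def _dataset(self, rng, n_cells=20, vars_per_amp=2):
        panel = make_panel(3, 4, vars_per_amp)
        n_amp, n_var = 12, 12 * vars_per_amp
        cells = [f"c{i}" for i in range(n_cells)]
        counts = CountMatrix(
            panel.amplicons["amplicon_id"].tolist(),
            cells,
            rng.gamma(40.0, 0.05, size=(n_amp, n_cells)),  # tight around 2.0
        )
        if n_var:
            baf = BafTable(
                panel.variants["variant_id"].tolist(),
                cells,
                np.clip(rng.normal(0.5, 0.03, size=(n_var, n_cells)), 0, 1),
            )
        else:
            baf = BafTable([], cells, np.zeros((0, n_cells)))
        spec = ReferenceSpec(cells[:10], {})
        return counts, baf, panel, spec

    def test_reference_cells_called_at_reference_cn(self):
        rng = np.random.default_rng(0)
        counts, baf, panel, spec = self._dataset(rng)
        calls = call_cells(counts, baf, panel, spec)
        assert np.all(calls.calls == 2)

    def test_depth_only_mode_runs_without_variants(self):
        rng = np.random.default_rng(1)
        counts, baf, panel, spec = self._dataset(rng, vars_per_amp=0)
        calls = call_cells(counts, baf, panel, spec)
        assert calls.calls.shape == (20, 3)
        assert np.all((calls.calls >= 1) & (calls.calls <= 5))

    def test_unknown_reference_cell_rejected(self):
        rng = np.random.default_rng(2)
        counts, baf, panel, _ = self._dataset(rng)
        from tapcnv.io import LoadError

        with pytest.raises(LoadError, match="ghost"):
            call_cells(counts, baf, panel, ReferenceSpec(["ghost"], {}))
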