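"""Ground-truth construction, count/BAF generation, and study designs."""

import math

import numpy as np
import pandas as pd
import pytest

from tapcnv import simulate as sim
from tapcnv.evaluate import evaluate_calls, naive_baseline


class TestAmpliconParams:
    def test_scales_within_advertised_range(self):
        k, lam = sim.make_amplicon_params(200, np.random.default_rng(0))
        assert np.all((lam >= 0.5) & (lam <= 2.5))
        assert np.all(k >= 0.3)

    def test_seeded_reproducibility(self):
        a = sim.make_amplicon_params(50, np.random.default_rng(3))
        b = sim.make_amplicon_params(50, np.random.default_rng(3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_scale_rank_inverse_to_shape(self):
        k, lam = sim.make_amplicon_params(100, np.random.default_rng(1))
        order_k = np.argsort(k)
        order_lam = np.argsort(lam)[::-1]
        np.testing.assert_array_equal(order_k, order_lam)


class TestSimulateCounts:
    def _counts_at_cn(self, cn_values, shape, scale, n_cells, seed):
        panel = sim.make_panel(1, 1, 0)
        cn = pd.DataFrame(
            {"1": np.repeat(cn_values, n_cells)},
            index=[f"c{i}" for i in range(len(cn_values) * n_cells)],
        )
        rng = np.random.default_rng(seed)
        return sim.simulate_counts(cn, panel, np.array([shape]), np.array([scale]), rng), cn

    def test_mean_scales_linearly_with_cn(self):
        shape, scale = 2.0, 1.5
        cm, cn = self._counts_at_cn([1, 2, 3, 4, 5], shape, scale, 10000, 0)
        means = [cm.values[0, cn["1"].to_numpy() == c].mean() for c in range(1, 6)]
        slope = np.polyfit(range(1, 6), means, 1)[0]
        expected = scale * math.gamma(1 + 1 / shape) / 2.0
        assert abs(slope - expected) / expected < 0.05

    def test_cn4_to_cn2_mean_ratio_is_two(self):
        cm, cn = self._counts_at_cn([2, 4], 2.0, 1.5, 20000, 1)
        m2 = cm.values[0, cn["1"].to_numpy() == 2].mean()
        m4 = cm.values[0, cn["1"].to_numpy() == 4].mean()
        assert m4 / m2 == pytest.approx(2.0, rel=0.03)

    def test_integer_rounding_option(self):
        panel = sim.make_panel(1, 2, 0)
        cn = pd.DataFrame({"1": [2, 2]}, index=["c0", "c1"])
        rng = np.random.default_rng(0)
        cm = sim.simulate_counts(cn, panel, np.full(2, 2.0), np.full(2, 1.5), rng, integer_counts=True)
        assert np.all(cm.values == np.rint(cm.values))


class TestSimulateBaf:
    def _truth(self, config, populations, seed=0):
        return sim._build(config, populations, seed)

    def test_zero_noise_het_diploid_gives_half(self):
        cfg = sim.SimConfig(baf_sd=0.0, het_rate=1.0, n_chromosomes=2,
                            amplicons_per_chr=2, variants_per_amplicon=2)
        ds = sim._build(cfg, [("ref", 2, 5, 0)], seed=1)
        np.testing.assert_allclose(ds.baf.values, 0.5)

    def test_zero_het_gives_homozygous_maf(self):
        cfg = sim.SimConfig(baf_sd=0.0, het_rate=0.0, n_chromosomes=2,
                            amplicons_per_chr=2, variants_per_amplicon=2)
        ds = sim._build(cfg, [("ref", 2, 5, 0)], seed=1)
        maf = np.minimum(ds.baf.values, 1 - ds.baf.values)
        np.testing.assert_allclose(maf, 0.0)

    def test_trisomic_het_expected_maf_is_third(self):
        cfg = sim.SimConfig(baf_sd=0.0, het_rate=1.0, n_chromosomes=1,
                            amplicons_per_chr=1, variants_per_amplicon=4,
                            altered_fraction=1.0)
        ds = sim._build(cfg, [("ref", 2, 2, 0), ("alt", 3, 3, 1)], seed=2)
        alt_cols = [i for i, c in enumerate(ds.baf.cell_ids) if c.startswith("alt")]
        maf = np.minimum(ds.baf.values[:, alt_cols], 1 - ds.baf.values[:, alt_cols])
        np.testing.assert_allclose(maf, 1 / 3, atol=1e-12)

    def test_noise_truncated_to_unit_interval(self):
        cfg = sim.SimConfig(baf_sd=50.0, het_rate=1.0, n_chromosomes=2,
                            amplicons_per_chr=2, variants_per_amplicon=3)
        ds = sim._build(cfg, [("ref", 2, 20, 0)], seed=3)
        assert ds.baf.values.min() >= 0.0 and ds.baf.values.max() <= 1.0


class TestStudyDesigns:
    def test_study1_truth_marginals(self):
        ds = sim.build_study1(seed=7)
        pops = ds.truth.population.value_counts()
        assert set(pops.index) == {"cn1", "ref", "mixed", "cn3", "cn4", "cn5"}
        for p, n in pops.items():
            assert 72 <= n <= 88  # 80 cells with +-10% jitter
        for pop, cn in [("cn1", 1), ("cn3", 3), ("cn4", 4), ("cn5", 5)]:
            assert len(ds.truth.altered_chromosomes[pop]) == 7
            row = ds.truth.cn[ds.truth.population == pop].iloc[0]
            assert (row == cn).sum() == 7 and (row == 2).sum() == 15
        assert (ds.truth.cn[ds.truth.population == "ref"] == 2).all().all()
        assert (ds.truth.cn[ds.truth.population == "mixed"] == 2).all().all()

    def test_study1_naive_accuracy_on_unjittered_design(self):
        cfg = sim.SimConfig(study=1, cells_per_group=80, jitter=False)
        ds = sim.build_study1(seed=11, config=cfg)
        rep = evaluate_calls(naive_baseline(ds.truth.cn), ds.truth.cn)
        assert rep.accuracy == pytest.approx(104 / 132)

    def test_study1_replicates_differ(self):
        a = sim.build_study1(seed=1)
        b = sim.build_study1(seed=2)
        assert a.truth.altered_chromosomes != b.truth.altered_chromosomes

    def test_study2_naive_accuracy_and_direction(self):
        for direction, cn in [("gain", 3), ("loss", 1)]:
            ds = sim.build_study2(direction, seed=5)
            rep = evaluate_calls(naive_baseline(ds.truth.cn), ds.truth.cn)
            assert rep.accuracy == pytest.approx(37 / 44)
            alt = ds.truth.cn[ds.truth.population == "alt"]
            assert set(np.unique(alt)) == {2, cn}

    def test_study2_parameter_override(self):
        ds = sim.build_study2("gain", "amplicons_per_chr", 6, seed=1)
        assert len(ds.panel.amplicons) == 22 * 6
        ds = sim.build_study2("gain", "variants_per_amplicon", 0, seed=1)
        assert len(ds.panel.variants) == 0
        with pytest.raises(ValueError):
            sim.build_study2("gain", "nope", 1, seed=1)

    def test_study2_grid_has_108_runs(self):
        n_conditions = sum(len(v) for v in sim.STUDY2_GRID.values())
        assert n_conditions * 2 * 3 == 108  # x gains/losses x 3 replicates

    def test_dataset_byte_reproducible(self, tmp_path):
        for sub in ("a", "b"):
            sim.write_dataset(sim.build_study2("gain", seed=9), tmp_path / sub)
        for name in ("counts.tsv", "baf.tsv", "panel.tsv", "variants.tsv",
                     "reference.json", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_truth_roundtrip(self, tmp_path):
        ds = sim.build_study2("loss", seed=4)
        sim.write_truth(ds.truth, tmp_path / "truth.tsv")
        cn, pop = sim.read_truth(tmp_path / "truth.tsv")
        pd.testing.assert_frame_equal(cn, ds.truth.cn, check_names=False)
        assert (pop == ds.truth.population).all()
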