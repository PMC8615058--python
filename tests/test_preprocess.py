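import numpy as np
import pandas as pd
import pytest

from methdiff.preprocess import PipelineConfig, compute_ratios, correct_batch, filter_sites

from conftest import toy_matrix


class TestFilterSites:
    def test_site_below_coverage_in_one_sample_removed(self):
        total = np.full((3, 4), 12)
        total[1, 2] = 9
        m = toy_matrix(np.zeros_like(total), total)
        kept = filter_sites(m)
        assert kept.n_sites == 2
        assert 100 not in kept.sites["pos"].tolist()  # site index 1 sits at pos 100

    def test_saturated_site_removed_under_any_sample_scope(self):
        total = np.full((2, 3), 15)
        meth = np.zeros_like(total)
        meth[0, 1] = 15  # ratio 1.0 > 0.999 in one sample
        m = toy_matrix(meth, total)
        kept = filter_sites(m, saturation_scope="any_sample")
        assert kept.n_sites == 1

    def test_pooled_scope_keeps_binomially_saturated_site(self):
        # one sample at ratio 1.0 but pooled methylation well below the ceiling
        total = np.full((1, 4), 15)
        meth = np.array([[15, 13, 12, 14]])
        m = toy_matrix(meth, total)
        assert filter_sites(m, saturation_scope="site_mean").n_sites == 1
        assert filter_sites(m, saturation_scope="any_sample").n_sites == 0

    def test_boundary_coverage_retained(self):
        total = np.full((2, 3), 10)
        meth = (total * 0.5).astype(int)
        m = toy_matrix(meth, total)
        assert filter_sites(m).n_sites == 2

    def test_missing_site_fails_complete_case(self):
        total = np.array([[12, 0], [12, 12]])
        m = toy_matrix(np.zeros_like(total), total)
        assert filter_sites(m).sites["pos"].tolist() == [100]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        total = rng.integers(0, 30, size=(50, 5))
        meth = rng.binomial(total, 0.5)
        m = toy_matrix(meth, total)
        once = filter_sites(m)
        twice = filter_sites(once)
        pd.testing.assert_frame_equal(once.sites, twice.sites)
        assert np.array_equal(once.meth, twice.meth)

    def test_zero_sites_is_not_an_error(self):
        m = toy_matrix([[0, 0]], [[1, 1]])
        log = []
        out = filter_sites(m, log=log)
        assert out.n_sites == 0 and "0" in log[0]


class TestComputeRatios:
    def test_ratio_values(self):
        m = toy_matrix([[7, 0, 15]], [[10, 15, 15]])
        r = compute_ratios(m)
        assert r.ratio[0].tolist() == [0.7, 0.0, 1.0]

    def test_total_zero_is_an_error(self):
        m = toy_matrix([[0, 0]], [[0, 5]])
        with pytest.raises(ValueError, match="filter_sites"):
            compute_ratios(m)


class TestCorrectBatch:
    def test_single_batch_identity(self):
        m = toy_matrix([[3, 4, 5, 6]], [[10, 10, 10, 10]])
        r = compute_ratios(m)
        out = correct_batch(r)
        assert out.corrected
        np.testing.assert_array_equal(out.ratio, r.ratio)

    def test_noiseless_logit_offset_removed_exactly(self):
        # batch B shifted by +0.5 on the logit scale, no group effect
        rng = np.random.default_rng(0)
        n_sites, n = 200, 8
        base = rng.uniform(0.2, 0.8, size=n_sites)
        logit = np.log(base / (1 - base))[:, None] * np.ones((1, n))
        batches = ["a"] * 4 + ["b"] * 4
        logit[:, 4:] += 0.5
        ratio = 1 / (1 + np.exp(-logit))
        total = np.full((n_sites, n), 1000)
        m = toy_matrix(
            np.rint(ratio * 1000).astype(int), total,
            groups=["control", "control", "MDH", "MDH"] * 2,
            batches=batches,
            positions=np.arange(n_sites) * 50,
        )
        r = compute_ratios(m)
        r.ratio = ratio  # exact, bypass count rounding for the closed-form check
        out = correct_batch(r)
        diff = out.ratio[:, :4].mean(axis=1) - out.ratio[:, 4:].mean(axis=1)
        assert np.abs(diff).max() <= 1e-6

    def test_group_effect_survives_correction(self):
        # planted delta 0.2 plus a batch offset: recovered within +/-0.02
        rng = np.random.default_rng(1)
        n_sites = 2000
        base = rng.uniform(0.3, 0.6, size=n_sites)
        groups = ["control"] * 5 + ["MDH"] * 5
        batches = ["a", "b"] * 5
        ratio = np.tile(base[:, None], (1, 10))
        ratio[:, 5:] += 0.2
        logit = np.log(np.clip(ratio, 0.01, 0.99) / (1 - np.clip(ratio, 0.01, 0.99)))
        logit[:, [i for i, b in enumerate(batches) if b == "b"]] += 0.4
        ratio = 1 / (1 + np.exp(-logit)) + rng.normal(0, 0.01, size=(n_sites, 10))
        ratio = np.clip(ratio, 0.001, 0.999)
        m = toy_matrix(np.zeros((n_sites, 10), int), np.full((n_sites, 10), 10),
                       groups=groups, batches=batches, positions=np.arange(n_sites) * 10)
        r = compute_ratios(m)
        r.ratio = ratio
        out = correct_batch(r)
        delta = out.ratio[:, 5:].mean() - out.ratio[:, :5].mean()
        assert abs(delta - 0.2) <= 0.02

    def test_cross_sample_mean_preserved_in_logit_space(self):
        rng = np.random.default_rng(2)
        ratio = rng.uniform(0.1, 0.9, size=(100, 8))
        m = toy_matrix(np.zeros((100, 8), int), np.full((100, 8), 10),
                       groups=["control"] * 4 + ["MDH"] * 4, batches=["a", "b"] * 4)
        r = compute_ratios(m)
        r.ratio = ratio
        out = correct_batch(r)
        def logit(x):
            x = np.clip(x, 0.005, 0.995)
            return np.log(x / (1 - x))
        np.testing.assert_allclose(
            logit(out.ratio).mean(axis=1), logit(ratio).mean(axis=1), atol=1e-9
        )

    def test_confounded_batch_is_an_error(self):
        m = toy_matrix(
            np.zeros((3, 4), int), np.full((3, 4), 10),
            groups=["control", "control", "MDH", "MDH"],
            batches=["a", "a", "b", "b"],
        )
        r = compute_ratios(m)
        with pytest.raises(ValueError, match="confounded"):
            correct_batch(r)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig(min_delta=0.1, seed=7)
        p = tmp_path / "c.yaml"
        cfg.to_yaml(p)
        assert PipelineConfig.from_yaml(p) == cfg

    @pytest.mark.parametrize(
        "kw",
        [
            {"max_methylation": 1.5},
            {"alpha": 0.0},
            {"exclusivity_fraction": 1.2},
            {"min_coverage": 0},
            {"saturation_scope": "median"},
        ],
    )
    def test_threshold_validation(self, kw):
        with pytest.raises(ValueError):
            PipelineConfig(**kw)

    def test_defaults_are_study_criteria(self):
        cfg = PipelineConfig()
        assert (cfg.min_coverage, cfg.max_methylation, cfg.min_delta, cfg.alpha) == (10, 0.999, 0.08, 0.05)
        assert (cfg.neighbor_distance, cfg.min_dmr_dmcs, cfg.umr_max_meth) == (200, 2, 0.10)
        assert (cfg.exclusivity_fraction, cfg.promoter_bp, cfg.dmr_min_coverage) == (0.75, 1000, 1)
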