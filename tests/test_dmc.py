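import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methdiff.dmc import bh_adjust, call_dmcs, cluster_samples, ttest_site
from methdiff.preprocess import PipelineConfig, RatioMatrix


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, coded independently."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def bh_oracle(p):
    """Brute-force BH step-up: q_i = min over p_j >= p_i of m p_j / rank_j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {i: r + 1 for r, i in enumerate(order)}
    q = []
    for i in range(m):
        q.append(min(min(m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]), 1.0))
    return q


class TestTTest:
    def test_identical_means_zero_variance(self):
        t, p, d = ttest_site([0.5, 0.5, 0.5], [0.5, 0.5])
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_matches_textbook_oracle(self):
        a, b = (0.10, 0.12, 0.11), (0.50, 0.52, 0.48)
        t, p, d = ttest_site(a, b)
        to, po = pooled_t_oracle(a, b)
        assert abs(d - (-0.39)) < 1e-12
        assert abs(t - to) < 1e-10 and abs(p - po) < 1e-10

    def test_swap_antisymmetry(self):
        a, b = (0.1, 0.3, 0.2), (0.6, 0.4, 0.5)
        t1, p1, d1 = ttest_site(a, b)
        t2, p2, d2 = ttest_site(b, a)
        assert t2 == -t1 and p2 == p1 and d2 == -d1

    def test_zero_variance_unequal_means_clamped(self):
        t, p, d = ttest_site([0.2, 0.2], [0.8, 0.8])
        assert p == 1e-300 and t == -np.inf and d == pytest.approx(-0.6)

    def test_group_too_small(self):
        with pytest.raises(ValueError, match=">=2"):
            ttest_site([0.5], [0.4, 0.6])

    def test_welch_differs_under_unequal_variances(self):
        a, b = (0.1, 0.5, 0.9, 0.2), (0.40, 0.41, 0.39)
        _, p_pooled, _ = ttest_site(a, b)
        _, p_welch, _ = ttest_site(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert p_welch == pytest.approx(ref.pvalue, abs=1e-12)
        assert p_welch != p_pooled


class TestBH:
    def test_hand_case(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_singleton_and_all_ones(self):
        assert bh_adjust([0.5]).tolist() == [0.5]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust([0.1, float("nan")])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=8))
    def test_matches_bruteforce_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_order_preserved(self):
        p = [0.9, 0.01, 0.5]
        q = bh_adjust(p)
        assert q[1] == min(q)


def _ratio_matrix(ratio, groups):
    n_sites, n = ratio.shape
    samples = [f"S{i}" for i in range(n)]
    return RatioMatrix(
        sites=pd.DataFrame({"chrom": ["chr1"] * n_sites, "pos": np.arange(n_sites) * 300}),
        ratio=ratio,
        samples=samples,
        group=pd.Series(groups, index=samples),
        batch=pd.Series(["b0"] * n, index=samples),
    )


class TestCallDmcs:
    def test_effect_floor_blocks_small_delta(self):
        # strong q but |delta| = 0.079: not significant
        rng = np.random.default_rng(0)
        base = np.concatenate([rng.normal(0.5, 0.001, 5), rng.normal(0.579, 0.001, 5)])
        ratio = np.tile(base, (20, 1))
        ratio += rng.normal(0, 1e-4, ratio.shape)
        m = _ratio_matrix(ratio, ["control"] * 5 + ["MDH"] * 5)
        table = call_dmcs(m, "MDH_vs_control")
        assert (table["q"] < 0.05).all()
        assert (np.abs(table["delta"]) < 0.08).all()
        assert not table["significant"].any()

    def test_pooled_delta_lies_between_subgroup_deltas(self):
        rng = np.random.default_rng(1)
        ratio = rng.uniform(0, 1, size=(50, 20))
        groups = ["control"] * 6 + ["MDH"] * 7 + ["MDL"] * 7
        m = _ratio_matrix(ratio, groups)
        d_md = call_dmcs(m, "MD_vs_control")["delta"].to_numpy()
        d_h = call_dmcs(m, "MDH_vs_control")["delta"].to_numpy()
        d_l = call_dmcs(m, "MDL_vs_control")["delta"].to_numpy()
        lo, hi = np.minimum(d_h, d_l), np.maximum(d_h, d_l)
        assert ((d_md >= lo - 1e-12) & (d_md <= hi + 1e-12)).all()
        np.testing.assert_allclose(d_md, (7 * d_h + 7 * d_l) / 14, atol=1e-12)

    def test_small_group_rejected(self):
        m = _ratio_matrix(np.full((3, 3), 0.5), ["control", "MDH", "MDH"])
        with pytest.raises(ValueError, match=">=2"):
            call_dmcs(m, "MDH_vs_control")

    def test_unknown_comparison(self):
        m = _ratio_matrix(np.full((3, 4), 0.5), ["control", "control", "MDH", "MDH"])
        with pytest.raises(ValueError, match="comparison"):
            call_dmcs(m, "cases_vs_controls")

    def test_filter_then_fdr_restricts_bh_universe(self):
        rng = np.random.default_rng(3)
        ratio = rng.uniform(0.3, 0.7, size=(100, 8))
        ratio[:10, 4:] += 0.25
        m = _ratio_matrix(np.clip(ratio, 0, 1), ["control"] * 4 + ["MDH"] * 4)
        t1 = call_dmcs(m, "MDH_vs_control", PipelineConfig(filter_then_fdr=False))
        t2 = call_dmcs(m, "MDH_vs_control", PipelineConfig(filter_then_fdr=True))
        small = np.abs(t2["delta"]) < 0.08
        assert t2.loc[small, "q"].isna().all()
        assert t1["q"].notna().all()


class TestClusterSamples:
    def test_well_separated_groups_split_at_k2(self):
        rng = np.random.default_rng(0)
        n_sites, n = 300, 13
        ratio = rng.normal(0.5, 0.01, size=(n_sites, n))
        ratio[:, 6:] += 0.4
        groups = ["control"] * 6 + ["MDH"] * 7
        m = _ratio_matrix(np.clip(ratio, 0, 1), groups)
        table = call_dmcs(m, "MDH_vs_control")
        _, labels, rows = cluster_samples(m, table, top_k=150)
        assert len(rows) == 150
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_identical_samples_zero_distance(self):
        from scipy.spatial.distance import pdist

        ratio = np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 5))
        assert pdist(ratio.T).max() == 0.0

    def test_top_k_validation(self):
        m = _ratio_matrix(np.full((5, 4), 0.5), ["control", "control", "MDH", "MDH"])
        table = call_dmcs(m, "MDH_vs_control")
        with pytest.raises(ValueError):
            cluster_samples(m, table, top_k=0)
        with pytest.raises(ValueError):
            cluster_samples(m, table, top_k=10)
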