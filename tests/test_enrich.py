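import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from methdiff.enrich import compute_bias, enrichment_table, fit_pwf, wallenius_test


def bias_inputs(n_cpgs_map, dmc_rows):
    gene_cpgs = pd.Series(n_cpgs_map)
    dmc = pd.DataFrame(dmc_rows, columns=["gene_id", "delta"])
    return gene_cpgs, dmc


class TestBias:
    def test_formula_hand_case(self):
        gene_cpgs, dmc = bias_inputs({"G": 10}, [("G", 0.1), ("G", -0.3)])
        out = compute_bias(gene_cpgs, dmc)
        # mean |dDM| = 0.2 -> bias = 10 + 1/0.2 = 15
        assert out.loc[0, "bias"] == pytest.approx(15.0)
        assert out.loc[0, "n_dmc"] == 2 and out.loc[0, "sum_abs_dm"] == pytest.approx(0.4)

    def test_gene_without_dmcs_takes_cpg_count(self):
        gene_cpgs, dmc = bias_inputs({"G": 10}, [])
        assert compute_bias(gene_cpgs, dmc).loc[0, "bias"] == 10.0

    def test_doubling_deltas_halves_second_term(self):
        gene_cpgs, d1 = bias_inputs({"G": 10}, [("G", 0.1), ("G", 0.3)])
        _, d2 = bias_inputs({"G": 10}, [("G", 0.2), ("G", 0.6)])
        b1 = compute_bias(gene_cpgs, d1).loc[0, "bias"] - 10
        b2 = compute_bias(gene_cpgs, d2).loc[0, "bias"] - 10
        assert b2 == pytest.approx(b1 / 2)

    def test_bias_never_below_cpg_count(self):
        rng = np.random.default_rng(0)
        genes = {f"G{i}": int(rng.integers(1, 100)) for i in range(50)}
        rows = [(f"G{i}", float(rng.uniform(0.08, 0.5) * rng.choice([-1, 1])))
                for i in rng.integers(0, 50, 80)]
        gene_cpgs, dmc = bias_inputs(genes, rows)
        out = compute_bias(gene_cpgs, dmc)
        assert (out["bias"] >= out["n_cpgs"]).all()

    def test_permuting_gene_labels_permutes_bias(self):
        gene_cpgs, dmc = bias_inputs({"A": 5, "B": 9}, [("A", 0.2)])
        out = compute_bias(gene_cpgs, dmc).set_index("gene_id")
        gene_cpgs2 = gene_cpgs.rename({"A": "B", "B": "A"})
        gene_cpgs2 = pd.Series({"A": 9, "B": 5})
        dmc2 = pd.DataFrame([("B", 0.2)], columns=["gene_id", "delta"])
        out2 = compute_bias(gene_cpgs2, dmc2).set_index("gene_id")
        assert out.loc["A", "bias"] == out2.loc["B", "bias"]
        assert out.loc["B", "bias"] == out2.loc["A", "bias"]

    def test_zero_sum_with_dmcs_is_an_error(self):
        gene_cpgs, dmc = bias_inputs({"G": 10}, [("G", 0.0)])
        with pytest.raises(ValueError, match="zero"):
            compute_bias(gene_cpgs, dmc)


class TestPwf:
    def test_flat_null_gives_near_constant_weights(self):
        rng = np.random.default_rng(0)
        n = 2000
        bias = rng.uniform(1, 100, n)
        de = rng.random(n) < 0.3  # independent of bias
        w = fit_pwf(de, bias)
        assert w.max() - w.min() <= 0.25
        order = np.argsort(bias)
        # averaged over halves, weights are flat within +/-0.02
        assert abs(w[order][: n // 2].mean() - w[order][n // 2:].mean()) <= 0.02

    def test_isotonic_in_bias(self):
        rng = np.random.default_rng(1)
        bias = rng.uniform(0, 1, 500)
        de = rng.random(500) < bias
        w = fit_pwf(de, bias)
        order = np.argsort(bias)
        assert (np.diff(w[order]) >= -1e-12).all()

    def test_hand_pava_step_function(self):
        bias = np.arange(10, dtype=float)
        de = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        w = fit_pwf(de, bias)
        np.testing.assert_allclose(w, [1e-6] * 5 + [1.0] * 5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pwf(np.ones(20), np.arange(20))
        with pytest.raises(ValueError):
            fit_pwf(np.array([0, 1]), np.array([1.0, 2.0]))


def _universe(n, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n)]
    weights = pd.Series(rng.uniform(0.2, 2.0, n), index=genes)
    return genes, weights, rng


class TestWallenius:
    def test_equal_weights_match_exact_hypergeometric(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            M = int(rng.integers(20, 120))
            genes = [f"G{i}" for i in range(M)]
            weights = pd.Series(np.full(M, float(rng.uniform(0.5, 2.0))), index=genes)
            n_cat = int(rng.integers(2, M - 1))
            n_de = int(rng.integers(1, M - 1))
            cat = set(rng.choice(genes, n_cat, replace=False))
            de = set(rng.choice(genes, n_de, replace=False))
            p_over, p_under = wallenius_test(cat, de, weights)
            x = len(de & cat)
            assert p_over == pytest.approx(float(hypergeom.sf(x - 1, M, n_cat, n_de)), abs=1e-9)
            assert p_under == pytest.approx(float(hypergeom.cdf(x, M, n_cat, n_de)), abs=1e-9)

    def test_skewed_weights_match_sampling_null(self):
        # Monte-Carlo oracle: weighted sampling without replacement via
        # exponential race keys. Category and complement carry two distinct
        # weights, the regime where the univariate Wallenius urn is exact.
        genes, _, rng = _universe(50, seed=1)
        weights = pd.Series(np.where(np.arange(50) < 10, 2.2, 0.8), index=genes)
        cat = set(genes[:10])
        n_de = 15
        de = set(genes[:5]) | set(genes[30:40])  # x = 5 in the category
        reps = 30_000
        keys = rng.exponential(size=(reps, 50)) / weights.to_numpy()
        picks = np.argsort(keys, axis=1)[:, :n_de]
        in_cat = (picks < 10).sum(axis=1)
        x = len(de & cat)
        p_over, _ = wallenius_test(cat, de, weights)
        mc = (in_cat >= x).mean()
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(p_over - mc) <= 3 * max(se, 1e-3)

    def test_monotone_in_overlap(self):
        genes, weights, _ = _universe(40, seed=2)
        cat = set(genes[:12])
        ps = []
        for x in range(0, 9):
            de = set(genes[:x]) | set(genes[20 : 20 + (8 - x)])
            p_over, _ = wallenius_test(cat, de, weights)
            ps.append(p_over)
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_category_equal_to_universe(self):
        genes, weights, _ = _universe(10)
        p_over, p_under = wallenius_test(set(genes), {genes[0]}, weights)
        assert p_over == 1.0

    def test_empty_category_rejected(self):
        genes, weights, _ = _universe(10)
        with pytest.raises(ValueError, match="empty"):
            wallenius_test(set(), {genes[0]}, weights)


class TestEnrichmentTable:
    def _bias_table(self, genes, rng):
        return pd.DataFrame(
            {"gene_id": genes, "n_cpgs": rng.integers(5, 50, len(genes)),
             "n_dmc": 0, "sum_abs_dm": 0.0, "bias": rng.uniform(5, 50, len(genes))}
        )

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(100)]
        bias = self._bias_table(genes, rng)
        cat_planted = set(genes[:20])
        # 4x enrichment: DE rate 0.6 inside the category, 0.15 outside
        de = {g for i, g in enumerate(genes) if rng.random() < (0.6 if i < 20 else 0.15)}
        cats = {"PLANTED": cat_planted}
        for i in range(9):
            cats[f"NULL{i}"] = set(rng.choice(genes, 20, replace=False))
        out = enrichment_table(cats, de, bias)
        assert out.iloc[0]["category"] == "PLANTED"
        assert out.iloc[0]["q_over"] < 0.05

    def test_ratio_column_is_exact_arithmetic(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(60)]
        bias = self._bias_table(genes, rng)
        de = set(rng.choice(genes, 12, replace=False))
        cats = {f"C{i}": set(rng.choice(genes, rng.integers(3, 25), replace=False)) for i in range(6)}
        out = enrichment_table(cats, de, bias)
        assert (out["ratio"] == out["n_dm_in_cat"] / out["n_in_cat"]).all()

    def test_empty_overlap_category_reported_with_zero_ratio(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        bias = self._bias_table(genes, rng)
        de = set(genes[:5])
        out = enrichment_table({"C": set(genes[20:25])}, de, bias)
        assert out.iloc[0]["ratio"] == 0.0 and out.iloc[0]["p_over"] > 0.5

    def test_unknown_genes_dropped_from_category(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(30)]
        bias = self._bias_table(genes, rng)
        out = enrichment_table({"C": {"G1", "G2", "NOT_A_GENE"}}, {"G1", "G5"}, bias)
        assert out.iloc[0]["n_in_cat"] == 2 and out.iloc[0]["n_dropped"] == 1
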