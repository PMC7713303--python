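import numpy as np
import pandas as pd
import pytest
from scipy import stats

from islandtraits import pgls
from islandtraits import synthetic_data as sd
from islandtraits.errors import FitError


class TestFitPGLS:
    def test_identity_correlation_reduces_to_ols(self):
        y = np.array([1.0, 2.0, 3.0])
        res = pgls.fit_pgls(y, np.ones((3, 1)), correlation=np.eye(3))
        assert res.beta[0] == pytest.approx(2.0, abs=1e-12)
        assert res.RSS == pytest.approx(2.0, abs=1e-12)

    def test_exact_fit_has_zero_rss(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        beta = np.array([1.5, -0.7])
        res = pgls.fit_pgls(X @ beta, X, correlation=np.eye(10))
        np.testing.assert_allclose(res.beta, beta, atol=1e-10)
        assert res.RSS == pytest.approx(0.0, abs=1e-18)

    def test_whitening_matches_direct_normal_equations(self, tree_factory):
        """Two-route oracle: triangular whitening vs explicit-inverse GLS."""
        tree = tree_factory(30, seed=1)
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        C = pgls.brownian_correlation(tree)
        res = pgls.fit_pgls(y, X, tree=tree)
        Ci = np.linalg.inv(C)
        direct = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        np.testing.assert_allclose(res.beta, direct, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"Intercept": np.ones(8), "a": np.arange(8.0),
                          "b": 2 * np.arange(8.0)})
        with pytest.raises(FitError, match="aliased"):
            pgls.fit_pgls(np.arange(8.0), X, correlation=np.eye(8))

    def test_non_positive_definite_correlation_rejected(self):
        C = np.ones((4, 4))  # singular
        with pytest.raises(FitError, match="positive definite"):
            pgls.fit_pgls(np.arange(4.0), np.ones((4, 1)), correlation=C)


class TestAnovaF:
    def test_hand_computed_balanced_groups(self):
        """y = (0,1,1,2,2,3), 3 balanced groups: between-SS = 4, within-SS = 1.5;
        F = (4/2)/(1.5/3) = 4 with df (2, 3)."""
        y = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0])
        X = pgls.design_matrix(["a", "a", "b", "b", "c", "c"])
        full = pgls.fit_pgls(y, X, correlation=np.eye(6))
        red = pgls.fit_pgls(y, X[["Intercept"]], correlation=np.eye(6))
        ft = pgls.anova_f(full, red)
        assert ft.F == pytest.approx(4.0, abs=1e-10)
        assert (ft.df1, ft.df2) == (2, 3)
        assert ft.p_value == pytest.approx(stats.f.sf(4.0, 2, 3), abs=1e-12)

    def test_degrees_of_freedom_contract(self, tree_factory):
        # intercept + 2 habitat indicators on n tips -> df2 = n - 3
        tree = tree_factory(60, seed=3)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=4)
        y = np.array([tips[l] for l in tree.tip_labels])
        rng = np.random.default_rng(5)
        habs = rng.choice(["m", "c", "v"], size=60)
        X = pgls.design_matrix(habs)
        full = pgls.fit_pgls(y, X, tree=tree)
        red = pgls.fit_pgls(y, X[["Intercept"]], tree=tree)
        ft = pgls.anova_f(full, red)
        assert ft.df1 == 2 and ft.df2 == 57

    def test_non_nested_designs_rejected(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=12)
        X1 = pd.DataFrame({"Intercept": np.ones(12), "a": rng.normal(size=12)})
        X2 = pd.DataFrame({"b": rng.normal(size=12)})
        full = pgls.fit_pgls(y, X1, correlation=np.eye(12))
        red = pgls.fit_pgls(y, X2, correlation=np.eye(12))
        with pytest.raises(FitError, match="nested"):
            pgls.anova_f(full, red)


class TestContrasts:
    def _fit(self, y, habs, levels):
        X = pgls.design_matrix(habs, levels=levels)
        return pgls.fit_pgls(y, X, correlation=np.eye(len(y)))

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=15)
        y = np.concatenate([base, base, base])
        habs = ["m"] * 15 + ["c"] * 15 + ["v"] * 15
        fit = self._fit(y, habs, ["m", "c", "v"])
        cs = pgls.pairwise_contrasts(fit, ["m", "c", "v"], seed=1)
        assert (cs.p_adjusted > 0.9).all()
        assert len(set(cs.letters.values())) == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                            rng.normal(10, 1, 20)])
        habs = ["m"] * 20 + ["c"] * 20 + ["v"] * 20
        fit = self._fit(y, habs, ["m", "c", "v"])
        cs = pgls.pairwise_contrasts(fit, ["m", "c", "v"], seed=2)
        letters = cs.letters
        assert letters["v"] != letters["m"]
        assert letters["m"] == letters["c"]

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=45)
        habs = ["m"] * 15 + ["c"] * 15 + ["v"] * 15
        fit = self._fit(y, habs, ["m", "c", "v"])
        for method in ("mc", "holm"):
            cs = pgls.pairwise_contrasts(fit, ["m", "c", "v"], method=method,
                                         seed=3)
            assert (cs.p_adjusted >= cs.p_raw - 1e-12).all()

    def test_mc_adjustment_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=30)
        habs = ["m"] * 10 + ["c"] * 10 + ["v"] * 10
        fit = self._fit(y, habs, ["m", "c", "v"])
        a = pgls.pairwise_contrasts(fit, ["m", "c", "v"], seed=5)
        b = pgls.pairwise_contrasts(fit, ["m", "c", "v"], seed=5)
        np.testing.assert_array_equal(a.p_adjusted, b.p_adjusted)

    def test_letter_display_deterministic_function(self):
        letters = pgls.letter_display(["m", "c", "v"], [("m", "v")])
        assert letters["m"] != letters["v"]
        assert set(letters["c"]) & set(letters["m"])
        assert set(letters["c"]) & set(letters["v"])


class TestPhyloCorrelation:
    def test_self_correlation_is_one(self, bm_data):
        tree, vals, _ = bm_data
        out = pgls.phylo_correlation(vals, vals, tree, structure="BM")
        assert out["r"] == pytest.approx(1.0, abs=1e-10)

    def test_identity_reduces_to_pearson(self):
        import islandtraits.phylo as P
        star = P.parse_newick("(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=20), rng.normal(size=20)
        out = pgls.phylo_correlation(x, y, star, structure="BM")
        r_ref, p_ref = stats.pearsonr(x, y)
        assert out["r"] == pytest.approx(r_ref, abs=1e-10)
        assert out["p"] == pytest.approx(p_ref, abs=1e-10)
        assert out["df"] == 18

    def test_structure_selection_reports_choice(self, bm_data):
        tree, vals, _ = bm_data
        rng = np.random.default_rng(12)
        out = pgls.phylo_correlation(vals, vals + rng.normal(0, 0.3, vals.size),
                                     tree, structure="auto")
        assert out["structure"] in ("BM", "OU")

    def test_small_n_rejected(self, tree_factory):
        import islandtraits.phylo as P
        t = P.parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(FitError):
            pgls.phylo_correlation([1, 2, 3], [1, 2, 3], t)


class TestTreeSensitivity:
    def test_identical_trees_zero_spread(self, tree_factory):
        tree = tree_factory(40, seed=13)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=14)
        y = np.array([tips[l] for l in tree.tip_labels])
        rng = np.random.default_rng(15)
        habs = rng.choice(["m", "c", "v"], size=40)
        X = pgls.design_matrix(habs)
        out = pgls.tree_sensitivity([tree] * 4, y, X, X[["Intercept"]])
        assert (out.coef_stats["sd"] < 1e-12).all()
        assert out.prop_significant in (0.0, 1.0)
        assert not out.sensitive

    def test_strong_effect_always_significant(self, tree_factory):
        trees = [tree_factory(50, seed=20 + i) for i in range(5)]
        rng = np.random.default_rng(16)
        habs = np.array(["m", "c"] * 25)
        tips, _ = sd.simulate_trait(trees[0], "BM",
                                    {"sigma2": 0.1, "z0": 0.0}, seed=17)
        y = np.array([tips[l] for l in trees[0].tip_labels])
        y[habs == "c"] += 3.0
        X = pgls.design_matrix(habs)
        out = pgls.tree_sensitivity(trees, y, X, X[["Intercept"]])
        assert out.prop_significant == 1.0
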