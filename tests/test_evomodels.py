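import math

import numpy as np
import pytest
from scipy import stats

from islandtraits import evomodels as em
from islandtraits import phylo
from islandtraits import synthetic_data as sd
from islandtraits.errors import FitError, NotUltrametricError


class TestLoglikClosedForms:
    def test_bm_two_tip_star_is_bivariate_standard_normal(self):
        t = phylo.parse_newick("(A:1,B:1);")
        ln = em.model_loglik("BM", t, {"A": 0.0, "B": 0.0},
                             {"sigma2": 1.0, "z0": 0.0})
        assert ln == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_wn_is_sum_of_univariate_densities(self):
        t = phylo.parse_newick("(A:1,B:1,C:1);")
        x = {"A": 1.0, "B": 2.0, "C": 3.0}
        expected = stats.norm.logpdf([1, 2, 3], loc=2.0,
                                     scale=math.sqrt(2 / 3)).sum()
        ln = em.model_loglik("WN", t, x, {"mu": 2.0, "sigma2": 2 / 3})
        assert ln == pytest.approx(expected, abs=1e-12)

    def test_wn_equals_bm_on_unit_depth_star(self):
        t = phylo.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = {l: v for l, v in zip("ABCDE", [0.3, -1.2, 0.5, 2.0, -0.4])}
        wn = em.model_loglik("WN", t, x, {"mu": 0.1, "sigma2": 0.7})
        bm = em.model_loglik("BM", t, x, {"z0": 0.1, "sigma2": 0.7})
        assert wn == pytest.approx(bm, abs=1e-10)

    @pytest.mark.parametrize("method", ["dense", "pruning"])
    def test_ou_alpha_to_zero_reduces_to_bm(self, bm_data, method):
        tree, _, tips = bm_data
        bm = em.model_loglik("BM", tree, tips, {"sigma2": 1.0, "z0": 0.0},
                             method=method)
        ou = em.model_loglik("OU", tree, tips,
                             {"sigma2": 1.0, "z0": 0.0, "alpha": 1e-10},
                             method=method)
        assert ou == pytest.approx(bm, abs=1e-6)

    @pytest.mark.parametrize("method", ["dense", "pruning"])
    def test_eb_a_to_zero_reduces_to_bm(self, bm_data, method):
        tree, _, tips = bm_data
        bm = em.model_loglik("BM", tree, tips, {"sigma2": 1.0, "z0": 0.0},
                             method=method)
        eb = em.model_loglik("EB", tree, tips,
                             {"sigma2": 1.0, "z0": 0.0, "a": -1e-8},
                             method=method)
        assert eb == pytest.approx(bm, abs=1e-5)

    def test_domain_errors(self, bm_data):
        tree, _, tips = bm_data
        with pytest.raises(FitError):
            em.model_loglik("BM", tree, tips, {"sigma2": -1.0, "z0": 0.0})
        with pytest.raises(FitError):
            em.model_loglik("OU", tree, tips,
                            {"sigma2": 1.0, "z0": 0.0, "alpha": -0.1})
        with pytest.raises(FitError):
            em.model_loglik("EB", tree, tips,
                            {"sigma2": 1.0, "z0": 0.0, "a": 0.1})

    def test_non_ultrametric_refused_for_ou(self):
        t = phylo.parse_newick("((A:1,B:3):1,(C:1,D:1):3);")
        with pytest.raises(NotUltrametricError):
            em.model_loglik("OU", t, {"A": 0, "B": 1, "C": 0, "D": 1},
                            {"sigma2": 1.0, "z0": 0.0, "alpha": 0.5})
        # force flag overrides
        em.model_loglik("OU", t, {"A": 0, "B": 1, "C": 0, "D": 1},
                        {"sigma2": 1.0, "z0": 0.0, "alpha": 0.5},
                        method="dense", force=True)


class TestDensePruningEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_routes_agree_on_random_trees(self, tree_factory, seed):
        rng = np.random.default_rng(100 + seed)
        tree = tree_factory(int(rng.integers(6, 50)), seed=200 + seed)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 0.3, "z0": 0.0},
                                    seed=300 + seed)
        T = tree.height
        params = {
            "BM": {"sigma2": rng.uniform(0.1, 2), "z0": rng.normal()},
            "OU": {"sigma2": rng.uniform(0.1, 2), "z0": rng.normal(),
                   "alpha": rng.uniform(0.1, 5) / T},
            "EB": {"sigma2": rng.uniform(0.1, 2), "z0": rng.normal(),
                   "a": -rng.uniform(0.1, 5) / T},
            "WN": {"sigma2": rng.uniform(0.1, 2), "mu": rng.normal()},
        }
        for model, p in params.items():
            d = em.model_loglik(model, tree, tips, p, method="dense")
            q = em.model_loglik(model, tree, tips, p, method="pruning")
            assert d == pytest.approx(q, abs=1e-8), model


class TestFitModel:
    def test_wn_closed_form(self):
        t = phylo.parse_newick("(A:1,B:1,C:1,D:1);")
        f = em.fit_model("WN", t, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.0})
        assert f.params["mu"] == pytest.approx(2.0)
        assert f.params["sigma2"] == pytest.approx(0.5)  # ML variance
        assert f.k == 2

    def test_bm_degenerate_constant_trait(self, tree_factory):
        tree = tree_factory(10, seed=9)
        f = em.fit_model("BM", tree, {l: 3.3 for l in tree.tip_labels})
        assert f.params["sigma2"] == pytest.approx(0.0, abs=1e-12)
        assert f.params["z0"] == pytest.approx(3.3)

    def test_too_few_tips(self):
        t = phylo.parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(FitError, match="4 tips"):
            em.fit_model("BM", t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_bm_rate_recovery_single_replicate(self, tree_factory):
        tree = tree_factory(200, seed=42)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=43)
        f = em.fit_model("BM", tree, tips)
        assert 0.7 < f.params["sigma2"] < 1.3

    def test_ou_fit_recovers_strong_pull(self, tree_factory):
        tree = tree_factory(150, seed=44)
        alpha = 5.0 / tree.height
        tips, _ = sd.simulate_trait(
            tree, "OU", {"sigma2": 1.0, "z0": 0.0, "alpha": alpha}, seed=45)
        f = em.fit_model("OU", tree, tips)
        assert f.params["alpha"] > 0.5 / tree.height

    def test_missing_tips_prune_and_set_n(self, tree_factory):
        tree = tree_factory(20, seed=46)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=47)
        partial = {l: v for l, v in list(tips.items())[:12]}
        f = em.fit_model("BM", tree, partial)
        assert f.n == 12


class TestAICcMachinery:
    @pytest.mark.parametrize("lnL,k,n", [(-10.0, 2, 30), (-1468.971, 3, 1982),
                                         (0.5, 3, 10)])
    def test_aicc_identity(self, lnL, k, n):
        assert em.aicc(lnL, k, n) - (-2 * lnL + 2 * k) == pytest.approx(
            2 * k * (k + 1) / (n - k - 1), abs=1e-12)

    def test_weights_sum_to_one_and_order(self):
        w = em.akaike_weights([100.0, 102.0, 130.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] > w[1] > w[2]

    def test_equal_aicc_splits_weight(self):
        w = em.akaike_weights([50.0, 50.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_huge_deltas_give_degenerate_weights(self):
        w = em.akaike_weights([0.0, 165.238, 1161.223, 1163.237])
        assert w[0] == pytest.approx(1.0, abs=1e-12)
        assert w[1:].max() < 1e-12


class TestModelTable:
    def test_best_model_and_sorting(self, tree_factory):
        tree = tree_factory(60, seed=50)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=51)
        comp = em.model_table(tree, tips)
        rows = comp.to_rows()
        assert rows[0]["delta_AICc"] == 0.0
        assert rows[0]["model"] == comp.best
        deltas = [r["delta_AICc"] for r in rows]
        assert deltas == sorted(deltas)
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_tie_break_prefers_fewer_parameters(self):
        f1 = em.ModelFit("OU", {}, lnL=-10.0, k=3, n=50, AICc=26.0)
        f2 = em.ModelFit("BM", {}, lnL=-11.0, k=2, n=50, AICc=26.0)
        comp = em.compare_fits({"OU": f1, "BM": f2})
        assert comp.best == "BM"


class TestFitAcrossTrees:
    def test_identical_trees_zero_se(self, tree_factory):
        tree = tree_factory(25, seed=60)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=61)
        mt = em.fit_across_trees([tree] * 5, tips)
        assert all(se == pytest.approx(0.0, abs=1e-12)
                   for se in mt.se_weight.values())
        assert sum(mt.mean_weight.values()) == pytest.approx(1.0, abs=1e-8)

    def test_wn_data_selects_wn_across_trees(self, tree_factory):
        trees = [tree_factory(30, seed=70 + i) for i in range(8)]
        rng = np.random.default_rng(71)
        tips = {l: float(v) for l, v in
                zip(trees[0].tip_labels, rng.normal(0, 1, 30))}
        mt = em.fit_across_trees(trees, tips)
        assert mt.mean_weight["WN"] == max(mt.mean_weight.values())
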