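import numpy as np
import pytest

from islandtraits import phylo
from islandtraits import synthetic_data as sd
from islandtraits.errors import FitError, InvalidTreeError


class TestSimulateTree:
    def test_two_tip_cherry(self):
        t = sd.simulate_tree(2, seed=0)
        assert t.n_tips == 2
        assert t.is_ultrametric(1e-9)

    def test_binary_tree_node_count(self):
        t = sd.simulate_tree(100, seed=1)
        assert t.n_tips == 100
        assert t.n_nodes == 199  # 2n - 1 for a binary tree

    def test_ultrametric_at_tight_tolerance(self):
        for seed in range(5):
            t = sd.simulate_tree(50, seed=seed)
            ok, dev = phylo.validate_ultrametric(t, 1e-9)
            assert ok, dev

    def test_seed_determinism(self):
        a = phylo.write_newick(sd.simulate_tree(30, seed=7))
        b = phylo.write_newick(sd.simulate_tree(30, seed=7))
        assert a == b

    def test_birth_death_with_extinction(self):
        t = sd.simulate_tree(40, birth=0.3, death=0.1, seed=2)
        assert t.n_tips == 40
        assert t.is_ultrametric(1e-9)

    def test_invalid_rates_rejected(self):
        with pytest.raises(InvalidTreeError):
            sd.simulate_tree(10, birth=0.1, death=0.2, seed=0)
        with pytest.raises(InvalidTreeError):
            sd.simulate_tree(1, seed=0)


class TestSimulateTrait:
    def test_zero_rate_bm_is_constant(self, tree_factory):
        tree = tree_factory(20, seed=3)
        tips, states = sd.simulate_trait(tree, "BM",
                                         {"sigma2": 0.0, "z0": 1.7}, seed=4)
        assert all(v == pytest.approx(1.7) for v in tips.values())
        np.testing.assert_allclose(states, 1.7)

    def test_trait_determinism(self, tree_factory):
        tree = tree_factory(20, seed=5)
        a, _ = sd.simulate_trait(tree, "OU",
                                 {"sigma2": 1.0, "z0": 0.0, "alpha": 0.1},
                                 seed=6)
        b, _ = sd.simulate_trait(tree, "OU",
                                 {"sigma2": 1.0, "z0": 0.0, "alpha": 0.1},
                                 seed=6)
        assert a == b

    def test_ou_stationary_variance(self, tree_factory):
        """With alpha*T = 20 tips are near stationarity: across-tip variance
        approaches sigma2 / (2 alpha)."""
        tree = tree_factory(200, seed=7)
        alpha = 20.0 / tree.height
        target = 1.0 / (2 * alpha)
        vars_ = []
        for rep in range(200):
            tips, _ = sd.simulate_trait(
                tree, "OU", {"sigma2": 1.0, "z0": 0.0, "alpha": alpha},
                seed=1000 + rep)
            vars_.append(np.var(list(tips.values())))
        assert np.mean(vars_) == pytest.approx(target, rel=0.25)

    def test_wn_uncorrelated_with_patristic_distance(self, tree_factory):
        tree = tree_factory(100, seed=8)
        D = phylo.tree_matrices(tree).D
        iu = np.triu_indices(100, 1)
        cors = []
        for rep in range(20):
            tips, _ = sd.simulate_trait(tree, "WN", {"sigma2": 1.0, "mu": 0.0},
                                        seed=2000 + rep)
            x = np.array([tips[l] for l in tree.tip_labels])
            diffs = np.abs(x[:, None] - x[None, :])[iu]
            cors.append(np.corrcoef(diffs, D[iu])[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_bm_increments_match_rate(self, tree_factory):
        """Whitened tip values under the true BM covariance are i.i.d. with
        variance sigma2."""
        tree = tree_factory(500, seed=9)
        tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 2.0, "z0": 0.0},
                                    seed=10)
        x = np.array([tips[l] for l in tree.tip_labels])
        S = phylo.tree_matrices(tree).S
        W = np.linalg.cholesky(S)
        z = np.linalg.solve(W, x)
        assert np.var(z, ddof=0) == pytest.approx(2.0, rel=0.15)

    def test_domain_errors(self, tree_factory):
        tree = tree_factory(10, seed=11)
        with pytest.raises(FitError):
            sd.simulate_trait(tree, "EB", {"sigma2": 1.0, "z0": 0.0, "a": 0.5})
        with pytest.raises(FitError):
            sd.simulate_trait(tree, "nope", {"sigma2": 1.0, "z0": 0.0})


class TestHabitatScenario:
    def test_null_scenario_leaves_traits_untouched(self, tree_factory):
        sc = sd.SimScenario(n_tips=50, trait_model="BM",
                            trait_params={"sigma2": 1.0, "z0": 0.0}, seed=12)
        tree, hab, tips, _, _ = sd.simulate_scenario(sc)
        sc2 = sd.SimScenario(n_tips=50, trait_model="BM",
                             trait_params={"sigma2": 1.0, "z0": 0.0},
                             trait_shift={}, rate_multiplier={}, seed=12)
        _, _, tips2, _, _ = sd.simulate_scenario(sc2)
        assert tips == tips2

    def test_additive_shift_by_construction(self):
        diffs = []
        for rep in range(20):
            sc = sd.SimScenario(
                n_tips=150, trait_model="BM",
                trait_params={"sigma2": 0.1, "z0": 0.0},
                trait_shift={"volcanic_island": 0.3}, seed=100 + rep)
            tree, hab, tips, states = sd.simulate_scenario(sc)[:4]
            base = {l: states[t] for l, t in
                    zip(tree.tip_labels, tree.tip_ids)}
            v = [tips[l] - base[l] for l in tips if hab[l] == "volcanic_island"]
            m = [tips[l] - base[l] for l in tips if hab[l] == "mainland"]
            diffs.append(np.mean(v) - np.mean(m))
        assert np.mean(diffs) == pytest.approx(0.3, abs=1e-12)

    def test_rate_multiplier_inflates_terminal_rates(self):
        sc = sd.SimScenario(n_tips=200, trait_model="BM",
                            trait_params={"sigma2": 1.0, "z0": 0.0},
                            rate_multiplier={"continental_island": 8.0},
                            seed=13)
        tree, hab, tips, states = sd.simulate_scenario(sc)[:4]
        # |tip - parent| should be much larger for the fast habitat
        incr = {}
        for t, lab in zip(tree.tip_ids, tree.tip_labels):
            parent = tree.parent[t]
            incr[lab] = abs(tips[lab] - states[parent])
        fast = [incr[l] for l in incr if hab[l] == "continental_island"]
        slow = [incr[l] for l in incr if hab[l] != "continental_island"]
        assert np.mean(fast) > 3.0 * np.mean(slow)

    def test_widespread_fraction(self, tree_factory):
        sc = sd.SimScenario(n_tips=100, widespread_fraction=0.2, seed=14)
        _, hab, _, _, _ = sd.simulate_scenario(sc)
        assert sum(h == "widespread" for h in hab.values()) == 20

    def test_scenario_determinism(self):
        sc = sd.SimScenario(n_tips=40, seed=15)
        a = sd.simulate_scenario(sc)
        b = sd.simulate_scenario(sc)
        assert a[2] == b[2] and a[1] == b[1]

    def test_clade_block_clusters_habitats(self, tree_factory):
        sc = sd.SimScenario(n_tips=120, habitat_scheme="clade_block",
                            block_counts={"mainland": 1,
                                          "continental_island": 1,
                                          "volcanic_island": 1},
                            seed=16)
        tree, hab, _, _, _ = sd.simulate_scenario(sc)
        assert set(hab.values()) <= {"mainland", "continental_island",
                                     "volcanic_island"}


class TestMakeAssemblages:
    def test_full_overlap_identical(self, tree_factory):
        tree = tree_factory(40, seed=17)
        s1, s2 = sd.make_assemblages(tree, overlap=1.0, sizes=(15, 15), seed=18)
        assert s1 == s2

    def test_zero_overlap_disjoint(self, tree_factory):
        tree = tree_factory(40, seed=19)
        s1, s2 = sd.make_assemblages(tree, overlap=0.0, sizes=(15, 15), seed=20)
        assert not (s1 & s2)

    def test_intermediate_overlap_monotone_beta(self, tree_factory):
        from islandtraits import beta_div as bd
        tree = tree_factory(60, seed=21)
        sors = []
        for ov in (1.0, 0.5, 0.0):
            s1, s2 = sd.make_assemblages(tree, overlap=ov, sizes=(20, 20),
                                         seed=22)
            sors.append(bd.phylosor_pair(tree, s1, s2).beta_sor)
        assert sors[0] == 0.0
        assert sors[0] < sors[1] < sors[2]

    def test_infeasible_sizes_rejected(self, tree_factory):
        tree = tree_factory(10, seed=23)
        with pytest.raises(FitError):
            sd.make_assemblages(tree, overlap=0.0, sizes=(8, 8), seed=24)
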