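import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from latdiv import simulate as sim
from latdiv import traitmodels as tm
from latdiv import treeio


def expm_pruning_loglik(tree, states, mats_for, prior=(0.5, 0.5)):
    """Independent pruning oracle taking arbitrary per-branch matrices."""
    tips = np.array([states[lab] for lab in tree.tip_labels])
    down = [None] * tree.n_nodes
    logscale = 0.0
    for v in tree.postorder:
        if not tree.children[v]:
            down[v] = np.array([1.0 - tips[v], float(tips[v])])
            continue
        l = np.ones(2)
        for c in tree.children[v]:
            l = l * (mats_for(c) @ down[c])
        m = l.max()
        down[v] = l / m
        logscale += math.log(m)
    return math.log(prior[0] * down[tree.root][0]
                    + prior[1] * down[tree.root][1]) + logscale


def mk_expm_mats(tree, q01, q10):
    Q = np.array([[-q01, q01], [q10, -q10]])
    return lambda c: expm(Q * float(tree.length[c]))


def epoch_expm_mats(tree, params):
    ages = treeio.node_ages(tree)
    Qo = np.array([[-params.q_old, params.q_old], [params.q_old, -params.q_old]])
    Qy = np.array([[-params.q_young, params.q_young],
                   [params.q_young, -params.q_young]])

    def mats(c):
        a_c, a_p = float(ages[c]), float(ages[int(tree.parent[c])])
        if a_p <= params.tau:
            return expm(Qy * (a_p - a_c))
        if a_c >= params.tau:
            return expm(Qo * (a_p - a_c))
        return expm(Qo * (a_p - params.tau)) @ expm(Qy * (params.tau - a_c))

    return mats


class TestClassifyAffinity:
    @pytest.mark.parametrize("lat,expected", [
        (0.0, 0), (-45.0, 1), (23.43655, 1), (-23.43655, 1), (23.4, 0),
    ])
    def test_boundary_rule(self, lat, expected):
        assert tm.classify_affinity(lat) == expected

    def test_affinity_from_ranges(self):
        ranges = pd.DataFrame({"species": ["a", "b"], "min_lat": [-10.0, 30.0],
                               "max_lat": [10.0, 50.0]})
        states = tm.affinity_states(ranges)
        assert states["a"] == 0 and states["b"] == 1


class TestMkLoglik:
    def test_no_change_possible(self, cherry_tree):
        p = tm.MkParams(0.0, 0.0)
        assert tm.mk_loglik(cherry_tree, {"A": 0, "B": 0}, p) == pytest.approx(
            math.log(0.5))

    def test_impossible_data_flagged(self, cherry_tree):
        p = tm.MkParams(0.0, 0.0)
        assert tm.mk_loglik(cherry_tree, {"A": 0, "B": 1}, p) == -math.inf

    def test_worked_closed_form(self, cherry_tree):
        # L = 1/2 (P00^2 + P10^2) with P00 = (1 + e^{-2qt})/2 at q=0.5, t=1
        p = tm.MkParams(0.5, 0.5, symmetric=True)
        ll = tm.mk_loglik(cherry_tree, {"A": 0, "B": 0}, p)
        assert ll == pytest.approx(-1.2593663500769176, abs=1e-9)

    def test_missing_state_listed(self, three_tip_tree):
        with pytest.raises(ValueError, match="C"):
            tm.mk_loglik(three_tip_tree, {"A": 0, "B": 0}, tm.MkParams(0.1, 0.1))

    def test_matches_expm_oracle(self, rng):
        for _ in range(20):
            tree = sim.simulate_tree(n_tips=int(rng.integers(4, 11)), birth=0.2,
                                     seed=int(rng.integers(2**31)))
            q01, q10 = rng.uniform(0.01, 0.5, 2)
            states, _ = sim.simulate_binary_trait(tree, q01, q10,
                                                  seed=int(rng.integers(2**31)))
            ours = tm.mk_loglik(tree, states, tm.MkParams(q01, q10))
            oracle = expm_pruning_loglik(tree, states, mk_expm_mats(tree, q01, q10))
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_child_rotation(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        rotated = treeio.Phylogeny(tree.parent.copy(), tree.length.copy(),
                                   list(tree.tip_labels))
        for v in range(rotated.n_nodes):
            rotated.children[v] = rotated.children[v][::-1]
        rotated._postorder = None
        p = tm.MkParams(0.03, 0.01)
        assert tm.mk_loglik(rotated, states, p) == pytest.approx(
            tm.mk_loglik(tree, states, p), abs=1e-12)


class TestEpochLoglik:
    def test_nesting_identity(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        q = 0.07
        tau = 0.5 * tree.root_age()
        a = tm.epoch_loglik(tree, states, tm.EpochMkParams(tau, q, q))
        b = tm.mk_loglik(tree, states, tm.MkParams(q, q, symmetric=True))
        assert a == pytest.approx(b, abs=1e-10)

    def test_tau_beyond_root_error(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        with pytest.raises(ValueError, match="root"):
            tm.epoch_loglik(tree, states,
                            tm.EpochMkParams(tree.root_age() + 1, 0.1, 0.1))

    def test_matches_segment_product_oracle(self, rng):
        for _ in range(20):
            tree = sim.simulate_tree(n_tips=8, birth=0.2,
                                     seed=int(rng.integers(2**31)))
            states, _ = sim.simulate_binary_trait(tree, 0.1, 0.1,
                                                  seed=int(rng.integers(2**31)))
            params = tm.EpochMkParams(rng.uniform(0.1, 0.9) * tree.root_age(),
                                      *rng.uniform(0.01, 0.5, 2))
            ours = tm.epoch_loglik(tree, states, params)
            oracle = expm_pruning_loglik(tree, states, epoch_expm_mats(tree, params))
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestFitMk:
    def test_all_same_state_rate_collapses(self, yule_tree_50):
        states = pd.Series(0, index=yule_tree_50.tip_labels)
        fit = tm.fit_mk(yule_tree_50, states, symmetric=True)
        assert fit.params.q01 < 1e-6

    def test_symmetric_nested_in_asymmetric(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=31)
        sym = tm.fit_mk(yule_tree_50, states, symmetric=True)
        asym = tm.fit_mk(yule_tree_50, states, symmetric=False)
        assert sym.loglik <= asym.loglik + 1e-6

    def test_optimum_beats_probed_values(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=32)
        fit = tm.fit_mk(yule_tree_50, states, symmetric=True)
        for q in (0.001, 0.01, 0.05, 0.2):
            probed = tm.mk_loglik(yule_tree_50, states,
                                  tm.MkParams(q, q, symmetric=True))
            assert fit.loglik >= probed - 1e-8


class TestSweepEpochs:
    def test_profile_nonnegative(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=41)
        prof = tm.sweep_epochs(yule_tree_50, states, tau_min=5, tau_max=95, step=5)
        assert np.all(prof.delta_lnl >= 0.0)

    def test_grid_clipped_below_root(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=42)
        prof = tm.sweep_epochs(yule_tree_50, states, tau_min=10, tau_max=500, step=10)
        assert prof.taus.max() < yule_tree_50.root_age()

    def test_empty_grid_error(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=43)
        with pytest.raises(ValueError, match="empty"):
            tm.sweep_epochs(yule_tree_50, states, tau_min=150, tau_max=200)


class TestCompareModels:
    def test_aic_arithmetic_and_nesting(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.02, 0.02, seed=51)
        comp = tm.compare_models(yule_tree_50, states, tau_min=10, tau_max=90,
                                 step=10)
        tab = comp.table.set_index("model")
        assert list(tab["k"]) == [1, 2, 3]
        for model in tab.index:
            assert tab.loc[model, "AIC"] == pytest.approx(
                2 * tab.loc[model, "k"] - 2 * tab.loc[model, "lnL"])
        assert tab["dAIC"].min() == 0.0
        assert tab.loc["symmetric", "lnL"] <= tab.loc["asymmetric", "lnL"] + 1e-9
        assert tab.loc["symmetric", "lnL"] <= tab.loc["epoch", "lnL"] + 1e-9

    def test_model_selection_calibration(self):
        # homogeneous truth -> symmetric wins most.  For the epoch arm a
        # decelerating shift (fast old epoch, slow young epoch) is used:
        # a late symmetric acceleration is largely mimicked by asymmetric
        # homogeneous rates, whereas deep mixing followed by recent
        # stasis in both states is only explained by the epoch model.
        hom_wins = ep_wins = 0
        n = 7
        for s in range(n):
            tree = sim.scale_to_age(
                sim.simulate_tree(n_tips=150, birth=0.05, seed=600 + s), 140.0)
            st_h, _ = sim.simulate_binary_trait(tree, 0.01, 0.01, seed=700 + s)
            comp_h = tm.compare_models(tree, st_h, step=4)
            hom_wins += comp_h.best_model == "symmetric"
            tree_e = sim.scale_to_age(
                sim.simulate_tree(n_tips=300, birth=0.05, seed=600 + s), 140.0)
            st_e, _ = sim.simulate_binary_trait(
                tree_e, 0, 0, seed=800 + s,
                epoch=tm.EpochMkParams(40.0, 0.02, 0.002))
            comp_e = tm.compare_models(tree_e, st_e, step=4)
            ep_wins += comp_e.best_model == "epoch"
        assert hom_wins > n / 2
        assert ep_wins > n / 2


class TestMarginalAsr:
    def test_zero_rate_all_tropical(self, yule_tree_50):
        states = pd.Series(0, index=yule_tree_50.tip_labels)
        rec = tm.marginal_asr(yule_tree_50, states, tm.MkParams(1e-12, 1e-12))
        assert np.all(rec.p_extratropical < 1e-6)

    def test_worked_root_probability(self, cherry_tree):
        rec = tm.marginal_asr(cherry_tree, {"A": 0, "B": 0},
                              tm.MkParams(0.5, 0.5, symmetric=True))
        p_trop = 1.0 - rec.p_extratropical[cherry_tree.root]
        assert p_trop == pytest.approx(0.8240271368, abs=1e-6)

    def test_tips_reproduce_observed_states(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        rec = tm.marginal_asr(tree, states, tm.MkParams(0.02, 0.01))
        np.testing.assert_array_equal(
            rec.p_extratropical[: tree.n_tips],
            states.loc[list(tree.tip_labels)].to_numpy().astype(float))
        assert np.all((rec.p_extratropical >= 0) & (rec.p_extratropical <= 1))

    def test_mirrored_states_mirror_probabilities(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        p = tm.MkParams(0.03, 0.03, symmetric=True)
        a = tm.marginal_asr(tree, states, p).p_extratropical
        b = tm.marginal_asr(tree, 1 - states, p).p_extratropical
        np.testing.assert_allclose(a, 1.0 - b, atol=1e-10)

    def test_matches_enumeration_oracle(self, rng):
        # brute-force sum over all internal-node state assignments
        tree = sim.simulate_tree(n_tips=5, birth=0.2, seed=90)
        states, _ = sim.simulate_binary_trait(tree, 0.15, 0.15, seed=91)
        q01, q10 = 0.12, 0.3
        params = tm.MkParams(q01, q10)
        mats = mk_expm_mats(tree, q01, q10)
        tips = {lab: int(states[lab]) for lab in tree.tip_labels}
        internals = [v for v in range(tree.n_nodes) if tree.children[v]]
        prior = (0.5, 0.5)
        total = np.zeros(1)
        node_mass = {v: np.zeros(2) for v in internals}
        for assign in itertools.product((0, 1), repeat=len(internals)):
            full = dict(zip(internals, assign))
            full.update({tree.tip_id(lab): s for lab, s in tips.items()})
            lik = prior[full[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    lik *= mats(v)[full[int(tree.parent[v])], full[v]]
            total += lik
            for v in internals:
                node_mass[v][full[v]] += lik
        rec = tm.marginal_asr(tree, states, params)
        for v in internals:
            expected = node_mass[v][1] / total[0]
            assert rec.p_extratropical[v] == pytest.approx(expected, abs=1e-10)


class TestStochasticMaps:
    def test_zero_rate_uniform_tips(self, yule_tree_50):
        states = pd.Series(1, index=yule_tree_50.tip_labels)
        maps = tm.stochastic_maps(yule_tree_50, states, tm.MkParams(1e-12, 1e-12),
                                  n_sims=50, seed=0)
        assert np.all(maps.node_freq_extratropical > 0.999)
        assert maps.mean_changes == pytest.approx(0.0)

    def test_deterministic_under_seed(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        p = tm.MkParams(0.02, 0.02, symmetric=True)
        a = tm.stochastic_maps(tree, states, p, n_sims=200, seed=5)
        b = tm.stochastic_maps(tree, states, p, n_sims=200, seed=5)
        assert a.mean_changes == b.mean_changes
        np.testing.assert_array_equal(a.changes, b.changes)

    def test_node_frequencies_near_marginals(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        p = tm.fit_mk(tree, states, symmetric=True).params
        marg = tm.marginal_asr(tree, states, p).p_extratropical
        n = 4000
        maps = tm.stochastic_maps(tree, states, p, n_sims=n, seed=6)
        se = np.sqrt(np.maximum(marg * (1 - marg), 1e-12) / n)
        assert np.all(np.abs(maps.node_freq_extratropical - marg)
                      <= 3 * se + 1e-9)

    def test_epoch_params_supported(self, eight_tip_fixture):
        tree, states, _ = eight_tip_fixture
        params = tm.EpochMkParams(0.4 * tree.root_age(), 0.005, 0.05)
        maps = tm.stochastic_maps(tree, states, params, n_sims=500, seed=7)
        marg = tm.marginal_asr(tree, states, params).p_extratropical
        se = np.sqrt(np.maximum(marg * (1 - marg), 1e-12) / 500)
        assert np.all(np.abs(maps.node_freq_extratropical - marg)
                      <= 4 * se + 0.01)
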