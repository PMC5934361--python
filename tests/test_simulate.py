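import math

import numpy as np
import pandas as pd
import pytest

from latdiv import simulate as sim
from latdiv import treeio
from latdiv.traitmodels import TROPIC_BOUNDARY, EpochMkParams, affinity_states


class TestSimulateTree:
    def test_two_tip_cherry(self):
        t = sim.simulate_tree(n_tips=2, birth=0.1, seed=0)
        assert t.n_tips == 2
        d = t.depths[:2]
        assert d[0] == pytest.approx(d[1])

    def test_deterministic_under_seed(self):
        a = sim.simulate_tree(n_tips=25, birth=0.1, death=0.03, seed=7)
        b = sim.simulate_tree(n_tips=25, birth=0.1, death=0.03, seed=7)
        assert a.to_newick() == b.to_newick()

    def test_requested_tip_count_and_ultrametric(self):
        t = sim.simulate_tree(n_tips=64, birth=0.1, death=0.04, seed=3)
        assert t.n_tips == 64
        assert t.is_ultrametric()

    def test_yule_expected_tip_count(self):
        # 2 starting lineages for T my: E[N] = 2 exp(birth*T)
        rng = np.random.default_rng(42)
        counts = [
            sim.simulate_tree(crown_age=10.0, birth=0.1, n_start=2,
                              seed=int(rng.integers(2**31))).n_tips
            for _ in range(2000)
        ]
        counts = np.asarray(counts)
        expected = 2 * math.exp(0.1 * 10.0)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            sim.simulate_tree(n_tips=10, crown_age=5.0, birth=0.1)
        with pytest.raises(ValueError):
            sim.simulate_tree(n_tips=1, birth=0.1)


class TestSimulateBinaryTrait:
    def test_zero_rates_keep_root_state(self, yule_tree_50):
        states, truth = sim.simulate_binary_trait(yule_tree_50, 0.0, 0.0,
                                                  root_state=1, seed=0)
        assert (states == 1).all()
        assert truth.n_transitions == 0

    def test_transition_count_poisson_mean(self, yule_tree_50):
        # with q01 = q10 = q the change process is Poisson(q * tree length)
        q = 0.02
        total_len = float(yule_tree_50.length.sum())
        rng = np.random.default_rng(1)
        counts = np.array([
            sim.simulate_binary_trait(yule_tree_50, q, q,
                                      seed=int(rng.integers(2**31)))[1].n_transitions
            for _ in range(2000)
        ])
        expected = q * total_len
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_stationary_tip_frequency(self, yule_tree_50):
        # fast rates: tip state-1 frequency -> q01/(q01+q10)
        q01, q10 = 1.5, 0.5
        rng = np.random.default_rng(2)
        freqs = np.array([
            sim.simulate_binary_trait(yule_tree_50, q01, q10,
                                      seed=int(rng.integers(2**31)))[0].mean()
            for _ in range(500)
        ])
        se = freqs.std(ddof=1) / math.sqrt(len(freqs))
        assert abs(freqs.mean() - q01 / (q01 + q10)) < 3 * se

    def test_tip_marginals_match_matrix_exponential(self, eight_tip_fixture):
        from scipy.linalg import expm

        tree, _, _ = eight_tip_fixture
        q01, q10 = 0.012, 0.004
        Q = np.array([[-q01, q01], [q10, -q10]])
        # ultrametric: every tip marginal is P(root age)[0, 1]
        p1 = expm(Q * tree.root_age())[0, 1]
        rng = np.random.default_rng(3)
        n = 2000
        freq = np.zeros(tree.n_tips)
        for _ in range(n):
            st, _ = sim.simulate_binary_trait(tree, q01, q10,
                                              seed=int(rng.integers(2**31)))
            freq += st.to_numpy()
        freq /= n
        se = math.sqrt(p1 * (1 - p1) / n)
        assert np.all(np.abs(freq - p1) < 3 * se + 1e-12)


class TestSimulateRanges:
    def test_affinity_round_trip(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.3, 0.3, seed=4)
        ranges = sim.simulate_ranges(states, seed=5)
        recovered = affinity_states(ranges)
        pd.testing.assert_series_equal(
            recovered.sort_index(), states.sort_index(), check_names=False)

    def test_midpoints_respect_boundary(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.3, 0.3, seed=6)
        ranges = sim.simulate_ranges(states, seed=7)
        mid = (ranges["min_lat"] + ranges["max_lat"]) / 2
        by_species = dict(zip(ranges["species"], mid))
        for sp, s in states.items():
            if s == 0:
                assert abs(by_species[sp]) < TROPIC_BOUNDARY
            else:
                assert abs(by_species[sp]) >= TROPIC_BOUNDARY

    def test_latitudes_in_bounds(self, yule_tree_50):
        states, _ = sim.simulate_binary_trait(yule_tree_50, 0.5, 0.5, seed=8)
        ranges = sim.simulate_ranges(states, seed=9)
        assert (ranges["min_lat"] >= -90).all() and (ranges["max_lat"] <= 90).all()


class TestSimulateTipRates:
    def _ranges(self, tree, seed):
        states, _ = sim.simulate_binary_trait(tree, 0.02, 0.02, seed=seed)
        return sim.simulate_ranges(states, seed=seed + 1)

    def test_single_regime_no_noise_constant(self, yule_tree_50):
        ranges = self._ranges(yule_tree_50, 10)
        rates, _ = sim.simulate_tip_rates(yule_tree_50, 1, [0.05], 0.0, ranges,
                                          seed=11, noise_sd=0.0)
        assert np.allclose(rates["rate"], 0.05)

    def test_regimes_are_monophyletic_partition(self, yule_tree_50):
        ranges = self._ranges(yule_tree_50, 12)
        rates, truth = sim.simulate_tip_rates(yule_tree_50, 5, [0.02] * 5, 0.0,
                                              ranges, seed=13)
        assert sorted(rates["species"]) == sorted(yule_tree_50.tip_labels)
        assert rates["regime"].nunique() == 5
        for tips in truth.regimes.values():
            ids = [yule_tree_50.tip_id(s) for s in tips]
            m = ids[0]
            for i in ids[1:]:
                m = yule_tree_50.mrca(m, i)
            # clade of the MRCA contains exactly the regime's tips
            under = sim._tips_under(yule_tree_50, m)
            assert sorted(under) == sorted(tips)

    def test_null_beta_uncorrelated(self, yule_tree_50):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(14)
        stats = []
        for _ in range(200):
            ranges = self._ranges(yule_tree_50, int(rng.integers(2**30)))
            rates, _ = sim.simulate_tip_rates(
                yule_tree_50, 5, np.exp(rng.normal(-3, 0.5, 5)), 0.0, ranges,
                seed=int(rng.integers(2**30)), noise_sd=0.2)
            mid = (ranges["min_lat"] + ranges["max_lat"]).abs() / 2
            stats.append(spearmanr(rates.sort_values("species")["rate"],
                                   ranges.assign(m=mid).sort_values("species")["m"]).statistic)
        stats = np.array(stats)
        se = stats.std(ddof=1) / math.sqrt(len(stats))
        assert abs(stats.mean()) < 3 * se

    def test_negative_beta_induces_negative_correlation(self):
        from scipy.stats import spearmanr

        tree = sim.scale_to_age(sim.simulate_tree(n_tips=300, birth=0.05, seed=15),
                                140.0)
        states, _ = sim.simulate_binary_trait(tree, 0.02, 0.02, seed=16)
        ranges = sim.simulate_ranges(states, seed=17)
        rates, _ = sim.simulate_tip_rates(tree, 1, [0.05], -2.0, ranges, seed=18,
                                          noise_sd=0.05)
        df = rates.merge(ranges, on="species")
        rho = spearmanr(df["rate"],
                        ((df["min_lat"] + df["max_lat"]) / 2).abs()).statistic
        assert rho < -0.5

    def test_too_many_regimes_error(self, cherry_tree):
        ranges = pd.DataFrame({"species": ["A", "B"], "min_lat": [0, 0],
                               "max_lat": [1, 1]})
        with pytest.raises(ValueError, match="exceeds"):
            sim.simulate_tip_rates(cherry_tree, 3, [1, 1, 1], 0.0, ranges, seed=0)


class TestSimulateIncidence:
    def test_interval_overlap(self):
        ranges = pd.DataFrame({"species": ["a", "b"], "min_lat": [0, 0],
                               "max_lat": [10, 10]})
        polys = pd.DataFrame({"polygon": ["p", "q"], "min_lat": [5, 20],
                              "max_lat": [15, 30]})
        inc = sim.simulate_incidence(ranges, polys)
        assert inc.loc["a", "p"] == 1 and inc.loc["a", "q"] == 0

    def test_total_matches_brute_force(self, rng):
        S, P = 40, 12
        ranges = pd.DataFrame({
            "species": [f"s{i}" for i in range(S)],
            "min_lat": rng.uniform(-90, 80, S)})
        ranges["max_lat"] = ranges["min_lat"] + rng.uniform(0, 10, S)
        lo = rng.uniform(-90, 80, P)
        polys = pd.DataFrame({"polygon": [f"p{j}" for j in range(P)],
                              "min_lat": lo, "max_lat": lo + rng.uniform(0, 20, P)})
        inc = sim.simulate_incidence(ranges, polys)
        brute = sum(
            1
            for _, r in ranges.iterrows()
            for _, p in polys.iterrows()
            if not (r["max_lat"] < p["min_lat"] or p["max_lat"] < r["min_lat"])
        )
        assert inc.to_numpy().sum() == brute

    def test_empty_polygons_error(self):
        ranges = pd.DataFrame({"species": ["a"], "min_lat": [0], "max_lat": [1]})
        with pytest.raises(ValueError, match="empty"):
            sim.simulate_incidence(ranges, ranges.iloc[:0].rename(
                columns={"species": "polygon"}))
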