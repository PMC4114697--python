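import math

import numpy as np
import pytest

from oracles import ctmc_matrix, enum_loglik, enum_posteriors
from srnaevo import gainloss as gl
from srnaevo.synthdata import simulate_trait, simulate_tree
from srnaevo.treeio import parse_newick


def random_profile(tree, rng, trait_id="t", p_missing=0.15):
    states = {}
    for leaf in tree.leaves():
        u = rng.random()
        states[leaf] = None if u < p_missing else int(u > 0.5)
    if all(v is None for v in states.values()):
        states[tree.leaves()[0]] = 1
    return gl.PhyleticProfile(trait_id, states)


class TestTransitionMatrix:
    def test_identity_at_t_zero(self):
        assert np.allclose(gl.transition_matrix(1, 1, 0), np.eye(2))

    def test_stationary_limit(self):
        P = gl.transition_matrix(1, 3, 1e6)
        assert np.allclose(P, [[0.75, 0.25], [0.75, 0.25]])

    def test_matches_matrix_exponential(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g, l = rng.uniform(0.05, 5, 2)
            t = rng.uniform(0, 10)
            assert np.allclose(
                gl.transition_matrix(g, l, t), ctmc_matrix(g, l, t), atol=1e-12
            )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            gl.transition_matrix(0, 1, 1)
        with pytest.raises(ValueError):
            gl.transition_matrix(1, 1, -0.1)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            g, l = rng.uniform(0.05, 8, 2)
            t1, t2 = rng.uniform(0, 5, 2)
            lhs = gl.transition_matrix(g, l, t1) @ gl.transition_matrix(g, l, t2)
            assert np.allclose(lhs, gl.transition_matrix(g, l, t1 + t2), atol=1e-12)


class TestPruningLoglik:
    def test_zero_branch_both_present_gives_log_prior(self):
        tree = parse_newick("(A:0,B:0):0;")
        prof = gl.PhyleticProfile("t", {"A": 1, "B": 1})
        model = gl.GainLossModel.single(0.4, 1.2)
        pi1 = 0.4 / 1.6
        assert gl.pruning_loglik(tree, prof, model) == pytest.approx(math.log(pi1))

    def test_two_leaf_pattern_by_hand(self):
        t = 0.7
        g, l = 0.6, 1.1
        tree = parse_newick(f"(A:{t},B:{t}):0;")
        prof = gl.PhyleticProfile("t", {"A": 1, "B": 0})
        model = gl.GainLossModel.single(g, l)
        P = gl.transition_matrix(g, l, t)
        prior = model.prior(g, l)
        expected = sum(prior[s] * P[s, 1] * P[s, 0] for s in (0, 1))
        assert gl.pruning_loglik(tree, prof, model) == pytest.approx(
            math.log(expected), abs=1e-12
        )

    def test_matches_enumeration_oracle(self, small_tree):
        rng = np.random.default_rng(11)
        for rep in range(5):
            g, l = rng.uniform(0.1, 3, 2)
            prof = random_profile(small_tree, rng, f"t{rep}")
            model = gl.GainLossModel.single(g, l)
            assert gl.pruning_loglik(small_tree, prof, model) == pytest.approx(
                enum_loglik(small_tree, prof, g, l), abs=1e-10
            )

    def test_mixture_is_weighted_sum_of_category_likelihoods(self, small_tree):
        rng = np.random.default_rng(5)
        prof = random_profile(small_tree, rng)
        cats = [(0.3, 1.0, 0.4), (2.0, 0.5, 0.6)]
        model = gl.GainLossModel(cats)
        expected = math.log(
            sum(w * math.exp(enum_loglik(small_tree, prof, g, l)) for g, l, w in cats)
        )
        assert gl.pruning_loglik(small_tree, prof, model) == pytest.approx(
            expected, abs=1e-10
        )

    def test_non_leaf_label_rejected(self):
        tree = parse_newick("(A:1,B:1):0;")
        prof = gl.PhyleticProfile("t", {"A": 1, "X": 0})
        with pytest.raises(ValueError, match="non-leaf"):
            gl.pruning_loglik(tree, prof, gl.GainLossModel.single(1, 1))


class TestPosteriors:
    def test_observed_leaves_are_clamped(self, small_tree):
        rng = np.random.default_rng(2)
        prof = random_profile(small_tree, rng)
        post = gl.node_posteriors(small_tree, prof, gl.GainLossModel.single(0.7, 0.9))
        for leaf, obs in prof.states.items():
            if obs is not None:
                assert post[leaf] == pytest.approx(float(obs))

    def test_symmetric_star_is_ambivalent(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1):0;")
        prof = gl.PhyleticProfile("t", {"A": 1, "B": 1, "C": 0, "D": 0})
        post = gl.node_posteriors(tree, prof, gl.GainLossModel.single(1.0, 1.0))
        assert post[tree.root] == pytest.approx(0.5, abs=1e-12)

    def test_matches_enumeration_oracle(self, small_tree):
        rng = np.random.default_rng(23)
        for rep in range(4):
            g, l = rng.uniform(0.1, 3, 2)
            prof = random_profile(small_tree, rng, f"t{rep}")
            post = gl.node_posteriors(small_tree, prof, gl.GainLossModel.single(g, l))
            expected = enum_posteriors(small_tree, prof, g, l)
            for node, val in expected.items():
                assert post[node] == pytest.approx(val, abs=1e-8), node

    def test_posterior_calibration_on_simulated_traits(self):
        # among internal nodes with posterior near 0.7 the true state
        # should be present about 70% of the time
        tree = simulate_tree(16, seed=7)
        g, l = 0.5, 1.0
        profs, states_all = [], []
        for i in range(2000):
            p, s = simulate_trait(tree, g, l, seed=20000 + i, trait_id=f"c{i}")
            profs.append(p)
            states_all.append(s)
        X, _, _ = gl.profiles_to_matrix(profs, tree)
        post, order = gl.posteriors_matrix(tree, X, gl.GainLossModel.single(g, l))
        internal = [j for j, n in enumerate(order) if tree.nodes[n].children]
        hits = []
        for k in range(len(profs)):
            for j in internal:
                if 0.65 <= post[k, j] <= 0.75:
                    hits.append(states_all[k][order[j]])
        assert len(hits) > 100
        assert abs(np.mean(hits) - 0.7) <= 0.1


class TestMLStates:
    def test_threshold_and_tie_break(self):
        post = gl.PosteriorProfile("t", {"a": 0.51, "b": 0.5, "c": 1.0, "d": 0.49})
        states = gl.marginal_ml_states(post)
        assert states == {"a": 1, "b": 0, "c": 1, "d": 0}


class TestFitRates:
    def test_recovers_simulation_rates(self):
        tree = simulate_tree(32, seed=42)
        profs = [
            simulate_trait(tree, 0.5, 1.0, seed=1000 + i, trait_id=f"t{i}")[0]
            for i in range(500)
        ]
        model = gl.fit_rates(tree, profs)
        (g, l, _w), = model.categories
        assert abs(g - 0.5) / 0.5 < 0.2
        assert abs(l - 1.0) / 1.0 < 0.2
        assert model.loglik is not None and math.isfinite(model.loglik)

    def test_symmetric_profiles_give_symmetric_rates(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        profs = [
            gl.PhyleticProfile("p", {"A": 1, "B": 1, "C": 0, "D": 0}),
            gl.PhyleticProfile("q", {"A": 0, "B": 0, "C": 1, "D": 1}),
        ]
        model = gl.fit_rates(tree, profs)
        (g, l, _w), = model.categories
        assert g == pytest.approx(l, rel=1e-3)

    def test_all_absent_drives_gain_to_lower_bound(self, caplog):
        tree = parse_newick("((A:1,B:1):1,C:1):0;")
        prof = gl.PhyleticProfile("t", {"A": 0, "B": 0, "C": 0})
        with caplog.at_level("WARNING", logger="srnaevo.gainloss"):
            model = gl.fit_rates(tree, [prof])
        (g, _l, _w), = model.categories
        assert g == pytest.approx(gl.RATE_BOUNDS[0])
        assert any("bound" in r.message for r in caplog.records)
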