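"""Fitch origin counting and Mk likelihood machinery.

Randomized checks compare the dynamic programs against enumeration oracles
(every internal-state assignment); one pinned value cross-checks the Mk1
pruning likelihood against an independent reference implementation
(phytools::fitMk in R, flat root prior).
"""

import math

import numpy as np
import pytest

from mitokaryo.phylo import (
    MkModel,
    TreeError,
    fit_rates,
    fitch_origins,
    marginal_asr,
    mk1,
    mk_loglik,
    origin_tally,
    parse_newick,
    write_newick,
)
from mitokaryo.simulate import random_bifurcating_tree, simulate_binary_character
from conftest import enum_fitch, enum_marginals, enum_mk_loglik


def _random_states(tree, rng):
    return {l.taxon.label: int(rng.integers(2)) for l in tree.leaf_node_iter()}


class TestNewick:
    def test_four_tip_tree_unit_lengths(self):
        tree = parse_newick("((A,B),(C,D));")
        assert len(tree.leaf_nodes()) == 4
        assert all(
            n.edge.length == 1.0
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node
        )

    def test_round_trip(self):
        text = "((Lsp1:0.06,Lsp3:0.05):0.09,(Lsp2:0.08,Ltinnunculi:0.1):0.07);"
        tree = parse_newick(text)
        again = parse_newick(write_newick(tree))
        assert {l.taxon.label for l in again.leaf_node_iter()} == {
            "Lsp1", "Lsp3", "Lsp2", "Ltinnunculi",
        }

    def test_malformed_raises(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B);")

    def test_duplicate_tips_raise(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A,B),(A,C));")

    def test_polytomy_accepted(self):
        tree = parse_newick("(A,B,C,(D,E));")
        assert len(tree.leaf_nodes()) == 5


class TestFitch:
    def test_laemobothriidae_single_origin(self):
        tree = parse_newick("((Lsp1,Lsp3),(Lsp2,Ltinnunculi));")
        states = {"Lsp1": 0, "Lsp3": 0, "Lsp2": 0, "Ltinnunculi": 1}
        res = fitch_origins(tree, states)
        assert res.min_gains == 1
        assert res.gain_range == (1, 1)

    def test_all_single_state_zero_gains(self):
        tree = parse_newick("((A,B),(C,D));")
        res = fitch_origins(tree, {t: 0 for t in "ABCD"})
        assert res.min_changes == 0 and res.min_gains == 0

    def test_missing_tip_state_raises(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError, match="without a character state"):
            fitch_origins(tree, {"A": 0, "B": 1, "C": 0})

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_bifurcating_tree(8, seed=seed)
        states = _random_states(tree, rng)
        root_state = [0, 1, None][seed % 3]
        got = fitch_origins(tree, states, root_state)
        changes, lo, hi = enum_fitch(tree, states, root_state)
        assert (got.min_changes, got.min_gains, got.max_gains) == (changes, lo, hi)

    def test_gain_count_bounded_by_true_events(self):
        # irreversible gains: parsimony can merge but never exceed them
        model = MkModel("AsymmMk", 0.4, 0.0)
        for seed in range(20):
            tree = random_bifurcating_tree(12, seed=300 + seed)
            from mitokaryo.simulate import simulate_binary_character_history

            states, _, true_gains = simulate_binary_character_history(
                tree, model, root_state=0, seed=seed
            )
            assert fitch_origins(tree, states).min_gains <= true_gains


class TestOriginTally:
    def test_study_tally(self):
        tally = origin_tally(
            [("mammal lice", 1), ("amblyceran lice", 4), ("ischnoceran lice", 9)]
        )
        assert tally["total"] == 14

    def test_empty_is_zero(self):
        assert origin_tally([])["total"] == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            origin_tally([("x", -1)])


class TestMkLikelihood:
    def test_two_tip_closed_form(self):
        # states differing across a path of total length t under rate q:
        # P(0->1, t) = (1 - exp(-2qt)) / 2, averaged over the uniform prior
        # a zero-length sister branch pins the root state to B's state, so
        # the likelihood is prior(1) * P(1 -> 0 over t)
        q, t = 0.7, 1.3
        tree = parse_newick(f"(A:{t},B:0.0);")
        ll = mk_loglik(tree, {"A": 0, "B": 1}, mk1(q))
        p10 = (1 - math.exp(-2 * q * t)) / 2
        assert ll == pytest.approx(math.log(0.5 * p10), abs=1e-12)

    def test_matches_phytools_reference_value(self):
        # logLik from phytools::fitMk (model="ER", fixedQ with rate 0.7,
        # pi=c(0.5, 0.5)) on the same tree and data: -3.243090143852
        tree = parse_newick("((A:0.3,B:0.7):0.4,(C:0.2,D:0.9):0.6);")
        ll = mk_loglik(tree, {"A": 0, "B": 1, "C": 0, "D": 1}, mk1(0.7))
        assert ll == pytest.approx(-3.243090143852, abs=1e-9)

    def test_zero_rate_with_both_states_is_minus_inf(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ll = mk_loglik(tree, {"A": 0, "B": 1, "C": 0, "D": 0}, mk1(0.0))
        assert ll == -math.inf

    @pytest.mark.parametrize("seed", range(40))
    def test_pruning_matches_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = random_bifurcating_tree(int(rng.integers(2, 7)), seed=seed)
        states = _random_states(tree, rng)
        model = MkModel(
            "AsymmMk", float(rng.uniform(0.01, 3)), float(rng.uniform(0.01, 3))
        )
        assert mk_loglik(tree, states, model) == pytest.approx(
            enum_mk_loglik(tree, states, model), abs=1e-10
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mk1(-0.1)


class TestFitRates:
    def test_constant_data_fits_lower_bound(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        model, _ = fit_rates(tree, {t: 0 for t in "ABCD"}, "Mk1")
        assert model.q01 <= 1e-6

    def test_asymm_nests_mk1(self):
        for seed in range(5):
            tree = random_bifurcating_tree(16, seed=seed)
            states = simulate_binary_character(tree, mk1(0.5), seed=seed)
            if len(set(states.values())) < 2:
                continue
            _, ll1 = fit_rates(tree, states, "Mk1")
            _, ll2 = fit_rates(tree, states, "AsymmMk")
            assert ll2 >= ll1 - 1e-7

    def test_recovery_smoke(self):
        # the full 200-replicate recovery experiment runs in the acceptance
        # suite; here a small median sanity check
        fits = []
        for seed in range(12):
            tree = random_bifurcating_tree(64, seed=40 + seed)
            states = simulate_binary_character(tree, mk1(0.5), seed=seed)
            model, _ = fit_rates(tree, states, "Mk1")
            fits.append(model.q01)
        assert 0.25 < float(np.median(fits)) < 1.0


class TestMarginalAsr:
    def test_symmetric_two_tip_root_is_half(self):
        tree = parse_newick("(A:1.0,B:1.0);")
        res = marginal_asr(tree, {"A": 0, "B": 1}, mk1(0.3))
        assert res.root_p_fragmented == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(2000 + seed)
        tree = random_bifurcating_tree(int(rng.integers(3, 7)), seed=seed)
        states = _random_states(tree, rng)
        model = MkModel(
            "AsymmMk", float(rng.uniform(0.05, 2)), float(rng.uniform(0.05, 2))
        )
        res = marginal_asr(tree, states, model)
        expected = enum_marginals(tree, states, model)
        for node_id, clade in res.clades.items():
            if len(clade) < 2 and node_id in states:
                continue
            if clade in expected:
                assert res.probs[node_id][1] == pytest.approx(
                    expected[clade][1], abs=1e-9
                )

    @pytest.mark.parametrize("seed", range(10))
    def test_probabilities_sum_to_one(self, seed):
        tree = random_bifurcating_tree(10, seed=seed)
        rng = np.random.default_rng(seed)
        states = _random_states(tree, rng)
        res = marginal_asr(tree, states, mk1(0.4))
        for p0, p1 in res.probs.values():
            assert p0 + p1 == pytest.approx(1.0, abs=1e-9)

    def test_near_zero_rate_all_single(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = marginal_asr(tree, {t: 0 for t in "ABCD"}, mk1(1e-9))
        for node_id, (p0, _) in res.probs.items():
            assert p0 == pytest.approx(1.0, abs=1e-6)
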