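"""Mk1 likelihood, rate estimation and marginal ancestral states."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import enumerate_mk
from oakniche.mk import (
    MISSING,
    CharacterColumn,
    MkModel,
    asr_two_trees,
    marginal_asr,
    match_nodes,
    mk_transition,
    ml_rate,
    prune_loglik,
)
from oakniche.grafting import FossilSpec, graft_all
from oakniche.simulate import sim_dated_tree, sim_mk_characters
from oakniche.trees import parse_tree


class TestTransition:
    def test_zero_time_is_identity(self):
        np.testing.assert_allclose(mk_transition(1.0, 0.0, 4), np.eye(4))

    def test_stationary_limit_is_uniform(self):
        p = mk_transition(5.0, 1e6, 3)
        np.testing.assert_allclose(p, np.full((3, 3), 1 / 3), atol=1e-12)

    def test_known_binary_values(self):
        p = mk_transition(1.0, 0.5, 2)
        assert p[0, 0] == pytest.approx(0.6839397, abs=1e-7)
        assert p[0, 1] == pytest.approx(0.3160603, abs=1e-7)

    @pytest.mark.parametrize("k", [2, 3, 5])
    @pytest.mark.parametrize("q", [0.01, 0.5, 2.0])
    @pytest.mark.parametrize("t", [0.0, 0.3, 5.0])
    def test_matches_matrix_exponential(self, k, q, t):
        rate = np.full((k, k), q)
        np.fill_diagonal(rate, -(k - 1) * q)
        np.testing.assert_allclose(mk_transition(q, t, k), expm(rate * t), atol=1e-10)

    def test_rows_sum_to_one(self):
        p = mk_transition(0.7, 2.3, 5)
        np.testing.assert_allclose(p.sum(axis=1), np.ones(5), atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mk_transition(1.0, -0.1, 2)


class TestPruning:
    def test_identical_tips_small_rate_limit(self, cherry_tree):
        model = MkModel(k=2, q=1e-9)
        char = CharacterColumn({"A": 0, "B": 0}, k=2)
        assert np.exp(prune_loglik(cherry_tree, char, model)) == pytest.approx(0.5, abs=1e-6)

    def test_split_tips_small_rate_limit(self, cherry_tree):
        model = MkModel(k=2, q=1e-9)
        char = CharacterColumn({"A": 0, "B": 1}, k=2)
        assert np.exp(prune_loglik(cherry_tree, char, model)) == pytest.approx(0.0, abs=1e-6)

    def test_cherry_closed_form(self, cherry_tree):
        model = MkModel(k=2, q=1.0)
        char = CharacterColumn({"A": 0, "B": 0}, k=2)
        expected = 0.5 * (0.6839397**2 + 0.3160603**2)
        assert np.exp(prune_loglik(cherry_tree, char, model)) == pytest.approx(expected, abs=1e-7)

    def test_out_of_range_state_rejected(self, cherry_tree):
        with pytest.raises(ValueError):
            CharacterColumn({"A": 0, "B": 2}, k=2)

    def test_missing_tip_contributes_all_ones(self, three_tip_tree):
        model = MkModel(k=3, q=0.4)
        full = CharacterColumn({"A": 1, "B": 1, "C": MISSING}, k=3)
        # summing the likelihood over all C states equals treating C missing
        total = sum(
            np.exp(prune_loglik(three_tip_tree, CharacterColumn({"A": 1, "B": 1, "C": s}, k=3), model))
            for s in range(3)
        )
        assert np.exp(prune_loglik(three_tip_tree, full, model)) == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = sim_dated_tree(int(rng.integers(3, 7)), seed=seed)
        k = int(rng.choice([2, 3, 5]))
        q = float(rng.uniform(0.05, 2.0))
        tips = {tree.label[t]: int(rng.integers(k)) for t in tree.tips()}
        total, _ = enumerate_mk(tree, tips, k, q)
        ll = prune_loglik(tree, CharacterColumn(tips, k=k), MkModel(k=k, q=q))
        assert ll == pytest.approx(np.log(total), rel=1e-9)

    def test_polytomy_handled_exactly(self):
        tree = parse_tree("(A:1,B:1,C:1,D:1);")
        k, q = 3, 0.6
        tips = {"A": 0, "B": 1, "C": 1, "D": 2}
        total, _ = enumerate_mk(tree, tips, k, q)
        ll = prune_loglik(tree, CharacterColumn(tips, k=k), MkModel(k=k, q=q))
        assert ll == pytest.approx(np.log(total), rel=1e-12)

    def test_state_label_permutation_invariance(self):
        tree = sim_dated_tree(6, seed=3)
        k, q = 3, 0.5
        rng = np.random.default_rng(0)
        tips = {tree.label[t]: int(rng.integers(k)) for t in tree.tips()}
        base = prune_loglik(tree, CharacterColumn(tips, k=k), MkModel(k=k, q=q))
        for perm in itertools.permutations(range(k)):
            permuted = {lab: perm[s] for lab, s in tips.items()}
            ll = prune_loglik(tree, CharacterColumn(permuted, k=k), MkModel(k=k, q=q))
            assert ll == pytest.approx(base, rel=1e-12)


class TestMarginalAsr:
    def test_symmetric_cherry_is_fifty_fifty(self, cherry_tree):
        res = marginal_asr(cherry_tree, CharacterColumn({"A": 0, "B": 1}, k=2), MkModel(k=2, q=1.0))
        np.testing.assert_allclose(res.node_probs[cherry_tree.root], [0.5, 0.5], atol=1e-12)

    def test_small_rate_limit_pins_shared_state(self, three_tip_tree):
        res = marginal_asr(
            three_tip_tree,
            CharacterColumn({"A": 2, "B": 2, "C": 2}, k=4),
            MkModel(k=4, q=1e-8),
        )
        for probs in res.node_probs.values():
            assert probs[2] > 0.9999

    def test_large_rate_limit_is_uniform(self, three_tip_tree):
        res = marginal_asr(
            three_tip_tree,
            CharacterColumn({"A": 0, "B": 1, "C": 2}, k=3),
            MkModel(k=3, q=1e4),
        )
        for probs in res.node_probs.values():
            np.testing.assert_allclose(probs, np.full(3, 1 / 3), atol=1e-6)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = sim_dated_tree(5, seed=seed)
        k = int(rng.choice([2, 3, 5]))
        q = float(rng.uniform(0.05, 2.0))
        tips = {tree.label[t]: int(rng.integers(k)) for t in tree.tips()}
        _, marg = enumerate_mk(tree, tips, k, q)
        res = marginal_asr(tree, CharacterColumn(tips, k=k), MkModel(k=k, q=q))
        for node, expected in marg.items():
            np.testing.assert_allclose(res.node_probs[node], expected, atol=1e-9)
            assert res.node_probs[node].sum() == pytest.approx(1.0, abs=1e-9)

    def test_conditional_mode_differs_but_normalizes(self, three_tip_tree):
        char = CharacterColumn({"A": 0, "B": 1, "C": 0}, k=2)
        model = MkModel(k=2, q=0.3)
        cond = marginal_asr(three_tip_tree, char, model, method="conditional")
        for probs in cond.node_probs.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestMlRate:
    def test_invariant_characters_pin_lower_bound(self):
        tree = sim_dated_tree(8, seed=1)
        chars = [CharacterColumn({lab: 0 for lab in tree.tip_labels()}, k=3)]
        q_hat, _, at_boundary = ml_rate(tree, chars, k=3)
        assert at_boundary
        assert q_hat < 1e-6

    def test_matches_grid_search_oracle(self):
        tree = sim_dated_tree(8, seed=2)
        # a clean single-clade split has an interior rate optimum
        clade_node = max(
            (n for n in tree.internal_nodes() if n != tree.root),
            key=lambda n: len(tree.clade_tips(n)),
        )
        clade = tree.clade_tips(clade_node)
        chars = [
            CharacterColumn({lab: int(lab in clade) for lab in tree.tip_labels()}, k=2)
        ]
        q_hat, ll_hat, at_boundary = ml_rate(tree, chars, k=2)
        assert not at_boundary
        grid = np.logspace(-6, 2, 10_000)
        lls = [prune_loglik(tree, chars[0], MkModel(k=2, q=float(g))) for g in grid]
        q_grid = float(grid[int(np.argmax(lls))])
        assert q_hat == pytest.approx(q_grid, rel=5e-3)
        assert ll_hat >= max(lls) - 1e-9

    def test_simulation_recovery_single_replicate(self):
        tree = sim_dated_tree(32, seed=5)
        chars = sim_mk_characters(tree, k=5, q=0.1, n_chars=1000, seed=7)
        q_hat, _, _ = ml_rate(tree, chars, k=5)
        assert q_hat == pytest.approx(0.1, rel=0.1)


class TestTwoTrees:
    def test_zero_fossils_identical_results(self):
        tree = sim_dated_tree(6, seed=9)
        rng = np.random.default_rng(0)
        tips = {lab: int(rng.integers(3)) for lab in tree.tip_labels()}
        ext, gra = asr_two_trees(tree, tree, tips, {}, k=3, q=0.2)
        for node in ext.node_probs:
            np.testing.assert_allclose(ext.node_probs[node], gra.node_probs[node])

    def test_missing_fossil_state_is_named(self):
        tree = parse_tree("((A:10,B:10):5,C:15);")
        grafted = graft_all(tree, [FossilSpec("Fx", frozenset({"A", "B"}), 12, 8, state=1)])
        with pytest.raises(ValueError, match="Fx"):
            asr_two_trees(tree, grafted, {"A": 0, "B": 0, "C": 1}, {}, k=2, q=0.1)

    def test_stem_fossil_pulls_marginal_toward_its_state(self):
        tree = parse_tree("((A:2,B:2):20,(C:11,D:11):11);")
        tips = {"A": 0, "B": 0, "C": 0, "D": 0}
        fossils = [FossilSpec("F", frozenset({"A", "B"}), 15.0, 14.0, state=1)]
        grafted = graft_all(tree, fossils)
        ext, gra = asr_two_trees(tree, grafted, tips, {"F": 1}, k=2, q=0.05)
        mapping = match_nodes(ext, gra, frozenset(tree.tip_labels()))
        node_ab = tree.mrca({"A", "B"})
        assert gra.node_probs[mapping[node_ab]][1] > ext.node_probs[node_ab][1]

    def test_fossil_informed_flips_mediterranean_stem(self):
        from oakniche.simulate import suber_like_scenario

        tree, fossils, tips = suber_like_scenario()
        grafted = graft_all(tree, fossils)
        ext, gra = asr_two_trees(
            tree, grafted, tips, {f.label: f.state for f in fossils}, k=5
        )
        mapping = match_nodes(ext, gra, frozenset(tree.tip_labels()))
        stem = tree.mrca({"S1", "S2"})
        assert int(ext.node_probs[stem].argmax()) == 4
        assert int(gra.node_probs[mapping[stem]].argmax()) == 2
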