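"""Hamming distances and the neighbour-net circular split system."""

import numpy as np
import pytest

from conftest import normalize_split, tree_path_distances
from oakniche.nnet import (
    SplitSystem,
    TraitMatrix,
    circular_order,
    hamming,
    neighbor_net,
    read_trait_matrix,
    split_distances,
    write_splits_nexus,
    write_trait_matrix,
)
from oakniche.simulate import cerris_like_leaf_matrix, sim_dated_tree


class TestHamming:
    def test_identical_and_opposite_rows(self):
        m = TraitMatrix(
            taxa=["a", "b", "c"],
            data=[[0, 1, 0], [0, 1, 0], [1, 0, 1]],
            arity=[2, 2, 2],
        )
        d = hamming(m)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_missing_data_normalized_by_shared_characters(self):
        m = TraitMatrix(
            taxa=["a", "b", "c"],
            data=[[0, 1, -1, 2], [0, 0, 1, 2], [1, 1, 1, 0]],
            arity=[2, 2, 2, 3],
        )
        d = hamming(m)
        assert d[0, 1] == pytest.approx(1 / 3)  # 3 shared, 1 differing

    def test_ternary_mismatch_counts_one(self):
        m = TraitMatrix(taxa=["a", "b", "c"], data=[[0], [2], [1]], arity=[3])
        d = hamming(m)
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0

    def test_no_shared_characters_names_the_pair(self):
        m = TraitMatrix(
            taxa=["a", "b", "c"],
            data=[[0, -1], [-1, 1], [0, 1]],
            arity=[2, 2],
        )
        with pytest.raises(ValueError, match="'a' and 'b'"):
            hamming(m)

    def test_preset_leaf_matrix_is_valid_and_symmetric(self):
        m = cerris_like_leaf_matrix()
        assert m.data.shape == (15, 12)
        assert list(m.arity) == [2] * 11 + [3]
        d = hamming(m)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNeighborNet:
    def test_three_taxon_star_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        system = neighbor_net(d, ["A", "B", "C"])
        w = {tuple(sorted(k)): v for k, v in system.weights.items()}
        assert w[("B",)] == pytest.approx(1.5)
        assert w[("C",)] == pytest.approx(2.5)
        # the trivial split of A is stored as its complement arc {B, C}
        assert w[("B", "C")] == pytest.approx(0.5)

    def test_additive_tree_splits_and_weights(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> 4 trivial splits + AB|CD at weight 1
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        system = neighbor_net(d, taxa)
        w = {normalize_split(k, taxa): v for k, v in system.weights.items()}
        assert w[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert w[frozenset({"B"})] == pytest.approx(2.0)
        assert w[frozenset({"C"})] == pytest.approx(3.0)
        assert w[frozenset({"D"})] == pytest.approx(4.0)

    def test_zero_distances_give_no_splits(self):
        system = neighbor_net(np.zeros((4, 4)), list("ABCD"))
        assert system.weights == {}

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_net(d, list("ABC"))

    def test_negative_entries_rejected(self):
        d = np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="non-negative"):
            neighbor_net(d, list("ABC"))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_metrics_round_trip_and_contain_tree_splits(self, seed):
        rng = np.random.default_rng(seed)
        tree = sim_dated_tree(int(rng.integers(4, 9)), seed=seed)
        labs, d = tree_path_distances(tree)
        system = neighbor_net(d, labs)
        recovered = {normalize_split(k, labs) for k in system.weights}
        tree_splits = {
            normalize_split(tree.clade_tips(n), labs)
            for n in tree.nodes()
            if n != tree.root
        }
        assert tree_splits <= recovered
        taxa, dd = split_distances(system)
        perm = [taxa.index(t) for t in labs]
        assert np.abs(dd[np.ix_(perm, perm)] - d).max() < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_circular_metrics_weight_recovery(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(5, 9))
        taxa = [f"t{i}" for i in range(n)]
        order = list(rng.permutation(taxa))
        weights = {}
        for i in range(1, n):
            for j in range(i + 1, n + 1):
                if rng.random() < 0.5:
                    weights[frozenset(order[i:j])] = float(rng.uniform(0.1, 2.0))
        if not weights:
            weights[frozenset(order[1:2])] = 1.0
        truth = SplitSystem(cycle=order, weights=weights)
        tx, dm = split_distances(truth)
        perm = [tx.index(t) for t in taxa]
        dmat = dm[np.ix_(perm, perm)]
        rec = neighbor_net(dmat, taxa)
        rec_norm = {normalize_split(k, taxa): v for k, v in rec.weights.items()}
        for k, v in weights.items():
            assert rec_norm.get(normalize_split(k, taxa), 0.0) == pytest.approx(v, abs=1e-6)

    def test_relabeling_invariance_up_to_rotation(self):
        tree = sim_dated_tree(6, seed=42)
        labs, d = tree_path_distances(tree)
        sys1 = neighbor_net(d, labs)
        mapping = {lab: f"z_{lab}" for lab in labs}
        sys2 = neighbor_net(d, [mapping[l] for l in labs])
        w1 = {frozenset(mapping[t] for t in normalize_split(k, labs)): round(v, 9)
              for k, v in sys1.weights.items()}
        w2 = {normalize_split(k, list(mapping.values())): round(v, 9)
              for k, v in sys2.weights.items()}
        # same bipartitions and weights under the renaming
        assert {frozenset(s) for s in w1} == {frozenset(s) for s in w2}


class TestSplitDistances:
    def test_single_split_metric(self):
        system = SplitSystem(cycle=["A", "B", "C", "D"], weights={frozenset({"C", "D"}): 1.0})
        taxa, d = split_distances(system)
        i = {t: k for k, t in enumerate(taxa)}
        assert d[i["A"], i["C"]] == 1.0
        assert d[i["A"], i["B"]] == 0.0
        assert d[i["C"], i["D"]] == 0.0

    def test_non_arc_split_rejected(self):
        with pytest.raises(ValueError, match="arc"):
            SplitSystem(cycle=["A", "B", "C", "D"], weights={frozenset({"B", "D"}): 1.0})


class TestIO:
    def test_trait_matrix_round_trip(self):
        m = cerris_like_leaf_matrix()
        back = read_trait_matrix(write_trait_matrix(m))
        assert back.taxa == m.taxa
        assert (back.data == m.data).all()

    def test_splits_nexus_contains_cycle_and_weights(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        text = write_splits_nexus(neighbor_net(d, ["A", "B", "C"]))
        assert "BEGIN ST_SPLITS" in text and "CYCLE" in text
        assert "NSPLITS=3" in text
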