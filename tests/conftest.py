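"""Shared fixtures and independent oracle helpers for the test suite."""

import itertools

import numpy as np
import pytest

from oakniche.mk import mk_transition
from oakniche.trees import DatedTree, parse_tree


@pytest.fixture
def three_tip_tree() -> DatedTree:
    return parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_tree() -> DatedTree:
    return parse_tree("(A:0.5,B:0.5);")


def enumerate_mk(tree: DatedTree, tip_states, k: float, q: float):
    """Brute-force Mk oracle: total likelihood and per-internal-node joint
    marginals by explicit summation over every interior state assignment.

    Independent of the pruning implementation: uses only the transition
    matrix closed form and direct products over edges.
    """
    internals = tree.internal_nodes()
    tips = tree.tips()
    n_int = len(internals)
    assigns = np.array(list(itertools.product(range(k), repeat=n_int)), dtype=int)
    m = assigns.shape[0]
    state = {}
    for j, nd in enumerate(internals):
        state[nd] = assigns[:, j]
    for t in tips:
        s = tip_states[tree.label[t]]
        state[t] = np.full(m, s, dtype=int)
    prob = np.full(m, 1.0 / k)
    for child, par in tree.parent.items():
        P = mk_transition(q, tree.edge_length[child], k)
        prob = prob * P[state[par], state[child]]
    total = prob.sum()
    marginals = {}
    for nd in internals:
        marg = np.zeros(k)
        np.add.at(marg, state[nd], prob)
        marginals[nd] = marg / total if total > 0 else marg
    return total, marginals


def tree_path_distances(tree: DatedTree):
    """Tip-to-tip path-length matrix computed from ancestor paths (oracle)."""
    tips = tree.tips()
    labs = [tree.label[t] for t in tips]
    depth = {nd: tree.age[tree.root] - tree.age[nd] for nd in tree.nodes()}
    anc = {t: [t] + tree.ancestors(t) for t in tips}
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = set(anc[tips[i]]) & set(anc[tips[j]])
            mrca = max(common, key=lambda nd: depth[nd])
            d[i, j] = d[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * depth[mrca]
    return labs, d


def normalize_split(side, all_taxa):
    """Canonical representative of a bipartition (the lexicographically
    smaller side), for comparing split systems across storage conventions."""
    side = frozenset(side)
    comp = frozenset(all_taxa) - side
    return min(side, comp, key=lambda s: (len(s), sorted(s)))
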