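"""Equal-rates k-state Markov (Mk1) likelihood and ancestral-state reconstruction.

The Mk1 model is a continuous-time Markov chain on ``k`` unordered states
with one symmetric rate ``q`` for every off-diagonal transition.  Its
transition probabilities have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k q t)
    P_ij(t) = 1/k -   1/k   * exp(-k q t)        (i != j)

Likelihoods are computed by Felsenstein's pruning algorithm with per-node
rescaling (so 70+ tip trees at small rates do not underflow); marginal
ancestral states ("proportional likelihoods", the pie charts at internal
nodes) come from the standard up-down pass under the root prior, which
defaults to the Mk stationary distribution 1/k.  Polytomies are handled
exactly — a node simply multiplies the messages of all its children.

The same engine serves a 5-state climate-niche character and binary/ternary
leaf-trait characters, on trees with or without grafted fossil tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import DatedTree

__all__ = [
    "MkModel",
    "CharacterColumn",
    "AsrResult",
    "mk_transition",
    "prune_loglik",
    "ml_rate",
    "marginal_asr",
    "asr_two_trees",
    "MISSING",
]

MISSING = -1
Q_MIN = 1e-8


@dataclass
class MkModel:
    """Mk1 model frame: state count ``k``, rate ``q`` (changes/Ma per
    off-diagonal entry) and root prior (default uniform = stationary)."""

    k: int
    q: float
    root_prior: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.q <= 0:
            raise ValueError("q must be > 0")
        if self.root_prior is None:
            self.root_prior = np.full(self.k, 1.0 / self.k)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (self.k,) or abs(self.root_prior.sum() - 1) > 1e-9:
                raise ValueError("root prior must be length k and sum to 1")


@dataclass
class CharacterColumn:
    """One categorical character: tip label -> state index, with MISSING allowed."""

    states: Dict[str, int]
    k: int

    def __post_init__(self):
        observed = [s for s in self.states.values() if s != MISSING]
        if not observed:
            raise ValueError("character has no non-missing observation")
        bad = [s for s in observed if not (0 <= s < self.k)]
        if bad:
            raise ValueError(f"state index {bad[0]} out of range for k={self.k}")


@dataclass
class AsrResult:
    """Marginal state probabilities per internal node plus fit metadata."""

    node_probs: Dict[int, np.ndarray]
    fingerprint: Dict[int, FrozenSet[str]]
    loglik: float
    q: float
    q_estimated: bool = False
    q_at_boundary: bool = False


def mk_transition(q: float, t: float, k: int) -> np.ndarray:
    """Closed-form Mk1 transition matrix over a branch of length ``t``."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if q <= 0:
        raise ValueError("q must be > 0")
    e = np.exp(-k * q * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
    return p


# ----------------------------------------------------------- pruning machinery

def _tip_partials(
    tree: DatedTree, chars: Sequence[CharacterColumn], k: int
) -> Dict[int, np.ndarray]:
    """(n_chars, k) partial-likelihood array per tip; missing tips get all-ones.

    Tree tips absent from a character's map are treated as MISSING (e.g.
    fossil tips unscorable for a leaf trait).
    """
    n = len(chars)
    out: Dict[int, np.ndarray] = {}
    for tip in tree.tips():
        lab = tree.label[tip]
        arr = np.ones((n, k))
        for j, ch in enumerate(chars):
            s = ch.states.get(lab, MISSING)
            if s != MISSING:
                arr[j, :] = 0.0
                arr[j, s] = 1.0
        out[tip] = arr
    return out


def _up_pass(
    tree: DatedTree, tip_partials: Dict[int, np.ndarray], q: float, k: int
) -> Tuple[Dict[int, np.ndarray], np.ndarray, Dict[int, np.ndarray]]:
    """Felsenstein pruning with per-node rescaling.

    Returns (partials U_v, accumulated log-scale per character, transition
    matrices keyed by child node).  ``U_v[j, s]`` is proportional to
    P(data below v | state s) for character j, with the proportionality
    constants absorbed into the log-scale accumulator.
    """
    n_chars = next(iter(tip_partials.values())).shape[0]
    partials: Dict[int, np.ndarray] = {}
    pmats: Dict[int, np.ndarray] = {}
    logscale = np.zeros(n_chars)
    for node in tree.postorder():
        kids = tree.children.get(node, [])
        if not kids:
            partials[node] = tip_partials[node]
            continue
        acc = np.ones((n_chars, k))
        for c in kids:
            pmat = mk_transition(q, tree.edge_length[c], k)
            pmats[c] = pmat
            acc = acc * (partials[c] @ pmat.T)
        scale = acc.max(axis=1)
        scale[scale == 0.0] = 1.0  # impossible data: keep zeros, logL -> -inf
        acc = acc / scale[:, None]
        logscale += np.log(scale)
        partials[node] = acc
    return partials, logscale, pmats


def _loglik_from_up(
    tree: DatedTree,
    partials: Dict[int, np.ndarray],
    logscale: np.ndarray,
    prior: np.ndarray,
) -> np.ndarray:
    """Per-character log-likelihood from the root partials."""
    root_lik = partials[tree.root] @ prior
    with np.errstate(divide="ignore"):
        return np.log(root_lik) + logscale


def prune_loglik(
    tree: DatedTree, char: CharacterColumn, model: MkModel
) -> float:
    """Tree log-likelihood of one character under Mk1 (pruning algorithm)."""
    tp = _tip_partials(tree, [char], model.k)
    partials, logscale, _ = _up_pass(tree, tp, model.q, model.k)
    return float(_loglik_from_up(tree, partials, logscale, model.root_prior)[0])


def _total_loglik(
    tree: DatedTree, chars: Sequence[CharacterColumn], q: float, k: int,
    prior: np.ndarray,
) -> float:
    tp = _tip_partials(tree, chars, k)
    partials, logscale, _ = _up_pass(tree, tp, q, k)
    return float(_loglik_from_up(tree, partials, logscale, prior).sum())


def ml_rate(
    tree: DatedTree,
    chars: Sequence[CharacterColumn],
    k: int,
    q_max: float = 100.0,
    root_prior: Optional[np.ndarray] = None,
    rel_tol: float = 1e-8,
) -> Tuple[float, float, bool]:
    """Maximum-likelihood single rate shared by all characters.

    1-D bounded maximization of the summed log-likelihood over
    ``[Q_MIN, q_max]`` carried out on log10(q) (the likelihood surface is
    much better conditioned on a log scale).  Returns
    ``(q_hat, loglik, at_boundary)``; a boundary hit — e.g. every character
    invariant, driving q to the lower bound — is flagged rather than raised.
    """
    if not chars:
        raise ValueError("need at least one character")
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)

    def neg(u: float) -> float:
        return -_total_loglik(tree, chars, 10.0 ** u, k, prior)

    lo, hi = np.log10(Q_MIN), np.log10(q_max)
    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded",
        options={"xatol": rel_tol, "maxiter": 500},
    )
    q_hat = float(10.0 ** res.x)
    # bounded Brent stops short of the bracket ends; treat anything within
    # a millidecade of either bound as a boundary hit
    at_boundary = (res.x - lo) < 1e-3 or (hi - res.x) < 1e-3
    return q_hat, float(-res.fun), at_boundary


def marginal_asr(
    tree: DatedTree,
    char: CharacterColumn,
    model: MkModel,
    method: str = "marginal",
) -> AsrResult:
    """Marginal ancestral-state probabilities at every internal node.

    ``method="marginal"`` (default) gives P(state at node | all tip data, q)
    via the up-down pass; ``method="conditional"`` renormalizes the upward
    conditional likelihoods only (the other reading of Mesquite's
    "proportional likelihoods").
    """
    if method not in ("marginal", "conditional"):
        raise ValueError(f"unknown method {method!r}")
    k = model.k
    tp = _tip_partials(tree, [char], k)
    partials, logscale, pmats = _up_pass(tree, tp, model.q, k)
    loglik = float(_loglik_from_up(tree, partials, logscale, model.root_prior)[0])

    node_probs: Dict[int, np.ndarray] = {}
    if method == "conditional":
        for node in tree.internal_nodes():
            v = partials[node][0]
            node_probs[node] = v / v.sum()
    else:
        # downward messages: Down_root = prior; for child c of p,
        # Down_c = P_c^T (Down_p * prod_{siblings b} (P_b U_b))
        down: Dict[int, np.ndarray] = {tree.root: model.root_prior.copy()}
        for node in tree.nodes():  # preorder
            kids = tree.children.get(node, [])
            if not kids:
                continue
            msgs = {c: partials[c][0] @ pmats[c].T for c in kids}
            for c in kids:
                m = down[node].copy()
                for b in kids:
                    if b != c:
                        m = m * msgs[b]
                d = pmats[c].T @ m
                tot = d.sum()
                if tot > 0:
                    d = d / tot  # rescale; marginals are normalized anyway
                down[c] = d
        for node in tree.internal_nodes():
            v = partials[node][0] * down[node]
            node_probs[node] = v / v.sum()

    fp = {n: tree.clade_tips(n) for n in tree.internal_nodes()}
    return AsrResult(node_probs=node_probs, fingerprint=fp, loglik=loglik, q=model.q)


def asr_two_trees(
    extant_tree: DatedTree,
    grafted_tree: DatedTree,
    tip_states: Mapping[str, int],
    fossil_states: Mapping[str, int],
    k: int,
    q: Optional[float] = None,
    q_max: float = 100.0,
) -> Tuple[AsrResult, AsrResult]:
    """Paired extant-only vs fossil-informed reconstructions of one character.

    The extant tree is scored with ``tip_states`` only; the grafted tree adds
    ``fossil_states`` for every fossil tip.  If ``q`` is None the rate is
    ML-estimated separately on each tree.  Results are keyed so that each
    extant-tree MRCA can be matched to its grafted-tree counterpart through
    ``AsrResult.fingerprint`` restricted to extant labels (shadow-MRCA rows
    exist only in the grafted result).
    """
    extant_labels = set(extant_tree.tip_labels())
    fossil_labels = set(grafted_tree.tip_labels()) - extant_labels
    missing = sorted(fossil_labels - set(fossil_states))
    if missing:
        raise ValueError(f"no state supplied for grafted fossil(s): {missing}")

    char_extant = CharacterColumn(
        states={t: tip_states.get(t, MISSING) for t in extant_labels}, k=k
    )
    grafted_states = {t: tip_states.get(t, MISSING) for t in extant_labels}
    grafted_states.update({f: int(fossil_states[f]) for f in fossil_labels})
    char_grafted = CharacterColumn(states=grafted_states, k=k)

    results = []
    for tree, char in ((extant_tree, char_extant), (grafted_tree, char_grafted)):
        if q is None:
            q_hat, _, at_bound = ml_rate(tree, [char], k, q_max=q_max)
        else:
            q_hat, at_bound = float(q), False
        model = MkModel(k=k, q=q_hat)
        res = marginal_asr(tree, char, model)
        res.q_estimated = q is None
        res.q_at_boundary = at_bound
        results.append(res)
    return results[0], results[1]


def match_nodes(
    extant_res: AsrResult, grafted_res: AsrResult, extant_labels: FrozenSet[str]
) -> Dict[int, int]:
    """Map extant-tree internal nodes to grafted-tree nodes with the same
    extant-tip fingerprint (shadow MRCAs never match: their extant fingerprint
    duplicates their child's and the *lowest* grafted node wins)."""
    by_fp: Dict[FrozenSet[str], int] = {}
    for node, fp in grafted_res.fingerprint.items():
        key = frozenset(fp & extant_labels)
        prev = by_fp.get(key)
        # keep the node with the smallest clade (lowest = the true counterpart)
        if prev is None or len(grafted_res.fingerprint[node]) < len(
            grafted_res.fingerprint[prev]
        ):
            by_fp[key] = node
    out = {}
    for node, fp in extant_res.fingerprint.items():
        if fp in by_fp:
            out[node] = by_fp[fp]
    return out
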