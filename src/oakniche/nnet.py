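"""Hamming distances on categorical trait matrices and neighbour-net split networks.

The morphospace machinery works in two steps.  First, pairwise Hamming
distances are computed on a taxa x characters matrix of categorical states
(binary or small-arity; missing allowed): d(i,j) is the fraction of jointly
scored characters in which the two taxa differ, mismatches counting 1
whatever the state pair.

Second, the neighbour-net agglomeration of Bryant & Moulton turns the
distance matrix into a *circular split system*: an ordering of the taxa
around a circle plus non-negative weights for splits whose sides are
contiguous arcs.  Stage 1 repeatedly selects two clusters by the
neighbour-joining criterion, then two of their member nodes by the same
criterion on a mixed node/cluster unit set, links them, and replaces any
3-chain x-y-z by two nodes u, v via the standard reduction

    d(u,s) = 2/3 d(x,s) + 1/3 d(y,s)
    d(v,s) = 2/3 d(z,s) + 1/3 d(y,s)
    d(u,v) = 1/3 (d(x,y) + d(x,z) + d(y,z)),

unwinding the reductions at the end to obtain the circular ordering.  Stage 2
estimates weights for all n(n-1)/2 circular splits by non-negative least
squares and drops numerically zero ones.  For circular-decomposable input
(in particular any additive tree metric) the ordering is compatible with the
generating system and the weighted splits reproduce the distances.

Selection ties are broken by lexicographic taxon label so orderings are
reproducible.  The output is the split system itself (NEXUS SPLITS block,
loadable in split-network viewers); drawing is out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "TraitMatrix",
    "SplitSystem",
    "hamming",
    "neighbor_net",
    "split_distances",
    "circular_order",
    "read_trait_matrix",
    "write_splits_nexus",
]

MISSING = -1


@dataclass
class TraitMatrix:
    """Categorical character matrix: taxa x characters, -1 = missing."""

    taxa: List[str]
    data: np.ndarray  # (n_taxa, n_chars) int
    arity: np.ndarray  # (n_chars,) int, >= 2

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=int)
        self.arity = np.asarray(self.arity, dtype=int)
        if len(self.taxa) < 3:
            raise ValueError("need at least 3 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.data.shape != (len(self.taxa), len(self.arity)):
            raise ValueError("data shape does not match taxa x characters")
        if (self.arity < 2).any():
            raise ValueError("character arity must be >= 2")
        for j in range(self.data.shape[1]):
            col = self.data[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                raise ValueError(f"character {j} has no non-missing observation")
            if (obs >= self.arity[j]).any() or (obs < 0).any():
                raise ValueError(f"character {j} has states outside its arity")


def hamming(matrix: TraitMatrix) -> np.ndarray:
    """Normalized Hamming distances: differing / jointly scored characters.

    Ternary (or higher-arity) mismatches count 1 regardless of the state
    pair.  A taxon pair sharing no scored character is an error naming the
    pair.
    """
    X = matrix.data
    n = X.shape[0]
    d = np.zeros((n, n))
    scored = X != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = scored[i] & scored[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
                    "jointly scored character"
                )
            diff = int((X[i, both] != X[j, both]).sum())
            d[i, j] = d[j, i] = diff / m
    return d


@dataclass
class SplitSystem:
    """Circular split system: taxon cycle + weighted splits.

    Each split is stored as the frozenset of taxa on the side *not*
    containing the first taxon of the cycle; every stored split is a
    contiguous arc of the cycle.
    """

    cycle: List[str]
    weights: Dict[FrozenSet[str], float]

    def __post_init__(self):
        pos = {t: i for i, t in enumerate(self.cycle)}
        for split, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative split weight for {sorted(split)}")
            if not split or len(split) >= len(self.cycle):
                raise ValueError("split sides must be proper non-empty subsets")
            idx = sorted(pos[t] for t in split)
            if idx[-1] - idx[0] != len(idx) - 1:
                raise ValueError(f"split {sorted(split)} is not an arc of the cycle")


def split_distances(system: SplitSystem) -> Tuple[List[str], np.ndarray]:
    """Metric induced by the split system: d(i,j) = sum of weights of splits
    separating i from j."""
    taxa = list(system.cycle)
    pos = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))
    for split, w in system.weights.items():
        side = np.zeros(n, dtype=bool)
        for t in split:
            side[pos[t]] = True
        sep = side[:, None] != side[None, :]
        d += w * sep
    return taxa, d


# --------------------------------------------------------------- stage 1: cycle

def circular_order(dist: np.ndarray, taxa: Sequence[str]) -> List[str]:
    """Neighbour-net agglomeration producing the circular taxon ordering."""
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    dist = np.asarray(dist, dtype=float)
    _check_distance(dist)

    # working distance store over active node ids
    D: Dict[Tuple[int, int], float] = {}
    next_id = n
    active: List[int] = list(range(n))
    rep = {i: taxa[i] for i in range(n)}  # representative label for tie-breaks
    nbr: Dict[int, int] = {}  # pair links within clusters
    expansions: List[Tuple[int, int, int, int, int]] = []  # (u, v, a, b, c)

    def d(x: int, y: int) -> float:
        if x == y:
            return 0.0
        return D[(min(x, y), max(x, y))]

    def setd(x: int, y: int, val: float) -> None:
        D[(min(x, y), max(x, y))] = val

    for i in range(n):
        for j in range(i + 1, n):
            setd(i, j, float(dist[i, j]))

    def clusters() -> List[List[int]]:
        out = []
        seen = set()
        for x in sorted(active, key=lambda v: rep[v]):
            if x in seen:
                continue
            if x in nbr:
                pair = sorted((x, nbr[x]), key=lambda v: rep[v])
                out.append(pair)
                seen.update(pair)
            else:
                out.append([x])
                seen.add(x)
        return out

    def cdist(A: List[int], B: List[int]) -> float:
        return float(np.mean([d(x, y) for x in A for y in B]))

    def reduce3(a: int, b: int, c: int) -> Tuple[int, int]:
        """Replace chain a-b-c by u-v; returns (u, v) with u on a's side."""
        nonlocal next_id
        u, v = next_id, next_id + 1
        next_id += 2
        others = [s for s in active if s not in (a, b, c)]
        for s in others:
            setd(u, s, (2.0 / 3.0) * d(a, s) + (1.0 / 3.0) * d(b, s))
            setd(v, s, (2.0 / 3.0) * d(c, s) + (1.0 / 3.0) * d(b, s))
        setd(u, v, (d(a, b) + d(a, c) + d(b, c)) / 3.0)
        rep[u] = min(rep[a], rep[b])
        rep[v] = min(rep[c], rep[b])
        for x in (a, b, c):
            active.remove(x)
            nbr.pop(x, None)
        active.extend([u, v])
        nbr[u] = v
        nbr[v] = u
        expansions.append((u, v, a, b, c))
        return u, v

    while len(active) > 3:
        cl = clusters()
        if len(cl) < 2:
            break
        m = len(cl)
        # --- cluster pair selection (NJ criterion on cluster distances)
        cd = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                cd[i, j] = cd[j, i] = cdist(cl[i], cl[j])
        r = cd.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * cd[i, j] - r[i] - r[j]
                key = (q, rep[cl[i][0]], rep[cl[j][0]])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, ia, ib = best
        A, B = cl[ia], cl[ib]

        # --- node pair selection on the mixed unit set
        units: List[List[int]] = [cl[t] for t in range(m) if t not in (ia, ib)]
        units += [[x] for x in A] + [[x] for x in B]
        mu = len(units)

        def udist(x: int, U: List[int]) -> float:
            return float(np.mean([d(x, y) for y in U if y != x])) if U != [x] else 0.0

        best2 = None
        for x in A:
            rx = sum(udist(x, U) for U in units if U != [x])
            for y in B:
                ry = sum(udist(y, U) for U in units if U != [y])
                q = (mu - 2) * d(x, y) - rx - ry
                key = (q, min(rep[x], rep[y]), max(rep[x], rep[y]))
                if best2 is None or key < best2[0]:
                    best2 = (key, x, y)
        _, x, y = best2

        # --- link x and y; chain = A oriented to end at x, then B from y
        chain_a = A if len(A) == 1 or A[1] == x else A[::-1]
        chain_b = B if len(B) == 1 or B[0] == y else B[::-1]
        chain = chain_a + chain_b
        if len(chain) == 2:
            nbr[chain[0]] = chain[1]
            nbr[chain[1]] = chain[0]
        elif len(chain) == 3:
            reduce3(*chain)
        else:  # 4-chain: two successive reductions
            u, v = reduce3(chain[0], chain[1], chain[2])
            reduce3(u, v, chain[3])

    # --- assemble the terminal cycle, then unwind reductions
    cycle: List[int] = []
    for comp in clusters():
        cycle.extend(comp)
    for u, v, a, b, c in reversed(expansions):
        i = cycle.index(u)
        j = cycle.index(v)
        nn = len(cycle)
        if (i + 1) % nn == j:
            cycle[i : i + 1] = [a, b]
            cycle[cycle.index(v)] = c
        elif (j + 1) % nn == i:
            cycle[j : j + 1] = [c, b]
            cycle[cycle.index(u)] = a
        else:
            raise AssertionError("reduction pair not adjacent in cycle")

    labels = [taxa[i] for i in cycle]
    return _canonical_rotation(labels)


def _canonical_rotation(cycle: List[str]) -> List[str]:
    """Rotate/reflect so the smallest label is first and its smaller
    neighbour second (deterministic representative of the circular class)."""
    n = len(cycle)
    i = min(range(n), key=lambda k: cycle[k])
    fwd = [cycle[(i + k) % n] for k in range(n)]
    rev = [cycle[(i - k) % n] for k in range(n)]
    return fwd if fwd[1] <= rev[1] else rev


def _check_distance(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")


# ------------------------------------------------------------- stage 2: weights

def neighbor_net(
    dist: np.ndarray,
    taxa: Sequence[str],
    eps: float = 1e-8,
) -> SplitSystem:
    """Full neighbour-net: circular ordering + non-negative least-squares
    weights for all circular splits; splits with weight <= ``eps`` dropped."""
    taxa = list(taxa)
    dist = np.asarray(dist, dtype=float)
    _check_distance(dist)
    if len(taxa) != dist.shape[0]:
        raise ValueError("taxa/distance size mismatch")
    cycle = circular_order(dist, taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(cycle)

    # enumerate circular splits by the arc not containing cycle[0]
    splits: List[Tuple[int, int]] = [
        (i, j) for i in range(1, n) for j in range(i + 1, n + 1)
    ]
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    pair_index = {pq: r for r, pq in enumerate(pairs)}

    A = np.zeros((len(pairs), len(splits)))
    pos_in_cycle = {t: i for i, t in enumerate(cycle)}
    for s, (i, j) in enumerate(splits):
        inside = set(range(i, j))
        for p in range(n):
            for q in range(p + 1, n):
                if (p in inside) != (q in inside):
                    A[pair_index[(p, q)], s] = 1.0
    b = np.array([dist[idx[cycle[p]], idx[cycle[q]]] for p, q in pairs])
    w, _ = nnls(A, b)

    weights: Dict[FrozenSet[str], float] = {}
    for s, (i, j) in enumerate(splits):
        if w[s] > eps:
            weights[frozenset(cycle[i:j])] = float(w[s])
    return SplitSystem(cycle=cycle, weights=weights)


# ------------------------------------------------------------------- text I/O

def read_trait_matrix(text: str) -> TraitMatrix:
    """Trait matrix from tab-separated text: taxon <tab> state string
    (digits, '?' for missing).  Arity per character = max observed state + 1,
    floored at 2."""
    taxa: List[str] = []
    rows: List[List[int]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, states = line.split("\t")
        taxa.append(name)
        rows.append([MISSING if ch == "?" else int(ch) for ch in states])
    data = np.array(rows, dtype=int)
    arity = np.maximum(data.max(axis=0) + 1, 2)
    return TraitMatrix(taxa=taxa, data=data, arity=arity)


def write_trait_matrix(matrix: TraitMatrix) -> str:
    lines = ["# taxon\tstates"]
    for i, t in enumerate(matrix.taxa):
        s = "".join("?" if v == MISSING else str(v) for v in matrix.data[i])
        lines.append(f"{t}\t{s}")
    return "\n".join(lines) + "\n"


def write_splits_nexus(system: SplitSystem) -> str:
    """SplitsTree-compatible NEXUS: TAXA block + ST_SPLITS block with the
    circular ordering and weighted splits (taxon indices are 1-based in
    cycle order)."""
    n = len(system.cycle)
    pos = {t: i + 1 for i, t in enumerate(system.cycle)}
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN TAXA;\n")
    out.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
    for t in system.cycle:
        out.write(f"    '{t}'\n")
    out.write("  ;\nEND;\n\nBEGIN ST_SPLITS;\n")
    out.write(f"  DIMENSIONS NTAX={n} NSPLITS={len(system.weights)};\n")
    out.write("  FORMAT LABELS=NO WEIGHTS=YES;\n")
    cyc = " ".join(str(i + 1) for i in range(n))
    out.write(f"  CYCLE {cyc};\n  MATRIX\n")
    items = sorted(
        system.weights.items(), key=lambda kv: sorted(pos[t] for t in kv[0])
    )
    for split, w in items:
        members = " ".join(str(i) for i in sorted(pos[t] for t in split))
        out.write(f"    {w:.10g}\t{members},\n")
    out.write("  ;\nEND;\n")
    return out.getvalue()
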