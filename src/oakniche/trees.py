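"""Dated rooted trees: container, validation, I/O.

A :class:`DatedTree` is a rooted tree whose edges carry lengths in millions
of years (Ma) and whose nodes carry ages measured backwards from the present
(age 0 = today).  The root age equals the longest root-to-tip path, so an
ultrametric chronogram has every extant tip at age 0; fossil tips grafted
later sit at positive ages.

Newick/NEXUS reading and writing is delegated to dendropy; everything that
touches ages, monophyly or tree surgery is implemented here on a plain
parent/children representation so that downstream modules (grafting, pruning
likelihood) can manipulate nodes directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

__all__ = [
    "DatedTree",
    "TreeValidationError",
    "TreeParseError",
    "parse_tree",
    "write_tree",
]

AGE_TOL = 1e-9
TIP_AGE_TOL = 1e-6


class TreeParseError(ValueError):
    """Raised when tree text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates the dated-tree invariants."""


@dataclass
class DatedTree:
    """Rooted tree with node ages (Ma before present) and edge lengths (Ma).

    Nodes are integer ids.  ``parent[root]`` is absent; every non-root node
    has an entry in ``edge_length``.  Tips carry unique string labels.
    """

    root: int
    parent: Dict[int, int]
    children: Dict[int, List[int]]
    edge_length: Dict[int, float]
    label: Dict[int, str]  # tips (and optionally named internals)
    age: Dict[int, float] = field(default_factory=dict)
    _next_id: int = 0

    # ------------------------------------------------------------------ build
    @classmethod
    def from_parent_map(
        cls,
        parent: Dict[int, int],
        edge_length: Dict[int, float],
        label: Dict[int, str],
    ) -> "DatedTree":
        nodes = set(parent) | set(parent.values())
        roots = [n for n in nodes if n not in parent]
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        children: Dict[int, List[int]] = {n: [] for n in nodes}
        for c, p in parent.items():
            children[p].append(c)
        t = cls(
            root=roots[0],
            parent=dict(parent),
            children=children,
            edge_length=dict(edge_length),
            label=dict(label),
            _next_id=max(nodes) + 1,
        )
        t.recompute_ages()
        # canonicalize: edge lengths become exact age differences, so tree
        # surgery (splitting a branch and re-merging it) is exactly invertible
        for c, p in t.parent.items():
            d = t.age[p] - t.age[c]
            t.edge_length[c] = d if d > 0.0 else 0.0
        t.validate()
        return t

    # ------------------------------------------------------------ node access
    def nodes(self) -> List[int]:
        """All node ids in preorder from the root."""
        out: List[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    def postorder(self) -> List[int]:
        return list(reversed(self.nodes()))

    def tips(self) -> List[int]:
        return [n for n in self.nodes() if not self.children.get(n)]

    def tip_labels(self) -> List[str]:
        return [self.label[n] for n in self.tips()]

    def internal_nodes(self) -> List[int]:
        return [n for n in self.nodes() if self.children.get(n)]

    def tip_by_label(self, name: str) -> int:
        for n in self.tips():
            if self.label.get(n) == name:
                return n
        raise KeyError(f"unknown tip label: {name!r}")

    def new_node_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def copy(self) -> "DatedTree":
        return DatedTree(
            root=self.root,
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            edge_length=dict(self.edge_length),
            label=dict(self.label),
            age=dict(self.age),
            _next_id=self._next_id,
        )

    # ------------------------------------------------------------------- ages
    def recompute_ages(self) -> None:
        """Set node ages from edge lengths: root age = max root-to-tip path."""
        depth: Dict[int, float] = {self.root: 0.0}
        for n in self.nodes():
            for c in self.children.get(n, []):
                depth[c] = depth[n] + self.edge_length[c]
        height = max(depth[t] for t in self.tips())
        self.age = {n: height - d for n, d in depth.items()}
        # clamp tiny negatives from float accumulation
        for n, a in self.age.items():
            if -AGE_TOL < a < 0.0:
                self.age[n] = 0.0

    def validate(self, allow_noncontemporaneous: bool = True) -> None:
        seen: Set[str] = set()
        for t in self.tips():
            lab = self.label.get(t)
            if lab is None:
                raise TreeValidationError(f"tip {t} has no label")
            if lab in seen:
                raise TreeValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for c, p in self.parent.items():
            bl = self.edge_length[c]
            if bl < 0:
                raise TreeValidationError(f"negative branch length {bl} on node {c}")
            if self.age[p] < self.age[c] - AGE_TOL:
                raise TreeValidationError(
                    f"age inversion: parent {p} ({self.age[p]}) younger than child "
                    f"{c} ({self.age[c]})"
                )
            if abs(self.age[c] - (self.age[p] - bl)) > 1e-6:
                raise TreeValidationError(f"age/edge-length mismatch at node {c}")
        if not allow_noncontemporaneous:
            for t in self.tips():
                if abs(self.age[t]) > TIP_AGE_TOL:
                    raise TreeValidationError(
                        f"non-contemporaneous tip {self.label[t]!r} at age {self.age[t]}"
                    )

    def is_ultrametric(self, tol: float = TIP_AGE_TOL) -> bool:
        return all(abs(self.age[t]) <= tol for t in self.tips())

    # -------------------------------------------------------------- relations
    def ancestors(self, node: int) -> List[int]:
        """Path from ``node``'s parent up to the root (inclusive)."""
        out = []
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def mrca(self, tip_names: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        names = list(tip_names)
        if not names:
            raise ValueError("empty tip set")
        nodes = [self.tip_by_label(n) for n in names]
        if len(nodes) == 1:
            return nodes[0]
        paths = []
        for n in nodes:
            paths.append([n] + self.ancestors(n))
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # the lowest common node is the first along any tip's upward path
        for n in paths[0]:
            if n in common:
                return n
        raise AssertionError("rooted tree must have a common ancestor")

    def clade_tips(self, node: int) -> FrozenSet[str]:
        """Labels of all tips descending from (or equal to) ``node``."""
        out: Set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children.get(n, [])
            if not kids:
                out.add(self.label[n])
            else:
                stack.extend(kids)
        return frozenset(out)

    def is_monophyletic(self, tip_names: Iterable[str]) -> bool:
        names = frozenset(tip_names)
        return self.clade_tips(self.mrca(names)) == names

    def branch_age_interval(self, tip_names: Iterable[str]) -> Tuple[float, float]:
        """Age span of the stem branch above a monophyletic clade.

        Returns ``(age of clade MRCA, age of its parent)``; for the full tree
        the upper end is ``+inf``.
        """
        names = frozenset(tip_names)
        node = self.mrca(names)
        got = self.clade_tips(node)
        if got != names:
            intruders = sorted(got - names)
            raise TreeValidationError(
                f"clade {sorted(names)} is not monophyletic; MRCA also contains {intruders}"
            )
        low = self.age[node]
        if node == self.root:
            return (low, float("inf"))
        return (low, self.age[self.parent[node]])

    # --------------------------------------------------------------- serialise
    def to_dendropy(self) -> dendropy.Tree:
        taxon_namespace = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxon_namespace)
        dnodes: Dict[int, dendropy.Node] = {}
        for n in self.nodes():
            dn = dendropy.Node()
            if n in self.edge_length:
                dn.edge.length = self.edge_length[n]
            if not self.children.get(n):
                dn.taxon = taxon_namespace.new_taxon(self.label[n])
            dnodes[n] = dn
            if n == self.root:
                dtree.seed_node = dn
            else:
                dnodes[self.parent[n]].add_child(dn)
        return dtree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".12g"
        )
        return s.strip() + "\n"

    def to_nexus(self) -> str:
        return self.to_dendropy().as_string(
            schema="nexus", suppress_rooting=True, real_value_format_specifier=".12g"
        )

    def age_table(self) -> List[Tuple[int, str, float]]:
        """(node id, tip label or '', age) rows for the sidecar file."""
        return [
            (n, self.label.get(n, ""), self.age[n]) for n in self.nodes()
        ]


def _from_dendropy(dtree: dendropy.Tree) -> DatedTree:
    parent: Dict[int, int] = {}
    edge_length: Dict[int, float] = {}
    label: Dict[int, str] = {}
    ids: Dict[dendropy.Node, int] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[nd] = i
        if nd.parent_node is not None:
            parent[i] = ids[nd.parent_node]
            bl = nd.edge.length
            if bl is None:
                raise TreeParseError("branch length missing on an edge")
            if bl < 0:
                raise TreeValidationError(f"negative branch length {bl}")
            edge_length[i] = float(bl)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise TreeParseError("unlabelled tip")
            label[i] = nd.taxon.label
    if len(ids) == 1:
        raise TreeParseError("tree has no edges")
    # single-tip tree "(A:1);" arrives as root + one leaf; that is fine
    return DatedTree.from_parent_map(parent, edge_length, label)


def parse_tree(text: str, schema: str = "newick") -> DatedTree:
    """Parse Newick or NEXUS text into a :class:`DatedTree`.

    Ages are computed from branch lengths with the root age equal to the
    longest root-to-tip path.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several error types
        raise TreeParseError(f"could not parse tree text: {e}") from e
    return _from_dendropy(dtree)


def write_tree(tree: DatedTree, schema: str = "newick") -> str:
    if schema == "newick":
        return tree.to_newick()
    if schema == "nexus":
        return tree.to_nexus()
    raise ValueError(f"unknown schema: {schema}")
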