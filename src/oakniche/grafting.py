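"""Fossil tip grafting on dated trees.

A fossil that can be tied to a particular lineage is added as a *sister tip*
of that lineage: the stem branch above the anchor clade is broken at the
fossil's oldest possible age by a new internal node (the "shadow MRCA"), and
the fossil tip hangs from it with edge length ``oldest - youngest``, so the
fossil tip sits at age ``youngest``.  Fossils that cannot be tied to a branch
are carried through in reports but never enter the tree.

Grafting is purely additive: no pre-existing node age, edge length or tip is
touched, and pruning the fossil tips (suppressing the degree-2 shadow nodes)
restores the input tree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence

from .trees import DatedTree

__all__ = [
    "FossilSpec",
    "GraftError",
    "graft_fossil",
    "graft_all",
    "degraft",
    "read_fossil_specs",
    "write_fossil_specs",
    "SHADOW_PREFIX",
]

logger = logging.getLogger(__name__)

SHADOW_PREFIX = "shadow:"


class GraftError(ValueError):
    """Raised when a fossil cannot legally be grafted."""


@dataclass(frozen=True)
class FossilSpec:
    """A fossil taxon with its anchoring clade and age range.

    ``anchor`` is the set of extant tip labels whose stem branch the fossil
    breaks.  ``oldest_age`` dates the shadow MRCA; ``youngest_age`` dates the
    fossil tip itself.  ``state`` is the niche category (or trait value)
    scored for the fossil.  ``assignable=False`` marks fossils that cannot be
    tied to any branch ("unconnected stars"): they are skipped by grafting.
    """

    label: str
    anchor: FrozenSet[str]
    oldest_age: float
    youngest_age: float
    state: Optional[int] = None
    assignable: bool = True

    def __post_init__(self):
        if self.youngest_age < 0:
            raise ValueError(f"{self.label}: youngest_age must be >= 0")
        if self.oldest_age < self.youngest_age:
            raise ValueError(
                f"{self.label}: oldest_age ({self.oldest_age}) < youngest_age "
                f"({self.youngest_age})"
            )
        if not self.anchor:
            raise ValueError(f"{self.label}: empty anchor clade")


def _splice(tree: DatedTree, anchor_node: int, spec: FossilSpec) -> DatedTree:
    """Break the branch above ``anchor_node`` at ``spec.oldest_age`` (no checks).

    If ``anchor_node`` is the root, the shadow node becomes the new root.
    """
    out = tree.copy()
    shadow = out.new_node_id()
    tip = out.new_node_id()

    if anchor_node == out.root:
        out.root = shadow
    else:
        old_parent = out.parent[anchor_node]
        out.parent[shadow] = old_parent
        kids = out.children[old_parent]
        kids[kids.index(anchor_node)] = shadow
        out.edge_length[shadow] = out.age[old_parent] - spec.oldest_age
    out.parent[anchor_node] = shadow
    out.children[shadow] = [anchor_node, tip]
    out.parent[tip] = shadow
    out.children[tip] = []

    out.age[shadow] = spec.oldest_age
    out.age[tip] = spec.youngest_age
    out.edge_length[anchor_node] = spec.oldest_age - out.age[anchor_node]
    out.edge_length[tip] = spec.oldest_age - spec.youngest_age
    out.label[tip] = spec.label
    out.label[shadow] = SHADOW_PREFIX + spec.label
    out.validate()
    return out


def graft_fossil(tree: DatedTree, spec: FossilSpec) -> DatedTree:
    """Insert one fossil tip as a sister lineage of its anchor clade.

    The shadow MRCA is placed on the anchor's stem branch at ``oldest_age``;
    the fossil tip is attached below it at ``youngest_age``.  The oldest age
    must fall strictly inside the open age interval of the stem branch,
    otherwise a :class:`GraftError` names the admissible interval (ages are
    never clamped or re-anchored: a violation signals bad input).
    """
    if not spec.assignable:
        logger.info("fossil %s not assignable to a branch; skipped", spec.label)
        return tree
    if spec.label in set(tree.tip_labels()):
        raise GraftError(f"fossil label {spec.label!r} duplicates an existing tip")
    low, high = tree.branch_age_interval(spec.anchor)
    if not (low < spec.oldest_age < high):
        raise GraftError(
            f"fossil {spec.label!r}: oldest age {spec.oldest_age} outside the open "
            f"age interval ({low}, {high}) of the branch above {sorted(spec.anchor)}"
        )
    return _splice(tree, tree.mrca(spec.anchor), spec)


def graft_all(tree: DatedTree, specs: Sequence[FossilSpec]) -> DatedTree:
    """Graft every assignable fossil, oldest-first per anchor branch.

    Fossils anchored to the same branch are inserted in order of decreasing
    oldest age, so each successive (younger) fossil breaks the stem segment
    that still spans its age and the backbone is pectinate.  The result is
    independent of the input list order; exact age ties are broken by fossil
    label (logged), the earlier label ending up closer to the root.
    """
    usable = [s for s in specs if s.assignable]
    for s in specs:
        if not s.assignable:
            logger.info("fossil %s not assignable; excluded from tree", s.label)
    by_key = sorted(usable, key=lambda s: (-s.oldest_age, s.label))
    seen = {}
    for s in by_key:
        key = (s.anchor, s.oldest_age)
        if key in seen:
            logger.info(
                "fossils %s and %s share anchor and oldest age; tie broken by label",
                seen[key], s.label,
            )
        seen[key] = s.label
    out = tree
    for spec in by_key:
        out = _graft_on_current(out, spec)
    return out


def _graft_on_current(tree: DatedTree, spec: FossilSpec) -> DatedTree:
    """Graft against the already-grafted tree.

    Validates the oldest age against the *original* stem interval (the span
    from the extant anchor MRCA up to the first non-shadow ancestor), then
    splices into whichever segment of that stem still spans the age.  Shadow
    nodes from older fossils may sit at equal age (zero-length segments).
    """
    anchor_node = tree.mrca(spec.anchor)
    got = tree.clade_tips(anchor_node)
    extra = got - spec.anchor
    if extra and not all(_is_fossil_tip(tree, anchor_node, lab) for lab in extra):
        raise GraftError(
            f"clade {sorted(spec.anchor)} is not monophyletic; MRCA also contains "
            f"{sorted(extra)}"
        )
    low = tree.age[anchor_node]
    # top of the original stem = first ancestor that is not a shadow node
    node = anchor_node
    top = None
    walk = anchor_node
    while walk != tree.root:
        p = tree.parent[walk]
        if not str(tree.label.get(p, "")).startswith(SHADOW_PREFIX):
            top = p
            break
        walk = p
    high = float("inf") if top is None else tree.age[top]
    if not (low < spec.oldest_age < high):
        raise GraftError(
            f"fossil {spec.label!r}: oldest age {spec.oldest_age} outside the open "
            f"age interval ({low}, {high}) of the branch above {sorted(spec.anchor)}"
        )
    # climb through shadow segments strictly younger than the fossil
    while node != tree.root and tree.age[tree.parent[node]] < spec.oldest_age:
        node = tree.parent[node]
    return _splice(tree, node, spec)


def _is_fossil_tip(tree: DatedTree, below: int, label: str) -> bool:
    """True if ``label`` is a tip hanging from a shadow node within the clade."""
    tip = tree.tip_by_label(label)
    parent = tree.parent.get(tip)
    return parent is not None and str(tree.label.get(parent, "")).startswith(SHADOW_PREFIX)


def degraft(tree: DatedTree, fossil_labels: Iterable[str]) -> DatedTree:
    """Remove fossil tips and suppress their shadow nodes: the exact inverse of grafting."""
    out = tree.copy()
    for lab in fossil_labels:
        tip = out.tip_by_label(lab)
        shadow = out.parent[tip]
        kids = [c for c in out.children[shadow] if c != tip]
        if len(kids) != 1:
            raise GraftError(f"node above fossil {lab!r} is not a degree-2 shadow node")
        keep = kids[0]
        grand = out.parent.get(shadow)
        if grand is None:  # shadow node is the root
            out.root = keep
            out.parent.pop(keep, None)
            out.edge_length.pop(keep, None)
        else:
            gkids = out.children[grand]
            gkids[gkids.index(shadow)] = keep
            out.parent[keep] = grand
            # ages are untouched by grafting, so the age difference restores
            # the pre-graft edge length exactly
            out.edge_length[keep] = out.age[grand] - out.age[keep]
        for d in (tip, shadow):
            out.parent.pop(d, None)
            out.children.pop(d, None)
            out.edge_length.pop(d, None)
            out.label.pop(d, None)
            out.age.pop(d, None)
    out.validate()
    return out


# ------------------------------------------------------------------ text I/O

def read_fossil_specs(text: str) -> List[FossilSpec]:
    """Read fossil specs from tab-separated text.

    Columns: label, anchor tips joined by ';', oldest age, youngest age,
    state (integer or '-'), assignable (0/1).  Lines starting with '#' are
    comments.
    """
    specs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"expected 6 tab-separated fields, got {len(parts)}: {line!r}")
        label, anchor, oldest, youngest, state, assignable = parts
        specs.append(
            FossilSpec(
                label=label,
                anchor=frozenset(anchor.split(";")),
                oldest_age=float(oldest),
                youngest_age=float(youngest),
                state=None if state == "-" else int(state),
                assignable=assignable.strip() in ("1", "true", "True"),
            )
        )
    return specs


def write_fossil_specs(specs: Sequence[FossilSpec]) -> str:
    lines = ["# label\tanchor\toldest\tyoungest\tstate\tassignable"]
    for s in specs:
        state = "-" if s.state is None else str(s.state)
        lines.append(
            f"{s.label}\t{';'.join(sorted(s.anchor))}\t{s.oldest_age:.12g}"
            f"\t{s.youngest_age:.12g}\t{state}\t{int(s.assignable)}"
        )
    return "\n".join(lines) + "\n"
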