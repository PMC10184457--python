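"""Synthetic-data generators for every pipeline input.

The real study inputs — a RAD-seq chronogram, GBIF occurrence downloads, a
5-arc-minute climate raster, a fossil compendium — are not redistributable
at package scale, so each consumer gets a generator that emulates the
statistical structure of its input: birth-death dated trees, Mk-evolved
categorical characters, spatially clustered occurrences over a mosaic
climate grid, multinomially drawn ABBA/BABA site patterns with a
controllable admixture signal, and fossils with uniform age draws on valid
branches.  Every generator is a pure function of its arguments and a seed;
a single root seed fans out to independent substreams
(:class:`numpy.random.SeedSequence`) so changing one generator's settings
never perturbs another's draws.

The ``cerris_like`` preset assembles a complete demonstration workspace
shaped like the cork-oak study: a 15-species dated ingroup tree, a 5-state
climate-niche character, per-species Köppen/biome configurations, a
12-trait leaf matrix (11 binary and 1 ternary character), and a set of ~47
fossils, most of them assignable to branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dstat import QuartetData
from .grafting import FossilSpec
from .koppen import BIOME_CODES, KoppenGrid, KoppenProfile
from .mk import CharacterColumn, mk_transition
from .trees import DatedTree

__all__ = [
    "sim_dated_tree",
    "sim_mk_characters",
    "sim_koppen_world",
    "sim_quartet_sites",
    "sim_fossils",
    "PatchSpec",
    "SpeciesRangeSpec",
    "cerris_like_tree",
    "cerris_like_niche_states",
    "cerris_like_profiles",
    "cerris_like_biomes",
    "cerris_like_leaf_matrix",
    "cerris_like_fossils",
    "suber_like_scenario",
]

ABBA = (0, 1, 1, 0)
BABA = (1, 0, 1, 0)
UNINFORMATIVE = (0, 0, 0, 0)

# gamma-to-excess-ABBA scale: at gamma=0.3 the planted excess is 0.04, which
# with the default p0=0.02 background gives E[D] = 0.04/0.08 = 0.5
GAMMA_DELTA = 2.0 / 15.0


# ----------------------------------------------------------------- dated trees

def sim_dated_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> DatedTree:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips.

    Forward simulation from the crown (two lineages): exponential waiting
    times with total rate (birth+death) x lineage count; the clock stops at
    the first event *after* the lineage count reaches ``n_tips``, so for a
    pure-birth process the expected root age is sum_{i=2..n} 1/(i*birth).
    Replicates that go extinct (or whose extant count falls) before reaching
    ``n_tips`` are redrawn; persistently non-viable rates are an error.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if birth <= 0 or death < 0:
        raise ValueError("need birth > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        out = _try_bd(n_tips, birth, death, rng)
        if out is not None:
            return out
    raise RuntimeError(
        f"no surviving tree with {n_tips} tips after {max_retries} attempts "
        f"(birth={birth}, death={death})"
    )


def _try_bd(n_tips: int, birth: float, death: float, rng) -> Optional[DatedTree]:
    # events on a growing node table; lineage = (parent_node, start_time)
    parent: Dict[int, int] = {}
    edge: Dict[int, float] = {}
    next_id = 1
    root = 0
    alive: List[Tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    total = birth + death
    while len(alive) < n_tips:
        if not alive or len(alive) < 2:
            return None
        t += rng.exponential(1.0 / (total * len(alive)))
        i = rng.integers(len(alive))
        p, t0 = alive.pop(i)
        if rng.random() < birth / total:
            node = next_id
            next_id += 1
            parent[node] = p
            edge[node] = t - t0
            alive.append((node, t))
            alive.append((node, t))
        # death: the lineage simply disappears (unsampled extinct branch)
    # stop just before the next event
    t += rng.exponential(1.0 / (total * len(alive)))
    tips: Dict[int, str] = {}
    for j, (p, t0) in enumerate(alive):
        node = next_id
        next_id += 1
        parent[node] = p
        edge[node] = t - t0
        tips[node] = f"t{j + 1}"
    return _prune_to_dated(root, parent, edge, tips, n_tips)


def _prune_to_dated(
    root: int,
    parent: Dict[int, int],
    edge: Dict[int, float],
    tips: Dict[int, str],
    n_tips: int,
) -> Optional[DatedTree]:
    """Drop extinct lineages, suppress unary nodes, build a DatedTree."""
    children: Dict[int, List[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    keep: Dict[int, bool] = {}

    def mark(n: int) -> bool:
        if n in tips:
            keep[n] = True
            return True
        any_kept = False
        for c in children.get(n, []):
            if mark(c):
                any_kept = True
        keep[n] = any_kept
        return any_kept

    mark(root)
    if sum(1 for n in tips if keep.get(n)) != n_tips:
        return None

    new_parent: Dict[int, int] = {}
    new_edge: Dict[int, float] = {}
    label: Dict[int, str] = {}

    def build(n: int, acc_len: float, anc: Optional[int]) -> None:
        kids = [c for c in children.get(n, []) if keep.get(c)]
        if n in tips:
            new_parent[n] = anc
            new_edge[n] = acc_len
            label[n] = tips[n]
            return
        if len(kids) == 1:
            build(kids[0], acc_len + edge[kids[0]], anc)
            return
        if anc is not None:
            new_parent[n] = anc
            new_edge[n] = acc_len
        for c in kids:
            build(c, edge[c], n)

    top = root
    # descend through unary chain at the root
    while True:
        kids = [c for c in children.get(top, []) if keep.get(c)]
        if len(kids) == 1 and top not in tips:
            top = kids[0]
        else:
            break
    for c in [c for c in children.get(top, []) if keep.get(c)]:
        build(c, edge[c], top)
    if top not in new_parent and not [c for c in children.get(top, []) if keep.get(c)]:
        return None
    return DatedTree.from_parent_map(new_parent, new_edge, label)


# ------------------------------------------------------------- Mk characters

def sim_mk_characters(
    tree: DatedTree, k: int, q: float, n_chars: int, seed: int = 0
) -> List[CharacterColumn]:
    """Forward-simulate unordered k-state characters under Mk1 on a dated tree.

    Root states are drawn from the uniform (stationary) prior and propagated
    down every edge with the closed-form transition matrix.
    """
    rng = np.random.default_rng(seed)
    states: Dict[int, np.ndarray] = {
        tree.root: rng.integers(0, k, size=n_chars)
    }
    for node in tree.nodes():
        for c in tree.children.get(node, []):
            p = mk_transition(q, tree.edge_length[c], k) if q > 0 else np.eye(k)
            cum = p.cumsum(axis=1)
            u = rng.random(n_chars)
            parent_states = states[node]
            states[c] = (u[:, None] > cum[parent_states]).sum(axis=1)
    cols = []
    tip_nodes = tree.tips()
    for j in range(n_chars):
        cols.append(
            CharacterColumn(
                states={tree.label[t]: int(states[t][j]) for t in tip_nodes}, k=k
            )
        )
    return cols


# ------------------------------------------------------------- Koppen worlds

@dataclass(frozen=True)
class PatchSpec:
    """Rectangular patch of one climate class painted onto the mosaic grid
    (cell-index coordinates, half-open)."""

    koppen_class: str
    ix0: int
    iy0: int
    ix1: int
    iy1: int


@dataclass(frozen=True)
class SpeciesRangeSpec:
    """A species range: 2-D Gaussian cloud of occurrence records."""

    species: str
    center_lon: float
    center_lat: float
    sd_deg: float
    n_records: int
    biomes: FrozenSet[str] = frozenset({"TBMF"})


def sim_koppen_world(
    patches: Sequence[PatchSpec],
    species: Sequence[SpeciesRangeSpec],
    n_lon: int = 60,
    n_lat: int = 40,
    lon_min: float = 0.0,
    lat_min: float = 30.0,
    resolution_arcmin: float = 5.0,
    background: str = "Cfb",
    seed: int = 0,
) -> Tuple[KoppenGrid, pd.DataFrame, Dict[str, Set[str]]]:
    """Mosaic climate grid + clustered occurrences + biome memberships.

    Patches are painted in order over the background class.  Occurrence
    points are Gaussian around each species' centre, redrawn until they land
    inside the grid; a centre outside the grid is an error.
    """
    classes = np.full((n_lat, n_lon), background, dtype=object)
    for p in patches:
        classes[p.iy0 : p.iy1, p.ix0 : p.ix1] = p.koppen_class
    grid = KoppenGrid(
        lon_min=lon_min, lat_min=lat_min,
        resolution_arcmin=resolution_arcmin, classes=classes,
    )
    rng = np.random.default_rng(seed)
    rows = []
    biomes: Dict[str, Set[str]] = {}
    for sp in species:
        if grid.cell_index(sp.center_lon, sp.center_lat) is None:
            raise ValueError(f"{sp.species}: range centre outside grid extent")
        bad = set(sp.biomes) - BIOME_CODES
        if bad:
            raise ValueError(f"{sp.species}: unknown biome code(s) {sorted(bad)}")
        biomes[sp.species] = set(sp.biomes)
        got = 0
        while got < sp.n_records:
            draw = rng.normal(
                loc=(sp.center_lon, sp.center_lat),
                scale=sp.sd_deg,
                size=(sp.n_records - got, 2),
            )
            ok = (
                (draw[:, 0] >= grid.lon_min) & (draw[:, 0] <= grid.lon_max)
                & (draw[:, 1] >= grid.lat_min) & (draw[:, 1] <= grid.lat_max)
            )
            for lon, lat in draw[ok]:
                rows.append((sp.species, float(lon), float(lat)))
            got += int(ok.sum())
    occ = pd.DataFrame(rows, columns=["species", "lon", "lat"])
    return grid, occ, biomes


# ----------------------------------------------------------------- D-test loci

def sim_quartet_sites(
    taxa: Tuple[str, str, str, str],
    n_loci: int,
    sites_per_locus: int,
    p_abba: Optional[float] = None,
    p_baba: Optional[float] = None,
    p0: float = 0.02,
    gamma: float = 0.0,
    seed: int = 0,
) -> QuartetData:
    """Multinomial ABBA/BABA site patterns with an optional admixture signal.

    Either give explicit ``p_abba``/``p_baba``, or use admixture mode:
    p_ABBA = p0 + gamma * delta (delta = 2/15, so gamma = 0.3 plants
    E[D] = 0.5 over the p0 = 0.02 background), p_BABA = p0.  All remaining
    sites are uninformative (all-ancestral).
    """
    if p_abba is None and p_baba is None:
        p_abba = p0 + gamma * GAMMA_DELTA
        p_baba = p0
    if p_abba is None or p_baba is None:
        raise ValueError("give both p_abba and p_baba, or neither")
    if p_abba < 0 or p_baba < 0 or p_abba + p_baba > 1:
        raise ValueError("pattern probabilities must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(
        sites_per_locus, [p_abba, p_baba, 1.0 - p_abba - p_baba], size=n_loci
    )
    patterns = np.array([ABBA, BABA, UNINFORMATIVE], dtype=np.int8)
    loci = [
        np.repeat(patterns, counts[i], axis=0) for i in range(n_loci)
    ]
    return QuartetData(taxa=taxa, loci=loci)


# -------------------------------------------------------------------- fossils

def sim_fossils(
    tree: DatedTree,
    n_fossils: int,
    k: int = 5,
    state_probs: Optional[Sequence[float]] = None,
    p_unassignable: float = 0.0,
    seed: int = 0,
    label_prefix: str = "fossil",
) -> List[FossilSpec]:
    """Random fossil specs that satisfy the grafting preconditions by construction.

    Each fossil anchors to a uniformly chosen non-root branch; its oldest age
    is uniform on the open age interval of that branch, its youngest age
    uniform on [0, oldest]; its state is drawn from ``state_probs`` (uniform
    over k by default).  A fraction ``p_unassignable`` is marked
    non-assignable ("unconnected stars").
    """
    rng = np.random.default_rng(seed)
    probs = (
        np.full(k, 1.0 / k) if state_probs is None else np.asarray(state_probs, float)
    )
    if probs.shape != (k,) or abs(probs.sum() - 1) > 1e-9:
        raise ValueError("state_probs must be length k and sum to 1")
    branches = [n for n in tree.nodes() if n != tree.root]
    specs = []
    for i in range(n_fossils):
        node = branches[rng.integers(len(branches))]
        low = tree.age[node]
        high = tree.age[tree.parent[node]]
        while True:  # open interval; reject degenerate endpoints
            oldest = float(rng.uniform(low, high))
            if low < oldest < high:
                break
        youngest = float(rng.uniform(0.0, oldest))
        specs.append(
            FossilSpec(
                label=f"{label_prefix}_{i + 1:03d}",
                anchor=tree.clade_tips(node),
                oldest_age=oldest,
                youngest_age=youngest,
                state=int(rng.choice(k, p=probs)),
                assignable=bool(rng.random() >= p_unassignable),
            )
        )
    return specs


# ---------------------------------------------------------- cerris-like preset

SPECIES = [
    "Q_acutissima", "Q_chenii", "Q_variabilis",
    "Q_crenata", "Q_suber",
    "Q_brantii", "Q_ithaburensis", "Q_macrolepis",
    "Q_afares", "Q_libani", "Q_trojana",
    "Q_euboica", "Q_castaneifolia", "Q_look", "Q_cerris",
]


def cerris_like_tree() -> DatedTree:
    """Fixed 15-species dated tree shaped like the cork-oak chronogram.

    Node ages follow the study-scale reconstruction: East/West split in the
    late Eocene (36.7 Ma), western crown radiation in the late Oligocene
    (24.3 Ma), the Mediterranean subsections diverging through the Miocene,
    and the youngest sister pairs in the Pleistocene.
    """
    from .trees import parse_tree

    east = "(Q_chenii:13.1,(Q_acutissima:6.8,Q_variabilis:6.8):6.3):23.6"
    suber = "(Q_crenata:10,Q_suber:10):14.3"
    aegilops = "(Q_ithaburensis:13,(Q_macrolepis:2.4,Q_brantii:2.4):10.6):6.9"
    libani = "(Q_afares:10,(Q_trojana:1.8,Q_libani:1.8):8.2):3.5"
    cerris_ss = "(Q_euboica:10,(Q_castaneifolia:8,(Q_look:5,Q_cerris:5):3):2):3.5"
    core = f"({libani},{cerris_ss}):6.4"
    west = f"({suber},({aegilops},{core}):4.4):12.4"
    return parse_tree(f"({east},{west});")


def cerris_like_niche_states() -> Dict[str, int]:
    """Five-state climate-niche character scored for the 15 extant species
    (0 Moist-Subtropical ... 4 Full-Mediterranean)."""
    return {
        "Q_acutissima": 1, "Q_chenii": 0, "Q_variabilis": 1,
        "Q_crenata": 2, "Q_suber": 4,
        "Q_brantii": 3, "Q_ithaburensis": 4, "Q_macrolepis": 4,
        "Q_afares": 4, "Q_libani": 3, "Q_trojana": 4,
        "Q_euboica": 4, "Q_castaneifolia": 3, "Q_look": 4, "Q_cerris": 3,
    }


# Emulated per-species Köppen signatures.  Class fractions follow the listed
# climate types of each species (representative types >= 10 %, parenthetical
# types < 10 %); where the listed types and the verbal category disagree
# (notably Q. crenata, summarized as Nemoral despite a summer-dry listing)
# the fractions follow the category, keeping the minor classes below the
# representativeness threshold.
_PROFILES: Dict[str, Dict[str, float]] = {
    "Q_acutissima": {"Cfa": 0.45, "Cwa": 0.25, "Dwa": 0.10, "Dfa": 0.08, "Aw": 0.03, "BSk": 0.09},
    "Q_chenii": {"Cfa": 1.0},
    "Q_variabilis": {"Cfa": 0.35, "Cwa": 0.25, "Cwb": 0.12, "Dwa": 0.14, "Dfa": 0.06, "BSk": 0.08},
    "Q_crenata": {"Cfb": 0.54, "Cfa": 0.39, "Csa": 0.05, "Csb": 0.02},
    "Q_suber": {"Csa": 0.62, "Csb": 0.24, "Cfb": 0.09, "BSk": 0.05},
    "Q_brantii": {"Csa": 0.55, "Dsa": 0.20, "BSk": 0.15, "Csb": 0.10},
    "Q_ithaburensis": {"Csa": 0.72, "Csb": 0.16, "BSk": 0.07, "BWk": 0.05},
    "Q_macrolepis": {"Csa": 0.60, "Csb": 0.31, "Cfa": 0.09},
    "Q_afares": {"Csa": 0.68, "Csb": 0.32},
    "Q_libani": {"Csa": 0.40, "Csb": 0.18, "Dsa": 0.17, "Dsb": 0.15, "BSk": 0.10},
    "Q_trojana": {"Csa": 0.52, "Csb": 0.34, "Cfb": 0.08, "Dsb": 0.06},
    "Q_euboica": {"Csa": 1.0},
    "Q_castaneifolia": {"Csa": 0.55, "Dsa": 0.13, "Cfa": 0.22, "Cfb": 0.10},
    "Q_look": {"Csa": 0.85, "Csb": 0.15},
    "Q_cerris": {"Cfb": 0.38, "Csa": 0.27, "Csb": 0.16, "Dfb": 0.11, "Dsb": 0.08},
}

_BIOMES: Dict[str, FrozenSet[str]] = {
    "Q_acutissima": frozenset({"TBMF", "TSMBF"}),
    "Q_chenii": frozenset({"TBMF", "TSMBF"}),
    "Q_variabilis": frozenset({"TBMF", "TSMBF"}),
    "Q_crenata": frozenset({"TBMF"}),
    "Q_suber": frozenset({"MFWS"}),
    "Q_brantii": frozenset({"MFWS", "TBMF", "TGSS"}),
    "Q_ithaburensis": frozenset({"MFWS"}),
    "Q_macrolepis": frozenset({"MFWS"}),
    "Q_afares": frozenset({"MFWS", "TCF"}),
    "Q_libani": frozenset({"MFWS", "TBMF", "TGSS"}),
    "Q_trojana": frozenset({"TBMF", "MFWS"}),
    "Q_euboica": frozenset({"MFWS"}),
    "Q_castaneifolia": frozenset({"TBMF"}),
    "Q_look": frozenset({"MFWS"}),
    "Q_cerris": frozenset({"TBMF", "MFWS"}),
}


def cerris_like_profiles() -> Dict[str, KoppenProfile]:
    """Emulated Köppen profiles for the 15 species (exact fractions)."""
    return {
        sp: KoppenProfile(species=sp, fractions=dict(fr), n_cells=100)
        for sp, fr in _PROFILES.items()
    }


def cerris_like_biomes() -> Dict[str, Set[str]]:
    return {sp: set(b) for sp, b in _BIOMES.items()}


def cerris_like_leaf_matrix():
    """12-trait leaf matrix (11 binary + 1 ternary) for the 15 species.

    Characters summarize texture (evergreen/leathery), lamina size class,
    tooth development, bristle-like tooth tips, lobing and related leaf-form
    features; the final ternary character encodes overall tooth complexity.
    States are synthetic but patterned on the leaf-type gradients described
    for the group (East Asian bristle-toothed type, the kraskinensis-crenata
    type shared by early-diverging western species, and the reduced
    Mediterranean types).
    """
    from .nnet import TraitMatrix

    rows = {
        #                  texture leath size teeth brist lobed everg reduc mucro cusp marg  complexity(0,1,2)
        "Q_acutissima":    [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 0],
        "Q_chenii":        [0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0],
        "Q_variabilis":    [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 0],
        "Q_crenata":       [0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 1, 1],
        "Q_suber":         [1, 1, 0, 0, 0, 0, 1, 1, 0, 1, 0, 1],
        "Q_brantii":       [0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 2],
        "Q_ithaburensis":  [0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 1, 2],
        "Q_macrolepis":    [0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 2],
        "Q_afares":        [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1],
        "Q_libani":        [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 0],
        "Q_trojana":       [0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1],
        "Q_euboica":       [0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 1, 1],
        "Q_castaneifolia": [0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1],
        "Q_look":          [0, 1, 0, 1, 0, 0, 0, 0, 0, 1, 1, 2],
        "Q_cerris":        [0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 2],
    }
    taxa = list(rows)
    data = np.array([rows[t] for t in taxa], dtype=int)
    arity = np.array([2] * 11 + [3])
    return TraitMatrix(taxa=taxa, data=data, arity=arity)


def cerris_like_fossils(seed: int = 0, n_fossils: int = 47) -> List[FossilSpec]:
    """~47 fossils on the preset tree; roughly one in eight is unassignable.

    Fossil niche states are coherent in time and lineage, as in the real
    record: Palaeogene fossils are scored Moist-Subtropical/Meridio-Nemoral
    (the summer-dry biomes did not yet exist), Miocene fossils
    Meridio-Nemoral/Nemoral, and Plio-Pleistocene fossils track the modal
    state of their anchor clade's extant species.  Independent uniform state
    draws would make the combined character so homoplastic that the
    single-rate likelihood saturates and the reconstruction degenerates.
    """
    tree = cerris_like_tree()
    states = cerris_like_niche_states()
    rng = np.random.default_rng(seed)
    branches = [n for n in tree.nodes() if n != tree.root]
    specs: List[FossilSpec] = []
    for i in range(n_fossils):
        node = branches[rng.integers(len(branches))]
        low, high = tree.age[node], tree.age[tree.parent[node]]
        while True:
            oldest = float(rng.uniform(low, high))
            if low < oldest < high:
                break
        width = float(rng.uniform(0.5, 3.0))
        youngest = max(0.0, oldest - width)
        clade = tree.clade_tips(node)
        modal = int(np.bincount([states[t] for t in clade]).argmax())
        if oldest > 25.0:
            st = int(rng.choice([0, 1], p=[0.4, 0.6]))
        elif oldest > 12.0:
            st = int(rng.choice([1, 2], p=[0.4, 0.6]))
        elif oldest > 5.0:
            st = 2 if rng.random() < 0.4 else min(modal, 3)
        else:
            st = modal
        specs.append(
            FossilSpec(
                label=f"fossil_{i + 1:03d}",
                anchor=clade,
                oldest_age=oldest,
                youngest_age=youngest,
                state=st,
                assignable=bool(rng.random() >= 0.125),
            )
        )
    return specs


def cerris_like_world(
    n_records: int = 600, seed: int = 0
) -> Tuple[KoppenGrid, pd.DataFrame, Dict[str, Set[str]]]:
    """Synthetic occurrence world for the 15-species preset.

    The grid is a mosaic of one longitudinal stripe per climate class that
    appears in any emulated signature; each species' records are placed by
    first drawing a class from its signature fractions and then a uniform
    point inside that class's stripe.  Computed grid-weighted profiles
    therefore approximate the emulated signatures up to cell-occupancy
    sampling noise.
    """
    classes = sorted({c for fr in _PROFILES.values() for c in fr})
    stripe_w, n_lat = 40, 60
    n_lon = stripe_w * len(classes)
    arr = np.empty((n_lat, n_lon), dtype=object)
    for s, cls in enumerate(classes):
        arr[:, s * stripe_w : (s + 1) * stripe_w] = cls
    res = 5.0
    grid = KoppenGrid(lon_min=0.0, lat_min=30.0, resolution_arcmin=res, classes=arr)
    rng = np.random.default_rng(seed)
    rows = []
    for sp in SPECIES:
        fr = _PROFILES[sp]
        names = sorted(fr)
        draws = rng.choice(len(names), size=n_records, p=[fr[c] for c in names])
        for di in draws:
            s = classes.index(names[di])
            lon = rng.uniform(grid.lon_min + s * stripe_w * grid.res_deg,
                              grid.lon_min + (s + 1) * stripe_w * grid.res_deg)
            lat = rng.uniform(grid.lat_min, grid.lat_max)
            rows.append((sp, float(lon), float(lat)))
    occ = pd.DataFrame(rows, columns=["species", "lon", "lat"])
    return grid, occ, cerris_like_biomes()


def suber_like_scenario() -> Tuple[DatedTree, List[FossilSpec], Dict[str, int]]:
    """Constructed case where fossils flip an ancestral-niche reconstruction.

    A two-species Mediterranean clade (states 4) with long terminal branches
    sits on a long stem within an otherwise Nemoral (state 2) tree.  Three
    stem fossils scored Nemoral sit just above the clade MRCA.  Extant-only
    reconstruction makes the MRCA Mediterranean; adding the fossils flips
    the MRCA (and the stem's shadow nodes) to Nemoral — the qualitative
    signature of fossil-informed reconstruction in this group.
    """
    from .trees import parse_tree

    tree = parse_tree(
        "((S1:14,S2:14):6,(X1:14,(X2:10,X3:10):4):6);"
    )
    tip_states = {"S1": 4, "S2": 4, "X1": 2, "X2": 2, "X3": 2}
    anchor = frozenset({"S1", "S2"})
    fossils = [
        FossilSpec("fossilA", anchor, 19.0, 18.0, state=2),
        FossilSpec("fossilB", anchor, 17.0, 16.0, state=2),
        FossilSpec("fossilC", anchor, 15.0, 14.5, state=2),
    ]
    return tree, fossils, tip_states
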