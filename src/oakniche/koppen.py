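"""Köppen climate profiling of species occurrences and five-state niche coding.

A *Köppen profile* summarizes a species' climatic niche as the proportional
coverage of Köppen–Geiger climate classes over the grid cells its occurrence
records occupy.  Each occupied cell counts once, however many records fall in
it ("grid-weighted", unique-cell counting), so dense collecting in one place
does not bias the profile.  Profiles plus terrestrial-biome memberships are
then binned into five ordinal niche categories spanning the gradient from
fully humid subtropical forests to summer-drought Mediterranean specialists:

    0  Moist-Subtropical   1  Meridio-Nemoral   2  Nemoral
    3  Meridional          4  Full-Mediterranean

The binning is a deterministic rule cascade over (a) the biome set, (b) the
summer-dry fraction of the profile (total weight on Cs*/Ds* classes), (c) the
dominant class, and (d) the winter-cold summer-dry fraction (Ds* plus BSk).
All thresholds live in :class:`NicheRules` and default to the inclusive 10 %
used for "representative" classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "KOPPEN_CLASSES",
    "BIOME_CODES",
    "KoppenGrid",
    "KoppenProfile",
    "NicheCategory",
    "NicheRules",
    "snap_to_cells",
    "koppen_profile",
    "representative_types",
    "classify_niche",
    "read_occurrences",
    "read_grid",
    "write_grid",
    "read_biomes",
]

logger = logging.getLogger(__name__)

KOPPEN_CLASSES: FrozenSet[str] = frozenset(
    {
        "Af", "Am", "Aw",
        "BWh", "BWk", "BSh", "BSk",
        "Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc", "Cfa", "Cfb", "Cfc",
        "Dsa", "Dsb", "Dsc", "Dsd", "Dwa", "Dwb", "Dwc", "Dwd",
        "Dfa", "Dfb", "Dfc", "Dfd",
        "ET", "EF",
    }
)

BIOME_CODES: FrozenSet[str] = frozenset({"TSMBF", "TBMF", "TCF", "MFWS", "TGSS"})


class NicheCategory(IntEnum):
    MOIST_SUBTROPICAL = 0
    MERIDIO_NEMORAL = 1
    NEMORAL = 2
    MERIDIONAL = 3
    FULL_MEDITERRANEAN = 4

    @property
    def label(self) -> str:
        return {
            0: "Moist-Subtropical",
            1: "Meridio-Nemoral",
            2: "Nemoral",
            3: "Meridional",
            4: "Full-Mediterranean",
        }[int(self)]


@dataclass
class KoppenGrid:
    """Regular lon/lat grid of Köppen classes.

    Cells are half-open rectangles ``[west, east) x [south, north)`` of width
    ``resolution_arcmin``; a record exactly on the global east/north edge
    joins the last cell so the stated extent is fully covered.  ``classes``
    is indexed ``[lat_index, lon_index]`` from the south-west corner.
    """

    lon_min: float
    lat_min: float
    resolution_arcmin: float
    classes: np.ndarray  # (n_lat, n_lon) array of class strings

    def __post_init__(self):
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        self.classes = np.asarray(self.classes)
        bad = set(self.classes.ravel()) - KOPPEN_CLASSES
        if bad:
            raise ValueError(f"unknown climate class(es): {sorted(bad)}")

    @property
    def res_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def n_lat(self) -> int:
        return self.classes.shape[0]

    @property
    def n_lon(self) -> int:
        return self.classes.shape[1]

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.res_deg

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.res_deg

    def cell_index(self, lon: float, lat: float) -> Optional[Tuple[int, int]]:
        """(lon_index, lat_index) of the cell containing a point, or None."""
        if not (self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max):
            return None
        ix = int(math.floor((lon - self.lon_min) / self.res_deg))
        iy = int(math.floor((lat - self.lat_min) / self.res_deg))
        ix = min(ix, self.n_lon - 1)  # east/north global edge joins last cell
        iy = min(iy, self.n_lat - 1)
        return ix, iy

    def cell_center(self, ix: int, iy: int) -> Tuple[float, float]:
        return (
            self.lon_min + (ix + 0.5) * self.res_deg,
            self.lat_min + (iy + 0.5) * self.res_deg,
        )

    def cell_class(self, ix: int, iy: int) -> str:
        return str(self.classes[iy, ix])


@dataclass
class KoppenProfile:
    """Per-species climate signature: class -> fraction of occupied cells."""

    species: str
    fractions: Dict[str, float]
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError(f"{self.species}: profile needs >= 1 occupied cell")
        tot = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or abs(tot - 1.0) > 1e-9:
            raise ValueError(f"{self.species}: fractions must be >= 0 and sum to 1")

    def fraction(self, prefix_or_class: str) -> float:
        """Total weight of one class, or of all classes sharing a prefix
        (``"Cs"`` sums Csa+Csb+Csc)."""
        if prefix_or_class in self.fractions:
            return self.fractions[prefix_or_class]
        return sum(v for c, v in self.fractions.items() if c.startswith(prefix_or_class))

    @property
    def dominant(self) -> str:
        return max(self.fractions.items(), key=lambda kv: (kv[1], kv[0]))[0]

    @property
    def summer_dry(self) -> float:
        return self.fraction("Cs") + self.fraction("Ds")

    @property
    def winter_cold_summer_dry(self) -> float:
        return self.fraction("Ds") + self.fraction("BSk")


def snap_to_cells(
    occurrences: pd.DataFrame, grid: KoppenGrid
) -> Dict[str, Set[Tuple[int, int]]]:
    """Unique occupied grid cells per species.

    ``occurrences`` needs columns ``species``, ``lon``, ``lat``.  Records
    outside the grid extent are dropped with a logged count; duplicates
    within a cell collapse.
    """
    cells: Dict[str, Set[Tuple[int, int]]] = {}
    dropped: Dict[str, int] = {}
    for sp, lon, lat in occurrences[["species", "lon", "lat"]].itertuples(index=False):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise ValueError(f"coordinate out of range: ({lon}, {lat})")
        idx = grid.cell_index(float(lon), float(lat))
        if idx is None:
            dropped[sp] = dropped.get(sp, 0) + 1
            continue
        cells.setdefault(sp, set()).add(idx)
    for sp, n in sorted(dropped.items()):
        logger.warning("%s: %d record(s) outside grid coverage dropped", sp, n)
    return cells


def koppen_profile(
    species: str, cells: Set[Tuple[int, int]], grid: KoppenGrid
) -> KoppenProfile:
    """Grid-weighted Köppen profile from a species' occupied cells."""
    if not cells:
        raise ValueError(f"{species}: empty range (zero occupied cells)")
    counts: Dict[str, int] = {}
    for ix, iy in cells:
        c = grid.cell_class(ix, iy)
        counts[c] = counts.get(c, 0) + 1
    n = len(cells)
    return KoppenProfile(
        species=species,
        fractions={c: cnt / n for c, cnt in sorted(counts.items())},
        n_cells=n,
    )


def representative_types(profile: KoppenProfile, threshold: float = 0.10) -> List[str]:
    """Classes covering at least ``threshold`` of the occupied cells,
    sorted by descending fraction (dominant first; ties by class name)."""
    keep = [(c, f) for c, f in profile.fractions.items() if f >= threshold]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    return [c for c, _ in keep]


@dataclass(frozen=True)
class NicheRules:
    """Thresholds of the category cascade (inclusive comparisons)."""

    summer_dry_threshold: float = 0.10
    winter_cold_threshold: float = 0.10
    moist_dominants: FrozenSet[str] = frozenset({"Cfa", "Cwa"})


def classify_niche(
    profile: KoppenProfile,
    biomes: Set[str],
    rules: NicheRules = NicheRules(),
) -> NicheCategory:
    """Bin one species into the five-state niche category.

    The cascade is evaluated in order; rule 4 (Full-Mediterranean) is the
    residual, so the function is total on valid inputs:

    0. biome set within {TSMBF, TBMF} with TSMBF present, essentially no
       summer-dry coverage, and a moist-subtropical dominant class (Cfa/Cwa);
    1. straddles the TSMBF/TBMF ecotone (both present), no summer drought;
    2. temperate-forest biomes only (TBMF/TCF/TSMBF), no summer drought;
    3. summer drought present but the species reaches temperate/steppe/conifer
       biomes and is either not Csa-dominated or extends into winter-cold
       summer-dry climates (Ds*/BSk);
    4. otherwise: Mediterranean specialist.
    """
    if not biomes:
        raise ValueError(f"{profile.species}: empty biome set")
    bad = set(biomes) - BIOME_CODES
    if bad:
        raise ValueError(f"{profile.species}: unknown biome code(s) {sorted(bad)}")

    sdf = profile.summer_dry
    thr = rules.summer_dry_threshold
    dom = profile.dominant

    if (
        biomes <= {"TSMBF", "TBMF"}
        and "TSMBF" in biomes
        and sdf < thr
        and dom in rules.moist_dominants
    ):
        return NicheCategory.MOIST_SUBTROPICAL
    if "TSMBF" in biomes and "TBMF" in biomes and sdf < thr:
        return NicheCategory.MERIDIO_NEMORAL
    if biomes <= {"TBMF", "TCF", "TSMBF"} and sdf < thr:
        return NicheCategory.NEMORAL
    if (
        sdf >= thr
        and biomes & {"TBMF", "TGSS", "TCF"}
        and (dom != "Csa" or profile.winter_cold_summer_dry >= rules.winter_cold_threshold)
    ):
        return NicheCategory.MERIDIONAL
    return NicheCategory.FULL_MEDITERRANEAN


# ------------------------------------------------------------------- text I/O

def read_occurrences(text: str) -> pd.DataFrame:
    """Occurrence records from tab-separated text: species, lon, lat."""
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, lon, lat = line.split("\t")
        rows.append((sp, float(lon), float(lat)))
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


def write_occurrences(occ: pd.DataFrame) -> str:
    lines = ["# species\tlon\tlat"]
    for sp, lon, lat in occ[["species", "lon", "lat"]].itertuples(index=False):
        lines.append(f"{sp}\t{lon:.8f}\t{lat:.8f}")
    return "\n".join(lines) + "\n"


def write_grid(grid: KoppenGrid) -> str:
    """Grid as tabular text: a resolution header then lon_center, lat_center, class."""
    lines = [
        f"# resolution_arcmin: {grid.resolution_arcmin:g}",
        f"# origin: {grid.lon_min:.8f} {grid.lat_min:.8f}",
        "# lon_center\tlat_center\tclass",
    ]
    for iy in range(grid.n_lat):
        for ix in range(grid.n_lon):
            lon, lat = grid.cell_center(ix, iy)
            lines.append(f"{lon:.8f}\t{lat:.8f}\t{grid.cell_class(ix, iy)}")
    return "\n".join(lines) + "\n"


def read_grid(text: str) -> KoppenGrid:
    res = None
    origin = None
    cells = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "resolution_arcmin:" in line:
                res = float(line.split(":", 1)[1])
            elif "origin:" in line:
                parts = line.split(":", 1)[1].split()
                origin = (float(parts[0]), float(parts[1]))
            continue
        lon, lat, cls = line.split("\t")
        cells.append((float(lon), float(lat), cls))
    if res is None or origin is None or not cells:
        raise ValueError("grid text needs resolution and origin headers plus cells")
    res_deg = res / 60.0
    lons = sorted({c[0] for c in cells})
    lats = sorted({c[1] for c in cells})
    n_lon, n_lat = len(lons), len(lats)
    classes = np.empty((n_lat, n_lon), dtype=object)
    for lon, lat, cls in cells:
        ix = int(round((lon - origin[0]) / res_deg - 0.5))
        iy = int(round((lat - origin[1]) / res_deg - 0.5))
        classes[iy, ix] = cls
    if (classes == None).any():  # noqa: E711 — object array hole check
        raise ValueError("grid text does not cover its full extent")
    return KoppenGrid(
        lon_min=origin[0], lat_min=origin[1], resolution_arcmin=res, classes=classes
    )


def read_biomes(text: str) -> Dict[str, Set[str]]:
    """Per-species biome memberships: species <tab> codes joined by ';'."""
    out: Dict[str, Set[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, codes = line.split("\t")
        out[sp] = set(codes.split(";"))
    return out


def write_biomes(biomes: Mapping[str, Set[str]]) -> str:
    lines = ["# species\tbiomes"]
    for sp in sorted(biomes):
        lines.append(f"{sp}\t{';'.join(sorted(biomes[sp]))}")
    return "\n".join(lines) + "\n"
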