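"""Patterson's D-statistic (ABBA-BABA) with locus bootstrap.

For a four-taxon arrangement (((P1,P2),P3),O) with sites polarized against
the outgroup O (ancestral=0, derived=1), incomplete lineage sorting produces
the discordant patterns ABBA (P2 and P3 share the derived allele) and BABA
(P1 and P3 share it) at equal rates; gene flow between P3 and one ingroup
taxon skews the ratio.  The statistic is

    D = (nABBA - nBABA) / (nABBA + nBABA)

and significance comes from resampling whole loci with replacement:
Z = |D_obs| / sd(D_bootstrap).  Tests with |Z| at or above a configurable
threshold (3 by ABBA-BABA convention) are flagged as evidence of
introgression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "QuartetData",
    "DResult",
    "DTest",
    "count_patterns",
    "d_statistic",
    "bootstrap_z",
    "hypothesis_battery",
    "Z_THRESHOLD",
]

logger = logging.getLogger(__name__)

Z_THRESHOLD = 3.0


@dataclass
class QuartetData:
    """Polarized biallelic data for one four-taxon test.

    ``loci`` is a list of integer arrays of shape (n_sites, 4) with columns
    (P1, P2, P3, O); entries are 0 (ancestral), 1 (derived) or -1 (missing).
    In frequency mode entries may instead be derived-allele frequencies in
    [0, 1] (floats), with NaN for missing.
    """

    taxa: Tuple[str, str, str, str]
    loci: List[np.ndarray]

    def __post_init__(self):
        if len(self.taxa) != 4:
            raise ValueError("need exactly four taxa (P1, P2, P3, O)")
        if not self.loci:
            raise ValueError("need at least one locus")
        self.loci = [np.asarray(l) for l in self.loci]
        for l in self.loci:
            if l.ndim != 2 or l.shape[1] != 4:
                raise ValueError("each locus must be an (n_sites, 4) array")


@dataclass
class DResult:
    taxa: Tuple[str, str, str, str]
    n_abba: float
    n_baba: float
    d: Optional[float]
    z: Optional[float]
    n_loci: int
    n_boot: int
    n_dropped_sites: int = 0
    sd_zero: bool = False

    @property
    def significant(self) -> bool:
        return self.z is not None and (self.sd_zero or abs(self.z) >= Z_THRESHOLD)


def _locus_counts(locus: np.ndarray, frequency_mode: bool) -> Tuple[float, float, int]:
    """(nABBA, nBABA, n_dropped) for one locus."""
    a = np.asarray(locus, dtype=float)
    if frequency_mode:
        ok = ~np.isnan(a).any(axis=1)
        dropped = int((~ok).sum())
        p1, p2, p3, o = a[ok].T
        # polarize by outgroup frequency: derived = allele absent in O
        abba = ((1 - p1) * p2 * p3 * (1 - o)).sum()
        baba = (p1 * (1 - p2) * p3 * (1 - o)).sum()
        return float(abba), float(baba), dropped
    ok = (a >= 0).all(axis=1)
    dropped = int((~ok).sum())
    s = a[ok].astype(int)
    p1, p2, p3, o = s.T
    anc = o == 0  # sites where the outgroup carries the ancestral state
    abba = int(((p1 == 0) & (p2 == 1) & (p3 == 1) & anc).sum())
    baba = int(((p1 == 1) & (p2 == 0) & (p3 == 1) & anc).sum())
    return float(abba), float(baba), dropped


def count_patterns(
    quartet: QuartetData, frequency_mode: bool = False
) -> Tuple[float, float]:
    """Total ABBA and BABA counts over all loci (missing sites dropped)."""
    tot_a = tot_b = 0.0
    dropped = 0
    for locus in quartet.loci:
        a, b, d = _locus_counts(locus, frequency_mode)
        tot_a += a
        tot_b += b
        dropped += d
    if dropped:
        logger.info("%d site(s) with missing data dropped", dropped)
    return tot_a, tot_b


def d_statistic(n_abba: float, n_baba: float) -> Optional[float]:
    """D = (nABBA - nBABA)/(nABBA + nBABA); None when no informative sites."""
    if n_abba < 0 or n_baba < 0:
        raise ValueError("pattern counts must be non-negative")
    tot = n_abba + n_baba
    if tot == 0:
        return None
    return (n_abba - n_baba) / tot


def bootstrap_z(
    quartet: QuartetData,
    n_boot: int = 1000,
    seed: int = 0,
    frequency_mode: bool = False,
) -> DResult:
    """Observed D with a locus-bootstrap standard score.

    Loci are resampled with replacement ``n_boot`` times; Z is |D_obs|
    divided by the bootstrap standard deviation of D.  Degenerate data with
    zero bootstrap spread are flagged (``sd_zero``) rather than given an
    arbitrary Z.  Deterministic for a fixed seed.
    """
    if len(quartet.loci) < 2:
        raise ValueError("locus bootstrap needs >= 2 loci")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    per_locus = np.array(
        [_locus_counts(l, frequency_mode)[:2] for l in quartet.loci], dtype=float
    )
    dropped = sum(_locus_counts(l, frequency_mode)[2] for l in quartet.loci)
    n_abba, n_baba = per_locus.sum(axis=0)
    d_obs = d_statistic(n_abba, n_baba)

    rng = np.random.default_rng(seed)
    n_loci = per_locus.shape[0]
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    sums = per_locus[idx].sum(axis=1)  # (n_boot, 2)
    tot = sums.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_boot = np.where(tot > 0, (sums[:, 0] - sums[:, 1]) / np.where(tot > 0, tot, 1), np.nan)
    sd = float(np.nanstd(d_boot, ddof=1))

    if d_obs is None:
        z: Optional[float] = None
        sd_zero = False
    elif sd == 0.0 or np.isnan(sd):
        z = float("inf") if d_obs != 0 else 0.0
        sd_zero = True
    else:
        z = abs(d_obs) / sd
        sd_zero = False
    return DResult(
        taxa=quartet.taxa,
        n_abba=n_abba,
        n_baba=n_baba,
        d=d_obs,
        z=z,
        n_loci=n_loci,
        n_boot=n_boot,
        n_dropped_sites=dropped,
        sd_zero=sd_zero,
    )


def write_loci(quartet: QuartetData) -> str:
    """Loci as tabular text: header naming the taxa, then one line per locus
    with its site patterns ('0'/'1'/'.') joined by ';' (columns P1 P2 P3 O)."""
    lines = ["# taxa: " + "\t".join(quartet.taxa)]
    for i, locus in enumerate(quartet.loci):
        pats = [
            "".join("." if v < 0 else str(int(v)) for v in site) for site in locus
        ]
        lines.append(f"locus_{i + 1}\t{';'.join(pats)}")
    return "\n".join(lines) + "\n"


def read_loci(text: str) -> QuartetData:
    taxa = None
    loci = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "taxa:" in line:
                taxa = tuple(line.split("taxa:", 1)[1].split())
            continue
        _, pats = line.split("\t")
        arr = np.array(
            [[-1 if ch == "." else int(ch) for ch in p] for p in pats.split(";")],
            dtype=np.int8,
        )
        loci.append(arr)
    if taxa is None or len(taxa) != 4:
        raise ValueError("loci text must name four taxa in a '# taxa:' header")
    return QuartetData(taxa=taxa, loci=loci)


@dataclass(frozen=True)
class DTest:
    """A named four-taxon hypothesis (e.g. a putative hybrid origin)."""

    name: str
    p1: str
    p2: str
    p3: str
    outgroup: str


def hypothesis_battery(
    quartets: Mapping[str, QuartetData],
    tests: Sequence[DTest],
    n_boot: int = 1000,
    seed: int = 0,
    z_threshold: float = Z_THRESHOLD,
) -> pd.DataFrame:
    """Run a configured battery of D-tests and tabulate the verdicts.

    ``quartets`` maps test name -> QuartetData whose taxa must match the
    test's (P1, P2, P3, O); a mismatch or missing entry is an error.  Returns
    a DataFrame with one row per test: counts, D, Z, locus count and an
    introgression verdict at ``z_threshold``.  An empty test list yields an
    empty report.
    """
    rows = []
    for i, t in enumerate(tests):
        if t.name not in quartets:
            raise KeyError(f"no quartet data supplied for test {t.name!r}")
        qd = quartets[t.name]
        expected = (t.p1, t.p2, t.p3, t.outgroup)
        if tuple(qd.taxa) != expected:
            raise ValueError(
                f"test {t.name!r}: quartet taxa {qd.taxa} do not match {expected}"
            )
        res = bootstrap_z(qd, n_boot=n_boot, seed=seed + i)
        rows.append(
            {
                "test": t.name,
                "P1": t.p1,
                "P2": t.p2,
                "P3": t.p3,
                "O": t.outgroup,
                "nABBA": res.n_abba,
                "nBABA": res.n_baba,
                "D": np.nan if res.d is None else res.d,
                "Z": np.nan if res.z is None else res.z,
                "n_loci": res.n_loci,
                "verdict": (
                    "introgression"
                    if res.z is not None and not np.isnan(res.z) and res.z >= z_threshold
                    else "ns"
                ),
            }
        )
    cols = ["test", "P1", "P2", "P3", "O", "nABBA", "nBABA", "D", "Z", "n_loci", "verdict"]
    return pd.DataFrame(rows, columns=cols)
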