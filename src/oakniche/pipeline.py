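"""End-to-end orchestration: fixtures -> profile -> classify -> graft -> asr
-> dstat -> nnet -> report.

A run is driven by one YAML config with per-stage blocks; every stage reads
and writes plain-text artifacts in the workspace directory, so any stage can
be re-run (or skipped) against prebuilt inputs.  A run manifest (JSON) with
the config hash, seed, package version and SHA-256 digest of every artifact
is written last; reruns under the same config are byte-identical, manifest
included.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dstat import DTest, QuartetData, hypothesis_battery, read_loci, write_loci
from .grafting import graft_all, read_fossil_specs, write_fossil_specs
from .koppen import (
    NicheRules,
    classify_niche,
    koppen_profile,
    read_biomes,
    read_grid,
    read_occurrences,
    representative_types,
    snap_to_cells,
    write_biomes,
    write_grid,
    write_occurrences,
    KoppenProfile,
)
from .mk import AsrResult, asr_two_trees, match_nodes
from .nnet import hamming, neighbor_net, read_trait_matrix, write_splits_nexus, write_trait_matrix
from .trees import DatedTree, parse_tree
from . import simulate

__all__ = ["run_pipeline", "compare_asr_report", "DEFAULT_CONFIG", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ["fixtures", "profile", "classify", "graft", "asr", "dstat", "nnet", "report"]

DEFAULT_CONFIG: Dict = {
    "seed": 1,
    "stages": STAGES,
    "fixtures": {"preset": "cerris_like", "n_records": 600},
    "classify": {"summer_dry_threshold": 0.10, "winter_cold_threshold": 0.10},
    "asr": {"k": 5, "q_max": 100.0},
    "dstat": {
        "n_loci": 200,
        "sites_per_locus": 250,
        "n_boot": 500,
        "p0": 0.02,
        "z_threshold": 3.0,
        "tests": [
            {"name": "afares_origin", "p1": "Q_cerris", "p2": "Q_afares", "p3": "Q_suber", "o": "OUT", "gamma": 0.0},
            {"name": "crenata_origin", "p1": "Q_cerris", "p2": "Q_crenata", "p3": "Q_suber", "o": "OUT", "gamma": 0.0},
            {"name": "cerris_afares", "p1": "Q_trojana", "p2": "Q_afares", "p3": "Q_cerris", "o": "OUT", "gamma": 0.0},
            {"name": "aegilops_suber_libani", "p1": "Q_macrolepis", "p2": "Q_suber", "p3": "Q_libani", "o": "OUT", "gamma": 0.0},
            {"name": "ilex_suber", "p1": "Q_crenata", "p2": "Q_suber", "p3": "ILEX", "o": "OUT", "gamma": 0.0},
        ],
    },
    "nnet": {"eps": 1e-8},
}


def load_config(path: Optional[str] = None, overrides: Optional[Mapping] = None) -> Dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, dict(overrides))
    return cfg


def _deep_update(base: Dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    logger.info("STAGE-OUT %s (%d bytes)", path.name, len(text))


# -------------------------------------------------------------------- stages

def _stage_fixtures(cfg: Dict, ws: Path) -> None:
    seed = int(cfg["seed"])
    sub = np.random.SeedSequence(seed).spawn(4)
    fcfg = cfg["fixtures"]
    if fcfg.get("preset", "cerris_like") != "cerris_like":
        raise ValueError(f"unknown preset {fcfg['preset']!r}")
    tree = simulate.cerris_like_tree()
    _write(ws / "tree.nwk", tree.to_newick())
    states = simulate.cerris_like_niche_states()
    _write(
        ws / "niche_states.tsv",
        "# species\tstate\n"
        + "".join(f"{sp}\t{st}\n" for sp, st in sorted(states.items())),
    )
    fossils = simulate.cerris_like_fossils(seed=int(sub[0].generate_state(1)[0] % 2**31))
    _write(ws / "fossils.tsv", write_fossil_specs(fossils))
    grid, occ, biomes = simulate.cerris_like_world(
        n_records=int(fcfg.get("n_records", 600)),
        seed=int(sub[1].generate_state(1)[0] % 2**31),
    )
    _write(ws / "grid.tsv", write_grid(grid))
    _write(ws / "occurrences.tsv", write_occurrences(occ))
    _write(ws / "biomes.tsv", write_biomes(biomes))
    _write(ws / "leaf_matrix.tsv", write_trait_matrix(simulate.cerris_like_leaf_matrix()))
    # one loci file per configured D-test
    dcfg = cfg["dstat"]
    loci_seeds = np.random.SeedSequence(seed).spawn(4)[3].spawn(len(dcfg["tests"]))
    for t, ss in zip(dcfg["tests"], loci_seeds):
        qd = simulate.sim_quartet_sites(
            (t["p1"], t["p2"], t["p3"], t["o"]),
            n_loci=int(dcfg["n_loci"]),
            sites_per_locus=int(dcfg["sites_per_locus"]),
            p0=float(dcfg["p0"]),
            gamma=float(t.get("gamma", 0.0)),
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        _write(ws / f"loci_{t['name']}.tsv", write_loci(qd))


def _stage_profile(cfg: Dict, ws: Path) -> None:
    grid = read_grid((ws / "grid.tsv").read_text())
    occ = read_occurrences((ws / "occurrences.tsv").read_text())
    cells = snap_to_cells(occ, grid)
    lines = ["# species\tclass\tfraction\tn_cells"]
    for sp in sorted(cells):
        prof = koppen_profile(sp, cells[sp], grid)
        for cls, fr in sorted(prof.fractions.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"{sp}\t{cls}\t{fr:.10g}\t{prof.n_cells}")
    _write(ws / "profiles.tsv", "\n".join(lines) + "\n")


def _read_profiles(ws: Path) -> Dict[str, KoppenProfile]:
    profs: Dict[str, Dict[str, float]] = {}
    ncells: Dict[str, int] = {}
    for line in (ws / "profiles.tsv").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, cls, fr, n = line.split("\t")
        profs.setdefault(sp, {})[cls] = float(fr)
        ncells[sp] = int(n)
    return {
        sp: KoppenProfile(species=sp, fractions=fr, n_cells=ncells[sp])
        for sp, fr in profs.items()
    }


def _stage_classify(cfg: Dict, ws: Path) -> None:
    profiles = _read_profiles(ws)
    biomes = read_biomes((ws / "biomes.tsv").read_text())
    ccfg = cfg.get("classify", {})
    rules = NicheRules(
        summer_dry_threshold=float(ccfg.get("summer_dry_threshold", 0.10)),
        winter_cold_threshold=float(ccfg.get("winter_cold_threshold", 0.10)),
    )
    lines = ["# species\tcategory_code\tcategory_label\trepresentative_types"]
    for sp in sorted(profiles):
        cat = classify_niche(profiles[sp], biomes[sp], rules)
        reps = ",".join(representative_types(profiles[sp]))
        lines.append(f"{sp}\t{int(cat)}\t{cat.label}\t{reps}")
    _write(ws / "categories.tsv", "\n".join(lines) + "\n")


def _stage_graft(cfg: Dict, ws: Path) -> None:
    tree = parse_tree((ws / "tree.nwk").read_text())
    fossils = read_fossil_specs((ws / "fossils.tsv").read_text())
    grafted = graft_all(tree, fossils)
    _write(ws / "tree_grafted.nwk", grafted.to_newick())
    lines = ["# node_id\tlabel\tage"]
    for nid, lab, age in grafted.age_table():
        lines.append(f"{nid}\t{lab}\t{age:.10g}")
    _write(ws / "tree_grafted_ages.tsv", "\n".join(lines) + "\n")


def _read_states(path: Path) -> Dict[str, int]:
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, st = line.split("\t")
        out[sp] = int(st)
    return out


def _asr_table(res: AsrResult, tree: DatedTree, k: int) -> List[str]:
    lines = []
    for node in sorted(res.node_probs, key=lambda n: (-tree.age[n], n)):
        fp = ",".join(sorted(res.fingerprint[node]))
        probs = "\t".join(f"{p:.10g}" for p in res.node_probs[node])
        lines.append(f"{node}\t{tree.age[node]:.10g}\t{fp}\t{probs}")
    return lines


def _stage_asr(cfg: Dict, ws: Path) -> None:
    k = int(cfg["asr"].get("k", 5))
    tree = parse_tree((ws / "tree.nwk").read_text())
    grafted = parse_tree((ws / "tree_grafted.nwk").read_text())
    states = _read_states(ws / "niche_states.tsv")
    fossils = read_fossil_specs((ws / "fossils.tsv").read_text())
    fossil_states = {f.label: f.state for f in fossils if f.assignable}
    ext, gra = asr_two_trees(
        tree, grafted, states, fossil_states, k=k,
        q=cfg["asr"].get("q"), q_max=float(cfg["asr"].get("q_max", 100.0)),
    )
    header = "# node_id\tage\tclade\t" + "\t".join(f"p{s}" for s in range(k))
    for name, res, tr in (("asr_extant.tsv", ext, tree), ("asr_grafted.tsv", gra, grafted)):
        meta = f"# q={res.q:.10g} loglik={res.loglik:.10g} boundary={int(res.q_at_boundary)}"
        _write(ws / name, "\n".join([meta, header] + _asr_table(res, tr, k)) + "\n")


def _stage_dstat(cfg: Dict, ws: Path) -> None:
    dcfg = cfg["dstat"]
    tests = [
        DTest(t["name"], t["p1"], t["p2"], t["p3"], t["o"]) for t in dcfg["tests"]
    ]
    quartets = {
        t.name: read_loci((ws / f"loci_{t.name}.tsv").read_text()) for t in tests
    }
    report = hypothesis_battery(
        quartets, tests,
        n_boot=int(dcfg.get("n_boot", 500)),
        seed=int(cfg["seed"]),
        z_threshold=float(dcfg.get("z_threshold", 3.0)),
    )
    _write(ws / "dstat.tsv", report.to_csv(sep="\t", index=False, float_format="%.10g"))


def _stage_nnet(cfg: Dict, ws: Path) -> None:
    matrix = read_trait_matrix((ws / "leaf_matrix.tsv").read_text())
    d = hamming(matrix)
    lines = ["# taxon\t" + "\t".join(matrix.taxa)]
    for i, t in enumerate(matrix.taxa):
        lines.append(t + "\t" + "\t".join(f"{v:.10g}" for v in d[i]))
    _write(ws / "hamming.tsv", "\n".join(lines) + "\n")
    system = neighbor_net(d, matrix.taxa, eps=float(cfg["nnet"].get("eps", 1e-8)))
    _write(ws / "splits.nex", write_splits_nexus(system))


def _read_asr(path: Path, k: int):
    rows = {}
    meta = {}
    for line in path.read_text().splitlines():
        if line.startswith("# q="):
            for part in line[2:].split():
                key, val = part.split("=")
                meta[key] = float(val)
            continue
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        node, age, clade = int(parts[0]), float(parts[1]), parts[2]
        probs = np.array([float(x) for x in parts[3 : 3 + k]])
        rows[frozenset(clade.split(","))] = (node, age, probs)
    return rows, meta


def compare_asr_report(
    extant_res: AsrResult,
    grafted_res: AsrResult,
    extant_tree: DatedTree,
) -> pd.DataFrame:
    """Side-by-side extant-only vs fossil-informed node table.

    One row per shared MRCA: both probability vectors, the state flip (change
    of argmax) and the total-variation distance between the two vectors.
    """
    labels = frozenset(extant_tree.tip_labels())
    mapping = match_nodes(extant_res, grafted_res, labels)
    rows = []
    for n_ext, n_gra in mapping.items():
        pe = extant_res.node_probs[n_ext]
        pg = grafted_res.node_probs[n_gra]
        rows.append(
            {
                "clade": ",".join(sorted(extant_res.fingerprint[n_ext])),
                "age": extant_tree.age[n_ext],
                "argmax_extant": int(pe.argmax()),
                "argmax_grafted": int(pg.argmax()),
                "flipped": int(pe.argmax() != pg.argmax()),
                "tv_distance": float(0.5 * np.abs(pe - pg).sum()),
                **{f"extant_p{s}": float(v) for s, v in enumerate(pe)},
                **{f"grafted_p{s}": float(v) for s, v in enumerate(pg)},
            }
        )
    rows.sort(key=lambda r: (-r["age"], r["clade"]))
    return pd.DataFrame(rows)


def _stage_report(cfg: Dict, ws: Path) -> None:
    k = int(cfg["asr"].get("k", 5))
    tree = parse_tree((ws / "tree.nwk").read_text())
    ext_rows, ext_meta = _read_asr(ws / "asr_extant.tsv", k)
    gra_rows, gra_meta = _read_asr(ws / "asr_grafted.tsv", k)
    labels = frozenset(tree.tip_labels())
    # match by extant fingerprint; lowest grafted node wins
    best: Dict[frozenset, tuple] = {}
    for fp, (node, age, probs) in gra_rows.items():
        key = frozenset(fp & labels)
        if key not in best or len(fp) < best[key][0]:
            best[key] = (len(fp), node, age, probs)
    lines = [
        "# clade\tage\targmax_extant\targmax_grafted\tflipped\ttv_distance"
    ]
    ordered = sorted(ext_rows.items(), key=lambda kv: (-kv[1][1], ",".join(sorted(kv[0]))))
    for fp, (node, age, pe) in ordered:
        if fp not in best:
            continue
        pg = best[fp][3]
        flip = int(pe.argmax() != pg.argmax())
        tv = 0.5 * float(np.abs(pe - pg).sum())
        lines.append(
            f"{','.join(sorted(fp))}\t{age:.10g}\t{int(pe.argmax())}"
            f"\t{int(pg.argmax())}\t{flip}\t{tv:.10g}"
        )
    _write(ws / "asr_compare.tsv", "\n".join(lines) + "\n")


STAGE_FUNCS = {
    "fixtures": _stage_fixtures,
    "profile": _stage_profile,
    "classify": _stage_classify,
    "graft": _stage_graft,
    "asr": _stage_asr,
    "dstat": _stage_dstat,
    "nnet": _stage_nnet,
    "report": _stage_report,
}

STAGE_INPUTS = {
    "profile": ["grid.tsv", "occurrences.tsv"],
    "classify": ["profiles.tsv", "biomes.tsv"],
    "graft": ["tree.nwk", "fossils.tsv"],
    "asr": ["tree.nwk", "tree_grafted.nwk", "niche_states.tsv", "fossils.tsv"],
    "nnet": ["leaf_matrix.tsv"],
    "report": ["tree.nwk", "asr_extant.tsv", "asr_grafted.tsv"],
}


def run_pipeline(config: Dict, workdir: str | Path) -> Dict:
    """Execute the configured stages in order and write the run manifest.

    Returns the manifest dict.  A stage whose inputs are missing raises an
    error naming the stage that should be run first.
    """
    ws = Path(workdir)
    ws.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.get("stages", STAGES)]
    produced_by = {
        "grid.tsv": "fixtures", "occurrences.tsv": "fixtures",
        "biomes.tsv": "fixtures", "tree.nwk": "fixtures",
        "fossils.tsv": "fixtures", "niche_states.tsv": "fixtures",
        "leaf_matrix.tsv": "fixtures", "profiles.tsv": "profile",
        "tree_grafted.nwk": "graft", "asr_extant.tsv": "asr",
        "asr_grafted.tsv": "asr",
    }
    import time

    for stage in stages:
        for req in STAGE_INPUTS.get(stage, []):
            if not (ws / req).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs {req}; run stage "
                    f"{produced_by.get(req, 'fixtures')!r} first"
                )
        t0 = time.perf_counter()
        STAGE_FUNCS[stage](config, ws)
        logger.info("STAGE %s done in %.2fs", stage, time.perf_counter() - t0)

    cfg_text = json.dumps(config, sort_keys=True)
    manifest = {
        "tool": "oakniche",
        "version": __version__,
        "seed": int(config["seed"]),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stages": stages,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(ws.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write(ws / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
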