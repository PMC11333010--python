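"""End-to-end orchestration: enumerate, classify, score, scan, report.

``run_pipeline`` executes the topology census, the OFHT stage (on a
synthetic or user-supplied table) and the lattice designability study in
dependency order, writing TSV tables plus a JSON manifest whose headline
counts and content hashes make every run reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import lattice, ofht, synth, topology
from .errors import SchemaError

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("parafold")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration; defaults reproduce the reference study scale."""

    n_min: int = 3
    n_max: int = 6
    lattice_length: int = 16
    eps_hh: float = 1.0
    eps_penalty: float = 2.0
    eps_penalty_sweep: tuple[float, ...] = (0.1, 0.5, 1.0, 3.0, 4.0)
    designability_threshold: int = 100
    seed: int = 0
    table_path: str | None = None  # user-supplied classification TSV
    stages: tuple[str, ...] = ("topologies", "ofht", "lattice")
    out_dir: str = "parafold_out"
    resume: bool = False
    run_sweep: bool = False

    def __post_init__(self):
        bad = set(self.stages) - {"topologies", "ofht", "lattice"}
        if bad:
            raise SchemaError(f"unknown stages {sorted(bad)}")
        if not 2 <= self.n_min <= self.n_max:
            raise SchemaError("need 2 <= n_min <= n_max")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain-text KEY = VALUE config (values in JSON syntax)."""
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"bad config line {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                val = json.loads(val)
            except json.JSONDecodeError:
                pass  # bare string value
            if key in ("stages", "eps_penalty_sweep") and isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    def content_hash(self) -> str:
        """Hash of the scientifically relevant fields (not paths/exec mode)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("resume")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(repr=False)

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest, sort_keys=True).encode()
        ).hexdigest()


def _table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()[:16]


def _stage(name):
    t0 = time.time()
    log.info("[stage:%s] start", name)
    return lambda: log.info("[stage:%s] done in %.1fs", name, time.time() - t0)


def load_bundle(out_dir) -> ReportBundle:
    """Reload a previously written run (manifest + tables) from disk."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    tables = {
        p.stem: pd.read_csv(p, sep="\t") for p in sorted(out_dir.glob("*.tsv"))
    }
    return ReportBundle(manifest=manifest, tables=tables)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.resume and (out_dir / "manifest.json").exists():
        cached = load_bundle(out_dir)
        if cached.manifest.get("config_hash") == cfg.content_hash():
            log.info("[resume] reusing cached run %s", cfg.content_hash())
            return cached
    manifest: dict = {"config": asdict(cfg), "config_hash": cfg.content_hash()}
    tables: dict[str, pd.DataFrame] = {}

    topo_summary = None
    if "topologies" in cfg.stages or "ofht" in cfg.stages:
        done = _stage("topologies")
        topos = topology.enumerate_topologies(cfg.n_min, cfg.n_max)
        topo_summary = topology.summarize_topology_set(topos, clash_free_only=True)
        full = topology.summarize_topology_set(topos)
        tables["topologies"] = full.table
        manifest["topologies"] = {
            "n_enumerated": full.n_topologies,
            "n_clash_free": topo_summary.n_topologies,
            "n_frustration_free": len(topo_summary.frustration_free),
            "n_reverse_asymmetric_pairs": topo_summary.n_reverse_asymmetric_pairs,
            "n_term_edge_pct": topo_summary.n_term_edge_pct,
            "c_term_edge_pct": topo_summary.c_term_edge_pct,
            "grid": topo_summary.grid,
        }
        done()

    if "ofht" in cfg.stages:
        done = _stage("ofht")
        if cfg.table_path:
            table = ofht.EcodLikeTable.from_tsv(cfg.table_path)
        else:
            spec = synth.SyntheticTableSpec(seed=cfg.seed)
            table = synth.generate_ecod_like_table(spec)
        universe = [
            t
            for t in topology.enumerate_topologies(cfg.n_min, cfg.n_max)
            if topology.is_clash_free(t)
        ]
        scores = ofht.compute_ofht(table)
        categories = ofht.categorize_folds(scores, universe)
        pair_table = ofht.reverse_pair_report(scores, universe)
        tables["ofht_categories"] = categories
        tables["ofht_pairs"] = pair_table
        counts = categories["category"].value_counts().to_dict()
        manifest["ofht"] = {
            "n_domains": len(table),
            "n_h_groups": table.n_h_groups,
            "ofht_total": float(scores.ofht.sum()),
            "category_counts": {k: int(v) for k, v in counts.items()},
            "n_pairs": len(pair_table),
        }
        done()

    if "lattice" in cfg.stages:
        done = _stage("lattice")
        L = cfg.lattice_length
        confs = lattice.enumerate_conformations(L)
        ann = lattice.annotate_conformations(confs)
        params = lattice.EnergyParams(cfg.eps_hh, cfg.eps_penalty)
        result = lattice.designability_scan(annotations=ann, params=params)
        grid = lattice.grid_summary(result, cfg.designability_threshold)
        rcos = ann.rco_values()
        struct = pd.DataFrame(
            {
                "structure_id": np.arange(len(confs)),
                "n_c": ann.n_c,
                "n_penalty": ann.n_penalty,
                "n_fls": ann.n_fls,
                "rco": np.round(rcos, 6),
                "n_s": result.n_s,
            }
        )
        tables["lattice_structures"] = struct
        argmax = int(np.argmax(result.n_s))
        rev_idx = int(confs.reverse_indices()[argmax])
        manifest["lattice"] = {
            "L": L,
            "n_conformations": len(confs),
            "protein_like_count": result.protein_like_count,
            "max_ns": int(result.n_s.max()),
            "max_ns_reverse": int(result.n_s[rev_idx]),
            "n_highly_designable": int((result.n_s >= cfg.designability_threshold).sum()),
            "grid_all": grid.counts_all.tolist(),
            "grid_high": grid.counts_high.tolist(),
            "nc_columns": grid.nc_columns,
        }
        if cfg.run_sweep:
            sweep = {}
            for eps in cfg.eps_penalty_sweep:
                r = lattice.designability_scan(
                    annotations=ann, params=lattice.EnergyParams(cfg.eps_hh, eps)
                )
                sweep[str(eps)] = {
                    "protein_like_count": r.protein_like_count,
                    "max_ns": int(r.n_s.max()),
                }
            manifest["lattice"]["sweep"] = sweep
        done()

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    manifest["table_hashes"] = {k: _table_hash(v) for k, v in tables.items()}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(manifest=manifest, tables=tables)
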