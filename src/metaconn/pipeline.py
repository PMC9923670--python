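"""End-to-end orchestration: cohort -> matrices -> edge tests -> topology.

A single declarative configuration drives the full chain and writes a
reproducible artifact tree.  Every stage draws its seed from the master
seed by hashing (master, stage name), so any stage can be re-run in
isolation with identical results, and re-running an identical config
reproduces identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import compare_groups, spearman_matrix
from .network import DEFAULT_THRESHOLD, METRICS, build_graph, node_metrics, permutation_test
from .regions import RegionSet, default_region_set
from .synthetic import default_cohort_config, generate_cohort
from .tables import UptakeTable


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master, stage name), < 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    ``mode`` is "synthetic" (generate a default four-group cohort) or
    "tables" (read ``table_path``).  ``contrasts`` are ordered pairs;
    the sign convention everywhere is first-named group minus second.
    """

    mode: str = "synthetic"
    table_path: str | None = None
    region_set_path: str | None = None
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("pre_VEH", "pre_MLK"),
            ("pre_VEH", "QA_VEH"),
            ("QA_VEH", "QA_MLK"),
        ]
    )
    alpha: float = 0.01
    graph_scheme: str = "thresholded"
    graph_threshold: float = DEFAULT_THRESHOLD
    metrics: list[str] = field(default_factory=lambda: list(METRICS))
    n_perm: int = 1000
    n_per_group: int = 8
    seed: int = 0
    out_dir: str = "metaconn_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        cfg = cls(**raw)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config: dict
    config_hash: str
    checksums: dict[str, str]
    wall_clock_s: dict[str, float]
    warnings: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> UptakeTable:
    if config.mode == "synthetic":
        cc = default_cohort_config(
            seed=stage_seed(config.seed, "cohort"), n_per_group=config.n_per_group
        )
        return generate_cohort(cc)
    if config.mode == "tables":
        if config.table_path is None:
            raise ValueError("mode 'tables' requires table_path")
        rs = (
            RegionSet.from_tsv(config.region_set_path)
            if config.region_set_path
            else default_region_set()
        )
        return UptakeTable.from_csv(config.table_path, rs)
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full chain and write the artifact tree.

    Per contrast: both group matrices, the edge-comparison table with
    its significance mask, per-group node metrics and permutation
    results.  Aborts before any computation if a contrast names a group
    absent from the input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clocks: dict[str, float] = {}
    caught: list[str] = []

    t0 = time.perf_counter()
    table = _load_inputs(config)
    missing = {
        g for pair in config.contrasts for g in pair if g not in table.groups
    }
    if missing:
        raise ValueError(
            f"contrast groups {sorted(missing)} absent from input "
            f"(available: {table.groups})"
        )
    table.to_csv(out / "cohort.csv")
    clocks["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    conns = {}
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for group in table.groups:
            conn = spearman_matrix(table, group)
            conn.to_csv(out / f"rho_{group}.csv")
            conns[group] = conn
        caught += [str(w.message) for w in wrec]
    clocks["connectivity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    for g1, g2 in config.contrasts:
        cmp_ = compare_groups(conns[g1], conns[g2], alpha=config.alpha)
        tag = f"{g1}_vs_{g2}"
        cmp_.to_csv(out / f"edges_{tag}.csv")
        codes = table.region_set.codes
        pd.DataFrame(
            cmp_.significance_mask().astype(int), index=codes, columns=codes
        ).to_csv(out / f"sigmask_{tag}.csv")
    clocks["edge_tests"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics_frames = []
    for group, conn in conns.items():
        g = build_graph(conn, scheme=config.graph_scheme,
                        threshold=config.graph_threshold)
        metrics_frames.append(node_metrics(g))
        nx_edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in g.edges(data=True)],
            columns=["region_a", "region_b", "weight"],
        )
        nx_edges.to_csv(out / f"graph_{group}.csv", index=False)
    pd.concat(metrics_frames, ignore_index=True).to_csv(
        out / "node_metrics.csv", index=False
    )
    clocks["topology"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    for g1, g2 in config.contrasts:
        tag = f"{g1}_vs_{g2}"
        for metric in config.metrics:
            res = permutation_test(
                table, g1, g2, metric=metric, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"perm:{tag}:{metric}"),
                scheme=config.graph_scheme, threshold=config.graph_threshold,
            )
            res.table.assign(
                metric=metric, group_1=g1, group_2=g2,
                n_permutations=res.n_permutations,
            ).to_csv(out / f"perm_{tag}_{metric}.csv", index=False)
    clocks["permutation"] = time.perf_counter() - t0

    checksums = {
        p.name: _sha256_file(p) for p in sorted(out.glob("*.csv"))
    }
    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        config_hash=config.config_hash(),
        checksums=checksums,
        wall_clock_s=clocks,
        warnings=caught,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
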