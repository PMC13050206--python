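"""Configuration-driven end-to-end experiment runner.

An :class:`ExperimentConfig` fully determines one reproducible run: a GP
map source (built-in model, tabular TSV, or pre-built NC graph tables), a
fitness distribution, replicate counts, population size and a master seed.
The runner writes the NC-graph tables, a topography summary (simulated and
predicted), an adaptive-walk CSV, a navigability JSON, and a manifest.
Replicate counts default to the standard protocol: 1000 PF realizations
for topography, 1000 walkers on each of 100 PF maps for walks, and 500 PF
maps with 10 source phenotypes each for navigability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gp_maps import (
    FibonacciGPMap,
    GPMap,
    LowEvolvabilityFibonacciGPMap,
    read_gp_map_table,
)
from .nc_graph import (
    NCGraph,
    build_nc_graph,
    decompose_into_ncs,
    read_nc_graph,
    summarize_nc_graph,
    write_nc_graph,
)
from .pf_maps import DistributionSpec
from .topography import simulate_topography
from .dynamics import WalkEngine, walk_ensemble
from .navigability import estimate_navigability

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "run_experiment"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration validation failure, with a field-level message."""


@dataclass
class ExperimentConfig:
    # GP-map source: exactly one of model / gp_map_path / nc_graph_paths.
    model: str | None = None  # "fibonacci" | "le_fibonacci"
    L: int = 8
    gp_map_path: str | None = None
    nc_node_path: str | None = None
    nc_edge_path: str | None = None
    deleterious_label: str = "DELETERIOUS"

    distribution: str = "uniform01"
    rate: float = 1.0

    n_pf_maps_topography: int = 1000
    n_walkers: int = 1000
    n_pf_maps_walks: int = 100
    n_pf_maps_navigability: int = 500
    n_sources: int = 10
    population_size: int = 1000

    run_walks: bool = True
    run_navigability: bool = True

    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        sources = [
            self.model is not None,
            self.gp_map_path is not None,
            self.nc_node_path is not None,
        ]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one GP-map source must be set: model, gp_map_path, or nc_node_path"
            )
        if self.model is not None and self.model not in ("fibonacci", "le_fibonacci"):
            raise ConfigError(f"model: unknown built-in model {self.model!r}")
        if (self.nc_node_path is None) != (self.nc_edge_path is None):
            raise ConfigError("nc_node_path and nc_edge_path must be given together")
        for name in ("gp_map_path", "nc_node_path", "nc_edge_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")
        for name in (
            "n_pf_maps_topography",
            "n_walkers",
            "n_pf_maps_walks",
            "n_pf_maps_navigability",
            "n_sources",
            "population_size",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1, got {getattr(self, name)}")
        DistributionSpec(self.distribution, self.rate)  # raises on bad values

    @property
    def distribution_spec(self) -> DistributionSpec:
        return DistributionSpec(self.distribution, self.rate)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = ExperimentConfig(**data)
    cfg.validate()
    return cfg


def _resolve_gp_map(cfg: ExperimentConfig) -> GPMap | None:
    if cfg.model == "fibonacci":
        return FibonacciGPMap(length=cfg.L, deleterious_label=cfg.deleterious_label)
    if cfg.model == "le_fibonacci":
        return LowEvolvabilityFibonacciGPMap(length=cfg.L, deleterious_label=cfg.deleterious_label)
    if cfg.gp_map_path is not None:
        return read_gp_map_table(cfg.gp_map_path, deleterious_label=cfg.deleterious_label)
    return None


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured pipeline and write all result files.

    Returns the manifest dictionary.  Re-running an identical config
    reproduces numerically identical outputs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dist = cfg.distribution_spec

    gp_map = _resolve_gp_map(cfg)
    engine: WalkEngine | None = None
    if gp_map is not None:
        log.info("decomposing GP map into neutral components")
        labeling = decompose_into_ncs(gp_map)
        nc_graph = build_nc_graph(gp_map, labeling)
        engine = WalkEngine(gp_map, labeling)
    else:
        nc_graph = read_nc_graph(cfg.nc_node_path, cfg.nc_edge_path)
    write_nc_graph(nc_graph, out / "nc_nodes.tsv", out / "nc_edges.tsv")

    log.info("simulating topography (%d PF maps)", cfg.n_pf_maps_topography)
    topo = simulate_topography(
        nc_graph, dist, n_replicates=cfg.n_pf_maps_topography, seed=cfg.seed
    )
    band = topo.percentile_band()
    topo_payload = {
        "n_replicates": topo.n_replicates,
        "distribution": {"family": dist.family, "rate": dist.rate},
        "mean_peak_count": topo.mean_peak_count,
        "mean_ruggedness": topo.mean_ruggedness,
        "peak_count_percentiles_20_80": list(band["peak_count"]),
        "ruggedness_percentiles_20_80": list(band["ruggedness"]),
        "predicted_peak_count": topo.predicted_peak_count,
        "predicted_ruggedness": topo.predicted_ruggedness,
        "nc_graph_summary": summarize_nc_graph(nc_graph),
    }
    with open(out / "topography.json", "w") as fh:
        json.dump(topo_payload, fh, indent=2, sort_keys=True, default=float)

    files = ["nc_nodes.tsv", "nc_edges.tsv", "topography.json"]

    if cfg.run_walks and engine is not None:
        log.info("running adaptive walks (%d x %d)", cfg.n_walkers, cfg.n_pf_maps_walks)
        ens = walk_ensemble(
            gp_map,
            dist,
            n_walkers=cfg.n_walkers,
            n_pf_maps=cfg.n_pf_maps_walks,
            N=cfg.population_size,
            seed=cfg.seed,
            nc_graph=nc_graph,
            engine=engine,
        )
        if ens.n_redrawn_pf_maps:
            log.warning("redrew %d PF maps with no valid walk start", ens.n_redrawn_pf_maps)
        pd.DataFrame(
            {
                "pf_map_index": ens.pf_index,
                "endpoint_nc": ens.endpoint_nc,
                "endpoint_fitness": ens.endpoint_fitness,
                "steps": ens.n_steps,
            }
        ).to_csv(out / "walks.csv", index=False)
        files.append("walks.csv")
    elif cfg.run_walks:
        log.warning("walks need genotype-level data; skipped for NC-graph-only input")

    if cfg.run_navigability:
        log.info("estimating navigability (%d PF maps)", cfg.n_pf_maps_navigability)
        nav = estimate_navigability(
            nc_graph,
            dist,
            n_pf_maps=cfg.n_pf_maps_navigability,
            n_sources=cfg.n_sources,
            seed=cfg.seed,
            deleterious_label=cfg.deleterious_label,
        )
        nav_payload = {
            "n_pf_maps": nav.n_pf_maps,
            "n_sources": nav.n_sources,
            "n_success": nav.n_success,
            "navigability": nav.navigability,
            "source_policy": nav.source_policy,
        }
        with open(out / "navigability.json", "w") as fh:
            json.dump(nav_payload, fh, indent=2, sort_keys=True)
        files.append("navigability.json")

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
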