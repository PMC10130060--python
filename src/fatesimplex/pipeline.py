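"""End-to-end orchestration: simulate (optional) -> preprocess -> markers ->
simplex -> velocity -> potential -> binned arrows, with a run manifest.

A single global seed is fanned out into stable per-stage child seeds so each
stage is individually reproducible. Results go to files; logs go to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from . import markers as mk
from . import preprocess as pp
from . import simulate as sim
from . import simplex as sx
from . import velocity as vl

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their standard defaults."""

    # inputs: either a bundle directory on disk or a simulation
    input_dir: str | None = None
    simulate: bool = True
    outdir: str = "fatesimplex_out"
    # apex fate -> cluster label (order fixes the triangle vertices)
    apex: dict = field(
        default_factory=lambda: dict(zip(sim.FATE_NAMES, sim.APEX_LABELS))
    )
    # stage parameters (defaults follow the published procedure)
    min_counts: int = 10
    n_features: int = 3000
    n_pcs: int = 30
    knn_k: int = 30
    top_k: int = 30
    marker_mode: str = "genes"
    alpha: float = 0.05
    exclude_self: bool = False
    extreme_quantile: float = 0.05
    edge_mean: bool = False
    n_bins: int = 40
    upstream_bp: int = 3000
    graph_in: str | None = None
    # simulation parameters (used when simulate=True)
    sim_n_cells: int = 600
    sim_n_genes: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate and not self.input_dir:
            raise ValueError("config field 'input_dir' is required when simulate is false")
        if len(self.apex) != 3:
            raise ValueError("config field 'apex' must map exactly 3 fates to cluster labels")
        for name, val in (
            ("min_counts", self.min_counts),
            ("n_features", self.n_features),
            ("n_pcs", self.n_pcs),
            ("knn_k", self.knn_k),
            ("top_k", self.top_k),
            ("n_bins", self.n_bins),
            ("upstream_bp", self.upstream_bp),
        ):
            if val < 0:
                raise ValueError(f"config field {name!r} must be nonnegative")

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stable child seed below 2**31 derived from the global seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    """In-memory handles to the products of one run."""

    adata: "object"
    scaled: pp.ScaledMatrix
    coords: sx.SimplexCoordinates
    potential: vl.FatePotential
    arrows: vl.BinnedArrowField
    velocity_field: vl.VelocityField
    graph: "object"
    markers: dict
    manifest: dict


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write coords/arrows/markers/graph plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    try:
        import importlib.metadata as ilm

        manifest["version"] = ilm.version("fatesimplex")
    except Exception:  # pragma: no cover - not installed
        manifest["version"] = "unknown"

    def record(stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        manifest["stages"][stage] = info

    apex = sx.ApexSpec.from_mapping(config.apex)

    # --- input -------------------------------------------------------------
    if config.simulate:
        params = sim.SimParams(
            n_cells=config.sim_n_cells,
            n_genes=config.sim_n_genes,
            seed=stage_seed(config.seed, "simulate"),
        )
        adata, truth = sim.simulate_fate_landscape(params)
        fio.write_truth(truth, outdir / "truth.tsv", list(adata.obs_names), list(sim.FATE_NAMES))
        record("simulate", n_cells=adata.n_obs, n_genes=adata.n_vars)
    else:
        adata = fio.read_expression(config.input_dir)
        truth = None
        if "cluster" not in adata.obs:
            raise ValueError(f"input bundle {config.input_dir} lacks labels.tsv cluster labels")
        record("load", n_cells=adata.n_obs, n_genes=adata.n_vars)

    # --- preprocess ----------------------------------------------------------
    adata = pp.filter_genes(adata, min_counts=config.min_counts)
    record("filter_genes", n_genes=adata.n_vars, min_counts=config.min_counts)
    norm = pp.normalize_and_log(adata)
    record("normalize", n_cells=norm.n_obs)
    features = pp.select_variable_features(norm, n_target=config.n_features)
    record("variable_features", n_selected=len(features))
    scaled_vf = pp.scale_no_center(norm, features)
    knn = pp.pca_knn_graph(
        scaled_vf, n_pcs=config.n_pcs, k=config.knn_k, seed=stage_seed(config.seed, "pca")
    )
    record("knn", k=config.knn_k, n_pcs=knn.embedding.shape[1])

    # --- markers -------------------------------------------------------------
    labels = np.asarray(norm.obs["cluster"])
    marker_lists: dict[str, list[str]] = {}
    stats_frames = []
    for label in apex.cluster_labels:
        stats = mk.wilcoxon_one_vs_rest(norm.X, list(norm.var_names), labels, label)
        marker_lists[label] = mk.top_k_markers(
            stats, k=config.top_k, mode=config.marker_mode, alpha=config.alpha
        )
        stats = stats.reset_index()
        stats.insert(0, "cluster", label)
        stats["selected"] = stats["feature"].isin(set(marker_lists[label]))
        stats_frames.append(stats)
    import pandas as pd

    pd.concat(stats_frames, ignore_index=True).to_csv(
        outdir / "markers.tsv", sep="\t", index=False, float_format=fio.FLOAT_FORMAT
    )
    record("markers", per_cluster={k: len(v) for k, v in marker_lists.items()})

    # --- simplex -------------------------------------------------------------
    fate_features = sx.fate_feature_space(marker_lists, apex, k=config.top_k)
    scaled_fate = pp.scale_no_center(norm, fate_features)
    coords = sx.compute_simplex(scaled_fate, labels, apex, exclude_self=config.exclude_self)
    record("simplex", n_cells=len(coords.barcodes), n_features=len(fate_features))

    # --- velocity ------------------------------------------------------------
    # first-order KNN moments: suppress count noise before the steady-state fit
    S = pp.knn_smooth(norm.layers["spliced_norm"], knn)
    U = pp.knn_smooth(norm.layers["unspliced_norm"], knn)
    gamma, valid = vl.fit_gamma_steady_state(S, U, extreme_quantile=config.extreme_quantile)
    vfield = vl.compute_velocity(S, U, gamma, valid)
    if config.graph_in:
        graph = fio.read_velocity_graph(config.graph_in, norm.n_obs)
        record("velocity_graph", source=config.graph_in, nnz=int(graph.nnz))
    else:
        graph = vl.velocity_graph(vfield, S, knn)
        record("velocity_graph", nnz=int(graph.nnz), n_valid_genes=int(valid.sum()))
    fio.write_velocity_graph(graph, outdir / "velocity_graph.tsv")

    potential = vl.fate_potential(graph, labels, apex, edge_mean=config.edge_mean)
    record("potential", n_flagged=int(potential.zero_flag.sum()))
    arrows = vl.bin_arrows(coords, potential, n_bins=config.n_bins)
    record("arrows", n_bins=arrows.n_bins_x * arrows.n_bins_y)

    fio.write_simplex_outputs(coords, arrows, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    return PipelineResult(
        adata=norm,
        scaled=scaled_fate,
        coords=coords,
        potential=potential,
        arrows=arrows,
        velocity_field=vfield,
        graph=graph,
        markers=marker_lists,
        manifest=manifest,
    )
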