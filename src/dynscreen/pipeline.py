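"""Pipeline orchestration: simulate / quantify / analyze / full.

A run is driven by a :class:`RunConfig` (loadable from a YAML file),
executes its stages in order into a run directory, and records a
provenance manifest (parameters, seeds, input/output content hashes).
Stages are cached on content hashes: a rerun with unchanged inputs and
parameters skips the stage and reuses its outputs, which by
construction cannot change any result. All tabular outputs are CSV
written with a fixed float format, so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiling import hierarchical_cluster, kmeans_cargo_clusters, reduce_features
from .screen import AnalysisConfig, analyze_screen
from .synth.effects import plant_effects
from .synth.layout import generate_plate_layout, validate_layout
from .synth.population import SimConfig, simulate_screen

logger = logging.getLogger(__name__)

MODES = ("simulate", "quantify", "analyze", "full", "validate")
FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str
    out_dir: str
    seed: int | None = None
    # simulate
    n_plates: int = 2
    n_genes: int = 160
    wells_per_gene: int = 4
    control_design: dict | None = None
    sim: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    # analyze
    cells_path: str | None = None
    layout_path: str | None = None
    analysis: dict = field(default_factory=dict)
    cluster: bool = True
    # images: number of wells rendered to TIFF during simulate (0 = none,
    # the feature-table path is the canonical surface), and the image
    # directory consumed by quantify mode
    render_wells: int = 0
    render_cells_per_well: int = 8
    images_dir: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"mode: unknown mode {self.mode!r}")
        if self.mode in ("simulate", "full", "analyze") and self.seed is None:
            raise ConfigError(f"seed: required for mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "mode" not in raw:
            raise ConfigError("mode: field is required")
        if "out_dir" not in raw:
            raise ConfigError("out_dir: field is required")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_params(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=False):
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"mode": config.mode, "seed": config.seed, "stages": {}}
    if manifest_path.exists():
        try:
            manifest["stages"] = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            pass

    if config.mode in ("simulate", "full"):
        _stage_simulate(config, out, manifest)
    if config.mode == "quantify":
        _stage_quantify(config, out, manifest)
    if config.mode in ("analyze", "full"):
        _stage_analyze(config, out, manifest)
    if config.mode == "validate":
        report = validate_io(
            layout_path=config.layout_path, cells_path=config.cells_path,
            images_dir=config.images_dir,
        )
        manifest["validation"] = report
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _stage_cached(manifest, stage: str, params_hash: str, outputs: list[Path]) -> bool:
    prev = manifest["stages"].get(stage)
    return (
        prev is not None
        and prev.get("params_hash") == params_hash
        and all(p.exists() for p in outputs)
        and all(_hash_file(p) == h for p, h in zip(outputs, prev.get("output_hashes", [])))
    )


def _record_stage(manifest, stage, params_hash, outputs):
    manifest["stages"][stage] = {
        "params_hash": params_hash,
        "outputs": [str(p) for p in outputs],
        "output_hashes": [_hash_file(p) for p in outputs],
    }


def _stage_simulate(config: RunConfig, out: Path, manifest: dict):
    outputs = [out / "layout.csv", out / "ground_truth.csv", out / "cells.csv"]
    params = {
        "seed": config.seed,
        "n_plates": config.n_plates,
        "n_genes": config.n_genes,
        "wells_per_gene": config.wells_per_gene,
        "control_design": config.control_design,
        "sim": config.sim,
        "effects": config.effects,
        "render_wells": config.render_wells,
        "render_cells_per_well": config.render_cells_per_well,
    }
    params_hash = _hash_params(params)
    if _stage_cached(manifest, "simulate", params_hash, outputs):
        logger.info("simulate: cached, skipping")
        return
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    layout = generate_plate_layout(
        genes,
        n_plates=config.n_plates,
        control_design=config.control_design,
        wells_per_gene=config.wells_per_gene,
        seed=config.seed,
    )
    rng = np.random.default_rng([config.seed, 1])
    truth = plant_effects(genes, rng, **config.effects)
    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    cells = simulate_screen(layout, truth, sim_cfg)
    _write_csv(layout, outputs[0])
    _write_csv(truth.to_frame(), outputs[1])
    _write_csv(cells, outputs[2])
    if config.render_wells > 0:
        from .imagefiles import write_well_images
        from .synth.effects import CONTROL_EFFECTS, NO_EFFECT
        from .synth.population import well_rng
        from .synth.render import render_well_images

        img_dir = out / "images"
        for well in layout.head(config.render_wells).itertuples(index=False):
            well_cells = cells[
                (cells["plate_id"] == well.plate_id)
                & (cells["row"] == well.row)
                & (cells["col"] == well.col)
            ]
            well_cells = well_cells[well_cells["truth_viable"]].head(
                config.render_cells_per_well
            )
            effect = (
                truth.effect_for(well.gene)
                if well.role == "LIBRARY"
                else CONTROL_EFFECTS.get(well.role, NO_EFFECT)
            )
            rng = well_rng(config.seed + 1_000_003, well.plate_id, well.row, well.col)
            images, _ = render_well_images(well_cells, sim_cfg, rng, effect)
            write_well_images(
                images, img_dir, well.plate_id, well.row, well.col, sim_cfg.pixel_size_um
            )
    _record_stage(manifest, "simulate", params_hash, outputs)


def _stage_quantify(config: RunConfig, out: Path, manifest: dict):
    from .imagefiles import read_well_images
    from .quant.well import quantify_well

    img_dir = Path(config.images_dir or out / "images")
    if not img_dir.is_dir():
        raise ConfigError(f"quantify: image directory not found: {img_dir}")
    tiffs = sorted(img_dir.glob("*.tif*"))
    if not tiffs:
        raise ConfigError(f"quantify: no TIFF files in {img_dir}")
    outputs = [out / "quantified_cells.csv"]
    params = {"inputs": [_hash_file(p) for p in tiffs]}
    params_hash = _hash_params(params)
    if _stage_cached(manifest, "quantify", params_hash, outputs):
        logger.info("quantify: cached, skipping")
        return
    frames = []
    for tiff in tiffs:
        images, meta = read_well_images(tiff)
        spot_channels = [
            ch for ch in images if ch not in ("hoechst", "tubulin", "gamma_tubulin")
        ]
        table = quantify_well(
            images, spot_channels=spot_channels, pixel_size_um=meta["pixel_size_um"]
        )
        if len(table):
            table.insert(0, "plate_id", meta["plate_id"])
            table.insert(1, "row", meta["row"])
            table.insert(2, "col", meta["col"])
            frames.append(table)
    quantified = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    _write_csv(quantified, outputs[0])
    _record_stage(manifest, "quantify", params_hash, outputs)


def _stage_analyze(config: RunConfig, out: Path, manifest: dict):
    cells_path = Path(config.cells_path or out / "cells.csv")
    layout_path = Path(config.layout_path or out / "layout.csv")
    for p in (cells_path, layout_path):
        if not p.exists():
            raise ConfigError(f"analyze: input file not found: {p}")
    outputs = [out / "wells.csv", out / "rz.csv", out / "hit_table.csv", out / "fingerprints.csv"]
    if config.cluster:
        outputs.append(out / "clusters.csv")
    params = {
        "seed": config.seed,
        "analysis": config.analysis,
        "cluster": config.cluster,
        "inputs": [_hash_file(cells_path), _hash_file(layout_path)],
    }
    params_hash = _hash_params(params)
    if _stage_cached(manifest, "analyze", params_hash, outputs):
        logger.info("analyze: cached, skipping")
        return
    cells = pd.read_csv(cells_path)
    layout = pd.read_csv(layout_path, keep_default_na=False)
    analysis_cfg = AnalysisConfig(**config.analysis)
    result = analyze_screen(cells, layout, analysis_cfg)
    _write_csv(result.well_profiles, outputs[0])
    _write_csv(result.rz, outputs[1])
    _write_csv(result.hit_table.sort_index(), outputs[2], index=True)
    _write_csv(result.fingerprints.sort_index(), outputs[3], index=True)
    if config.cluster:
        cluster_rows = []
        channels = result.provenance["channels"]
        vectors = pd.DataFrame(index=result.gene_scores.index)
        if {"GFP", "RFP"} <= set(channels):
            vectors["PEX"] = result.gene_scores[
                ["GFP_log_loc_ratio", "RFP_log_loc_ratio"]
            ].mean(axis=1)
        for ch in channels:
            if ch not in ("GFP", "RFP"):
                vectors[ch] = result.gene_scores[f"{ch}_log_loc_ratio"]
        k = min(analysis_cfg.kmeans_k, max(len(vectors) - 1, 1))
        km = kmeans_cargo_clusters(vectors.dropna(), k=k, seed=config.seed)
        for gene, label in km.labels.items():
            cluster_rows.append({"gene": gene, "method": "kmeans", "cluster": int(label)})
        lis1_profiles = result.rz[result.rz["role"] == "POS_LIS1"][
            result.provenance["rz_features"]
        ]
        try:
            retained, _ = reduce_features(
                result.fingerprints,
                lis1_profiles,
                analysis_cfg.reduce_sd_cut,
                analysis_cfg.reduce_r2_cut,
            )
            hier = hierarchical_cluster(
                result.fingerprints[retained], n_clusters=min(10, len(result.fingerprints) - 1)
            )
            for gene, label in hier.labels.items():
                cluster_rows.append({"gene": gene, "method": "hierarchical", "cluster": int(label)})
        except ValueError as exc:
            logger.warning("hierarchical clustering skipped: %s", exc)
        _write_csv(pd.DataFrame(cluster_rows).sort_values(["method", "gene"]).reset_index(drop=True), outputs[4])
    _record_stage(manifest, "analyze", params_hash, outputs)


def validate_io(layout_path=None, cells_path=None, images_dir=None) -> dict:
    """Schema checks for pipeline inputs; distinguishes errors and warnings."""
    errors, warnings_ = [], []
    if layout_path is not None:
        p = Path(layout_path)
        if not p.exists():
            errors.append(f"unreadable layout file: {p}")
        else:
            layout = pd.read_csv(p, keep_default_na=False)
            errors.extend(f"layout: {e}" for e in validate_layout(layout))
    if cells_path is not None:
        p = Path(cells_path)
        if not p.exists():
            errors.append(f"unreadable cell table: {p}")
        else:
            head = pd.read_csv(p, nrows=5)
            required = {"plate_id", "row", "col", "nucleus_area", "nucleus_roundness"}
            missing = required - set(head.columns)
            if missing:
                errors.append(f"cell table: missing columns {sorted(missing)}")
            spot_cols = [c for c in head.columns if c.endswith("_spots_total")]
            if not spot_cols:
                warnings_.append("cell table: no spot-count columns found")
    if images_dir is not None:
        d = Path(images_dir)
        if not d.is_dir():
            errors.append(f"unreadable image directory: {d}")
        else:
            for tiff in sorted(d.glob("*.tif*")):
                sidecar = tiff.with_suffix(".json")
                if not sidecar.exists():
                    warnings_.append(f"missing channel-map sidecar for {tiff.name}")
    return {"errors": errors, "warnings": warnings_}
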