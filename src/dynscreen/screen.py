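"""End-to-end screen analysis on per-cell feature tables.

Runs the analysis stages in screening order: per-plate NTC-calibrated
viability and reporter gating, well aggregation, plate-local rZ
normalization, two-point lethality scoring, per-crRNA median pooling,
confound exclusion, threshold hit calling, and phenotypic
fingerprinting. Works identically on synthetic feature tables and on
tables produced by image quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hits as hitmod
from . import plates
from .quant.gating import (
    calibrate_reporter,
    calibrate_viability,
    gate_reporter_positive,
    gate_viable,
)
from .quant.regions import localization_ratio

WELL_KEYS = plates.WELL_KEYS


@dataclass
class AnalysisConfig:
    channels: tuple = ("GFP", "RFP", "EEA1")
    cargo_k: float = 2.5
    eea1_k: float | None = None  # override for EEA1-style endpoints
    lethal_k: float = 2.5
    micronucleus_k: float = 2.5
    mtoc_k: float = 2.5
    min_cells_per_well: int = 50
    viability_gate_k: float = 3.5
    kmeans_k: int = 14
    reduce_sd_cut: float = 3.0
    reduce_r2_cut: float = 0.8


@dataclass
class ScreenResult:
    well_profiles: pd.DataFrame
    rz: pd.DataFrame
    gene_scores: pd.DataFrame
    references: dict
    hit_table: pd.DataFrame
    exclusions: pd.DataFrame
    fingerprints: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def derive_cell_features(cells: pd.DataFrame, channels) -> pd.DataFrame:
    """Add per-cell derived readouts (log localization ratios, indicators)."""
    out = cells.copy()
    for ch in channels:
        inner = out[f"{ch}_spots_perinuclear"].to_numpy()
        periph = (
            out[f"{ch}_spots_intermediate"].to_numpy() + out[f"{ch}_spots_outer"].to_numpy()
        )
        out[f"{ch}_loc_ratio"] = localization_ratio(inner, periph)
    out["has_micronucleus"] = (out["micronucleus_count"] > 0).astype(float)
    for label, sel in (("p0", 0), ("p1", 1)):
        out[f"mtoc_{label}"] = (out["mtoc_count"] == sel).astype(float)
    out["mtoc_pmulti"] = (out["mtoc_count"] >= 2).astype(float)
    return out


def gate_cells(cells: pd.DataFrame, layout: pd.DataFrame, gate_k: float = 3.5):
    """Per-plate NTC-calibrated viability and reporter gates."""
    merged = cells.merge(layout[WELL_KEYS + ["role"]], on=WELL_KEYS, how="left")
    viable = pd.Series(False, index=cells.index)
    reporter = pd.Series(False, index=cells.index)
    for plate, idx in merged.groupby("plate_id").groups.items():
        sub = merged.loc[idx]
        ntc = sub[sub["role"] == "NTC"]
        cal = calibrate_viability(ntc, k=gate_k)
        viable.loc[idx] = gate_viable(sub, cal).to_numpy()
        thr = calibrate_reporter(ntc)
        reporter.loc[idx] = gate_reporter_positive(sub, thr).to_numpy()
    return viable, reporter


def aggregate_screen(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    channels,
    gate: pd.Series,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Well profiles: per-feature means over gated cells, plus QC counts."""
    feature_cols = [
        c
        for c in cells.columns
        if c not in WELL_KEYS
        and not c.startswith("truth_")
        and pd.api.types.is_numeric_dtype(cells[c])
    ]
    profiles = []
    for key, idx in cells.groupby(WELL_KEYS).groups.items():
        well_cells = cells.loc[idx]
        prof = plates.aggregate_well(
            well_cells, feature_cols, gate=gate.loc[idx], min_cells=min_cells
        )
        rec = dict(zip(WELL_KEYS, key))
        rec.update(prof.to_dict())
        profiles.append(rec)
    out = pd.DataFrame(profiles).reset_index(drop=True)
    # wells absent from the cell table (zero surviving cells) still get a row
    missing = layout.merge(out[WELL_KEYS], on=WELL_KEYS, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    for w in missing.itertuples(index=False):
        row = {k: getattr(w, k) for k in WELL_KEYS}
        row.update({"n_cells": 0, "n_viable": 0, "low_count": True, "excluded": True})
        out = pd.concat([out, pd.DataFrame([row])], ignore_index=True)
    return out


def analyze_screen(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> ScreenResult:
    """Full feature-table analysis of one screen run."""
    config = config or AnalysisConfig()
    channels = [ch for ch in config.channels if f"{ch}_spots_perinuclear" in cells.columns]
    cells = derive_cell_features(cells, channels)
    viable, reporter = gate_cells(cells, layout, config.viability_gate_k)
    profiles = aggregate_screen(
        cells, layout, channels, gate=viable & reporter, min_cells=config.min_cells_per_well
    )
    profiles = profiles.merge(
        layout[WELL_KEYS + ["role", "crrna_pool", "gene"]], on=WELL_KEYS
    )
    # log-transform localization ratios at well level (well means are
    # strictly positive for any realistic population)
    for ch in channels:
        with np.errstate(divide="ignore"):
            profiles[f"{ch}_log_loc_ratio"] = np.log(profiles[f"{ch}_loc_ratio"])

    loc_endpoints = [f"{ch}_log_loc_ratio" for ch in channels]
    spot_endpoints = [f"{ch}_spots_total" for ch in channels]
    morpho_endpoints = ["nucleus_area", "nucleus_roundness"]
    mn_endpoints = ["micronucleus_count", "has_micronucleus"]
    texture_feats = [c for c in profiles.columns if "_texture_" in c]
    rz_features = (
        loc_endpoints + spot_endpoints + morpho_endpoints + mn_endpoints + texture_feats
    )
    scored = profiles.dropna(subset=loc_endpoints)
    stats = plates.control_stats(scored, layout, rz_features)
    rz = plates.rz_table(scored, layout, rz_features, stats)
    rz = rz.merge(layout[WELL_KEYS + ["role", "crrna_pool", "gene"]], on=WELL_KEYS)

    # two-point lethality: viable cell count, NTC -> 0, crPLK1 -> +100
    lethality = []
    for plate, sub in profiles.groupby("plate_id"):
        med_ntc = sub.loc[sub["role"] == "NTC", "n_viable"].median()
        med_plk = sub.loc[sub["role"] == "EDIT_PLK1", "n_viable"].median()
        score = plates.two_point_normalize(sub["n_viable"], med_ntc, med_plk, 100.0)
        lethality.append(pd.Series(score, index=sub.index))
    profiles["lethality_score"] = pd.concat(lethality).sort_index()

    # gene-level scores: median per crRNA pool over its wells
    lib = rz[rz["role"] == "LIBRARY"]
    gene_scores = lib.groupby("gene")[rz_features].median()
    lib_prof = profiles[profiles["role"] == "LIBRARY"]
    gene_scores["lethality_score"] = lib_prof.groupby("gene")["lethality_score"].median()
    for p in ("mtoc_p0", "mtoc_p1", "mtoc_pmulti"):
        gene_scores[p] = lib_prof.groupby("gene")[p].mean()

    # control references (well-level scores on the same scales)
    references = {
        grp: {ep: rz.loc[rz["role"] == role, ep].to_numpy() for ep in rz_features}
        for grp, role in (("NTC", "NTC"), ("crLIS1", "POS_LIS1"))
    }
    for grp, role in (("NTC", "NTC"), ("crLIS1", "POS_LIS1")):
        references[grp]["lethality_score"] = profiles.loc[
            profiles["role"] == role, "lethality_score"
        ].to_numpy()

    lethal = hitmod.call_lethal(
        gene_scores["lethality_score"], references["crLIS1"]["lethality_score"], config.lethal_k
    )
    exclusions = hitmod.exclude_confounded(gene_scores, references, lethal_flags=lethal)

    eea1_k = config.eea1_k if config.eea1_k is not None else config.cargo_k
    rules = []
    for ch in channels:
        k = eea1_k if ch == "EEA1" else config.cargo_k
        rules.append(hitmod.ThresholdRule(f"{ch}_log_loc_ratio", "NTC", k, "two_sided", "rz"))
    cargo = hitmod.call_cargo_hits(gene_scores, references, rules)
    micronucleus = hitmod.call_micronucleus_hits(
        gene_scores["has_micronucleus"],
        references["crLIS1"]["has_micronucleus"],
        config.micronucleus_k,
    )
    ntc_props = (
        profiles[profiles["role"] == "NTC"][["mtoc_p0", "mtoc_p1", "mtoc_pmulti"]]
        .rename(columns={"mtoc_p0": "p0", "mtoc_p1": "p1", "mtoc_pmulti": "pmulti"})
        .dropna()
    )
    gene_props = gene_scores[["mtoc_p0", "mtoc_p1", "mtoc_pmulti"]].rename(
        columns={"mtoc_p0": "p0", "mtoc_p1": "p1", "mtoc_pmulti": "pmulti"}
    )
    try:
        mtoc = hitmod.categorize_mtoc(gene_props, ntc_props, k=config.mtoc_k)
    except ValueError:
        mtoc = None
    hit_table = hitmod.build_hit_table(
        gene_scores, exclusions, cargo, lethal=lethal, micronucleus=micronucleus, mtoc=mtoc
    )

    # fingerprints: median rZ per gene over the full rz feature registry
    fingerprints = lib.groupby("gene")[rz_features].median()

    provenance = {
        "channels": list(channels),
        "rz_features": rz_features,
        "rules": [vars(r) for r in rules],
        "viability_gate": {"method": "mad", "k": config.viability_gate_k},
        "normalization": "per-plate NTC median/MAD (rZ), 1.4826 consistency constant",
    }
    return ScreenResult(
        well_profiles=profiles,
        rz=rz,
        gene_scores=gene_scores,
        references=references,
        hit_table=hit_table,
        exclusions=exclusions,
        fingerprints=fingerprints,
        provenance=provenance,
    )
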