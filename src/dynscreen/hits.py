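"""Threshold-based hit calling with confound exclusion.

Hit thresholds are k*SD envelopes around the mean of a declared
reference control group (NTC, crLIS1, or the pooled union of both),
computed on the same scale as the scores (raw, rZ or two-point -- each
rule declares its scale explicitly). Thresholds are closed: a score at
exactly the boundary is a hit. Genes with strong viability or
nuclear-morphology effects are excluded before cargo-localization
calling, since such perturbations can relocalize cargo indirectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SIDEDNESS = ("two_sided", "low_only", "high_only")


@dataclass
class ThresholdRule:
    """One hit-calling rule: endpoint, reference group, k, sidedness."""

    endpoint: str
    reference: str = "NTC"  # NTC | crLIS1 | both
    k: float = 2.5
    sidedness: str = "two_sided"
    scale: str = "rz"  # raw | rz | two_point (bookkeeping for audit)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be > 0")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


def sd_envelope(reference_values, k: float):
    """(center, half-width) of the mean +/- k*SD control envelope."""
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 values")
    return float(ref.mean()), float(k * ref.std(ddof=1))


def apply_rule(scores: pd.Series, reference_values, rule: ThresholdRule) -> pd.DataFrame:
    """Apply one threshold rule; returns hit flag and signed direction.

    Direction is -1 (below the low bound), +1 (above the high bound) or
    0. Thresholds are closed (>=), so boundary scores are hits.
    """
    center, half = sd_envelope(reference_values, rule.k)
    s = scores.astype(float)
    low = s <= center - half
    high = s >= center + half
    if rule.sidedness == "low_only":
        high = pd.Series(False, index=s.index)
    elif rule.sidedness == "high_only":
        low = pd.Series(False, index=s.index)
    direction = high.astype(int) - low.astype(int)
    return pd.DataFrame(
        {
            "hit": low | high,
            "direction": direction,
            "threshold_low": center - half,
            "threshold_high": center + half,
        },
        index=s.index,
    )


def _reference(rule: ThresholdRule, references: dict):
    if rule.reference == "both":
        return np.concatenate(
            [np.asarray(references["NTC"], float), np.asarray(references["crLIS1"], float)]
        )
    if rule.reference not in references:
        raise ValueError(f"missing reference wells for group {rule.reference!r}")
    return references[rule.reference]


def call_cargo_hits(
    gene_scores: pd.DataFrame,
    references: dict,
    rules: list[ThresholdRule],
) -> pd.DataFrame:
    """Call cargo-localization hits per endpoint.

    ``gene_scores`` has one row per gene and one column per endpoint;
    ``references`` maps reference-group name to a dict of
    endpoint -> control well scores on the same scale. Both dispersion
    (negative) and hyperclustering (positive) directions are retained
    for two-sided rules.
    """
    out = pd.DataFrame(index=gene_scores.index)
    for rule in rules:
        ref = _reference(rule, {g: v[rule.endpoint] for g, v in references.items()})
        res = apply_rule(gene_scores[rule.endpoint], ref, rule)
        out[f"{rule.endpoint}_hit"] = res["hit"]
        out[f"{rule.endpoint}_direction"] = res["direction"]
    hit_cols = [c for c in out.columns if c.endswith("_hit")]
    out["any_cargo_hit"] = out[hit_cols].any(axis=1)
    return out


def exclude_confounded(
    gene_scores: pd.DataFrame,
    references: dict,
    area_endpoint: str = "nucleus_area",
    roundness_endpoint: str = "nucleus_roundness",
    lethal_flags: pd.Series | None = None,
    area_k: float = 4.0,
    roundness_k: float = 3.5,
) -> pd.DataFrame:
    """Flag genes confounded by viability or nuclear-morphology effects.

    Envelopes use the pooled NTC + crLIS1 control wells: +/- ``area_k``
    SD on nuclear area, ``roundness_k`` SD low-side on roundness.
    ``lethal_flags`` (from :func:`call_lethal`) is OR-ed in. Each flag
    records its triggering rule.
    """
    pooled = {
        ep: np.concatenate(
            [np.asarray(references["NTC"][ep], float), np.asarray(references["crLIS1"][ep], float)]
        )
        for ep in (area_endpoint, roundness_endpoint)
    }
    area = apply_rule(
        gene_scores[area_endpoint],
        pooled[area_endpoint],
        ThresholdRule(area_endpoint, "both", area_k, "two_sided"),
    )
    roundness = apply_rule(
        gene_scores[roundness_endpoint],
        pooled[roundness_endpoint],
        ThresholdRule(roundness_endpoint, "both", roundness_k, "low_only"),
    )
    out = pd.DataFrame(index=gene_scores.index)
    out["excluded_area"] = area["hit"]
    out["excluded_roundness"] = roundness["hit"]
    out["excluded_lethal"] = (
        lethal_flags.reindex(gene_scores.index).fillna(False).astype(bool)
        if lethal_flags is not None
        else False
    )
    out["excluded"] = out[["excluded_area", "excluded_roundness", "excluded_lethal"]].any(axis=1)
    reasons = []
    for _, r in out.iterrows():
        why = [
            name
            for name, flag in (
                (f"area_{area_k}sd", r["excluded_area"]),
                (f"roundness_-{roundness_k}sd", r["excluded_roundness"]),
                ("lethal", r["excluded_lethal"]),
            )
            if flag
        ]
        reasons.append(";".join(why))
    out["exclusion_reason"] = reasons
    return out


def call_lethal(
    viability_scores: pd.Series,
    lis1_reference,
    k: float = 2.5,
) -> pd.Series:
    """Lethality call on the two-point viability scale (NTC=0, crPLK1=100).

    A gene is lethal when its score exceeds the crLIS1 reference
    envelope on the high side (closed threshold).
    """
    center, half = sd_envelope(lis1_reference, k)
    return viability_scores.astype(float) >= center + half


def call_micronucleus_hits(
    micronucleus_scores: pd.Series,
    lis1_reference,
    k: float = 2.5,
) -> pd.Series:
    """Micronucleus phenotype call: crLIS1-referenced, high side only."""
    center, half = sd_envelope(lis1_reference, k)
    return micronucleus_scores.astype(float) >= center + half


def categorize_mtoc(
    gene_props: pd.DataFrame,
    ntc_props: pd.DataFrame,
    lis1_props: pd.DataFrame | None = None,
    k: float = 2.5,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Categorize genes by MTOC-count phenotype.

    Inputs are raw per-gene (and per-control-well) proportions of cells
    with 0, 1 and >1 gamma-Tubulin puncta, columns ``p0, p1, pmulti``
    summing to 1. Proportions are rZ-normalized against the NTC wells;
    genes below -k*SD(NTC) on the one-punctum proportion are split into
    ``mtoc_gain`` (>1-punctum proportion above +k*SD) or ``mtoc_loss``
    (zero-punctum proportion above +k*SD); the rest stay ``normal``.
    When crLIS1 wells are supplied, an auxiliary flag marks genes whose
    one-punctum decrease is stronger than the crLIS1 envelope.
    """
    cols = ["p0", "p1", "pmulti"]
    for df, name in ((gene_props, "gene"), (ntc_props, "NTC")):
        sums = df[cols].sum(axis=1)
        if (np.abs(sums - 1.0) > tol).any():
            raise ValueError(f"{name} MTOC proportions do not sum to 1")

    def rz(col):
        med = ntc_props[col].median()
        mad = (ntc_props[col] - med).abs().median()
        if mad == 0:
            raise ValueError(f"NTC MAD is zero for MTOC proportion {col}")
        return (gene_props[col] - med) / (1.4826 * mad), (ntc_props[col] - med) / (1.4826 * mad)

    out = pd.DataFrame(index=gene_props.index)
    decreased = pd.Series(False, index=gene_props.index)
    category = pd.Series("normal", index=gene_props.index)
    rz1_gene, rz1_ntc = rz("p1")
    c1, h1 = sd_envelope(rz1_ntc, k)
    decreased = rz1_gene <= c1 - h1
    rz_multi_gene, rz_multi_ntc = rz("pmulti")
    cm, hm = sd_envelope(rz_multi_ntc, k)
    rz0_gene, rz0_ntc = rz("p0")
    c0, h0 = sd_envelope(rz0_ntc, k)
    category[decreased & (rz_multi_gene >= cm + hm)] = "mtoc_gain"
    category[decreased & (rz0_gene >= c0 + h0) & (category == "normal")] = "mtoc_loss"
    out["one_punctum_decreased"] = decreased
    out["category"] = category
    if lis1_props is not None:
        med = ntc_props["p1"].median()
        mad = (ntc_props["p1"] - med).abs().median()
        rz1_lis1 = (lis1_props["p1"] - med) / (1.4826 * mad)
        cl, hl = sd_envelope(rz1_lis1, k)
        out["stronger_than_crLIS1"] = rz1_gene <= cl - hl
    return out


def summarize_confirmation(n_confirmed: int, n_total: int, decimals: int = 1) -> float:
    """Confirmation percentage, rounded half-up to the stated decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_confirmed <= n_total:
        raise ValueError("n_confirmed must be between 0 and n_total")
    pct = Decimal(100) * Decimal(n_confirmed) / Decimal(n_total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def build_hit_table(
    gene_scores: pd.DataFrame,
    exclusions: pd.DataFrame,
    cargo_hits: pd.DataFrame,
    lethal: pd.Series | None = None,
    micronucleus: pd.Series | None = None,
    mtoc: pd.DataFrame | None = None,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene hit table.

    Exclusion precedes cargo calling: excluded genes never carry cargo
    hit labels. Every gene appears exactly once.
    """
    table = gene_scores.copy()
    table = table.join(exclusions[["excluded", "exclusion_reason"]])
    cargo = cargo_hits.copy()
    hit_cols = [c for c in cargo.columns if c.endswith("_hit") or c == "any_cargo_hit"]
    cargo.loc[table["excluded"].astype(bool), hit_cols] = False
    table = table.join(cargo)
    if lethal is not None:
        table["lethal"] = lethal.reindex(table.index).fillna(False).astype(bool)
    if micronucleus is not None:
        table["micronucleus_hit"] = micronucleus.reindex(table.index).fillna(False).astype(bool)
    if mtoc is not None:
        table["mtoc_category"] = mtoc["category"].reindex(table.index).fillna("normal")
    if clusters is not None:
        table["cluster"] = clusters.reindex(table.index)
    return table
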