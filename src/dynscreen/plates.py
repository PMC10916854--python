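"""Plate-level statistics: well aggregation, robust normalization and
composite endpoints.

Normalization follows standard robust screening practice, per plate and
per feature:

* rZ score: ``(x - median_NTC) / (1.4826 * MAD_NTC)`` -- deviation from
  the plate's non-targeting-control median in units of the NTC robust
  spread (1.4826 is the consistency constant making the MAD estimate
  the SD of a normal distribution);
* two-point score: linear rescaling that maps the NTC median to 0 and
  the positive-control median to a signed target (e.g., -100 for
  crLIS1-referenced cargo endpoints, +100 for crPLK1-referenced
  lethality);
* robust Z-prime: ``1 - 3*(1.4826*MAD_pos + 1.4826*MAD_neg) /
  |median_pos - median_neg|``, the assay window between the control
  distributions (1 = perfect window).

Composite endpoints combine features that individually separate the
control classes (per-feature rZ' >= 0.1) with two-class Fisher
discriminant weights, then rescale the projection to the two-point
convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

MAD_SCALE = 1.4826

WELL_KEYS = ["plate_id", "row", "col"]


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# well aggregation


def aggregate_well(
    cells: pd.DataFrame,
    feature_cols=None,
    gate: pd.Series | None = None,
    min_cells: int = 50,
) -> pd.Series:
    """Aggregate one well's cell records into a well profile.

    Features are arithmetic means over gated cells. The profile records
    ``n_cells`` (all segmented cells), ``n_viable`` (cells passing the
    gate), a ``low_count`` flag for wells under ``min_cells`` gated
    cells, and an ``excluded`` flag (profile all-NaN) when no cell
    passes the gate.
    """
    if gate is None:
        gate = pd.Series(True, index=cells.index)
    gated = cells.loc[gate]
    if feature_cols is None:
        feature_cols = [
            c
            for c in cells.columns
            if c not in WELL_KEYS and pd.api.types.is_numeric_dtype(cells[c])
        ]
    out = {"n_cells": len(cells), "n_viable": len(gated)}
    out["low_count"] = len(gated) < min_cells
    out["excluded"] = len(gated) == 0
    for c in feature_cols:
        out[c] = float(gated[c].mean()) if len(gated) else np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# robust normalization


def rz_normalize(x, median_ntc: float, mad_ntc: float, feature: str = "", plate: str = ""):
    """Robust Z score against the plate's NTC reference."""
    if mad_ntc <= 0:
        raise NormalizationError(
            f"NTC MAD is zero for feature {feature or '?'} on plate {plate or '?'}"
        )
    return (np.asarray(x, dtype=float) - median_ntc) / (MAD_SCALE * mad_ntc)


def two_point_normalize(x, med_ntc: float, med_pos: float, pos_target: float):
    """Two-point score: NTC median -> 0, positive-control median -> pos_target."""
    if med_pos == med_ntc:
        raise NormalizationError("control medians are equal: no assay window")
    return pos_target * (np.asarray(x, dtype=float) - med_ntc) / (med_pos - med_ntc)


def robust_z_prime(pos_values, neg_values) -> float:
    """Robust assay-window statistic between two control distributions."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("robust Z-prime needs >= 3 values per group")
    med_p, med_n = np.median(pos), np.median(neg)
    if med_p == med_n:
        warnings.warn("equal control medians: assay window undefined", stacklevel=2)
        return -np.inf
    spread = MAD_SCALE * (median_abs_deviation(pos) + median_abs_deviation(neg))
    return float(1.0 - 3.0 * spread / abs(med_p - med_n))


def control_stats(
    well_profiles: pd.DataFrame,
    layout: pd.DataFrame,
    features,
    neg_role: str = "NTC",
    pos_role: str = "POS_LIS1",
    min_wells: int = 3,
    drop_low_count: bool = True,
) -> pd.DataFrame:
    """Per-plate, per-feature median/MAD of control wells.

    Low-count wells are excluded from control statistics (they still get
    scored downstream). Returns a tidy frame indexed by (plate, feature)
    with NTC and positive-control medians and MADs.
    """
    if "role" in well_profiles.columns:
        df = well_profiles
    else:
        df = well_profiles.merge(layout[WELL_KEYS + ["role"]], on=WELL_KEYS)
    if drop_low_count and "low_count" in df:
        df = df[~df["low_count"].astype(bool)]
    rows = []
    for plate, plate_df in df.groupby("plate_id"):
        for role, prefix in ((neg_role, "ntc"), (pos_role, "pos")):
            group = plate_df[plate_df["role"] == role]
            if len(group) < min_wells:
                raise NormalizationError(
                    f"plate {plate}: only {len(group)} {role} wells (need >= {min_wells})"
                )
        ntc = plate_df[plate_df["role"] == neg_role]
        pos = plate_df[plate_df["role"] == pos_role]
        for feat in features:
            rows.append(
                {
                    "plate_id": plate,
                    "feature": feat,
                    "ntc_median": float(ntc[feat].median()),
                    "ntc_mad": float(median_abs_deviation(ntc[feat].dropna())),
                    "pos_median": float(pos[feat].median()),
                    "pos_mad": float(median_abs_deviation(pos[feat].dropna())),
                }
            )
    return pd.DataFrame(rows).set_index(["plate_id", "feature"])


def rz_table(
    well_profiles: pd.DataFrame,
    layout: pd.DataFrame,
    features,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """rZ-normalize well features plate-locally against NTC controls."""
    if stats is None:
        stats = control_stats(well_profiles, layout, features)
    out = well_profiles[WELL_KEYS].copy()
    for feat in features:
        vals = np.full(len(well_profiles), np.nan)
        for plate, idx in well_profiles.groupby("plate_id").groups.items():
            s = stats.loc[(plate, feat)]
            vals[well_profiles.index.get_indexer(idx)] = rz_normalize(
                well_profiles.loc[idx, feat], s["ntc_median"], s["ntc_mad"], feat, str(plate)
            )
        out[feat] = vals
    return out


# ---------------------------------------------------------------------------
# composite (LDA) endpoints


@dataclass
class CompositeEndpoint:
    """Linear composite endpoint trained on control classes."""

    name: str
    features: list
    weights: np.ndarray
    scale: float
    offset: float
    metadata: dict = field(default_factory=dict)

    def apply(self, profiles: pd.DataFrame) -> pd.Series:
        x = profiles[self.features].to_numpy(dtype=float)
        return pd.Series(self.scale * (x @ self.weights) + self.offset, index=profiles.index, name=self.name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "features": list(self.features),
                "weights": [float(w) for w in self.weights],
                "scale": self.scale,
                "offset": self.offset,
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositeEndpoint":
        d = json.loads(text)
        return cls(
            name=d["name"],
            features=d["features"],
            weights=np.asarray(d["weights"], dtype=float),
            scale=d["scale"],
            offset=d["offset"],
            metadata=d.get("metadata", {}),
        )


class EndpointError(ValueError):
    pass


def fit_lda_endpoint(
    profiles: pd.DataFrame,
    labels: pd.Series,
    candidate_features,
    name: str = "composite",
    pos_label: str = "positive",
    neg_label: str = "NTC",
    rz_prime_min: float = 0.1,
    pos_target: float = -100.0,
) -> CompositeEndpoint:
    """Fisher-discriminant composite of individually informative features.

    Candidate features are filtered to those whose single-feature robust
    Z-prime between the classes is >= ``rz_prime_min``. The discriminant
    direction is ``w = (S_w + eps I)^-1 (mu_pos - mu_neg)`` with a ridge
    ``eps = 1e-6 tr(S_w)/p``; the projection is affinely rescaled so the
    NTC median maps to 0 and the positive-control median to
    ``pos_target``.
    """
    labels = pd.Series(labels, index=profiles.index)
    pos = profiles[labels == pos_label]
    neg = profiles[labels == neg_label]
    kept, prime = [], {}
    for feat in candidate_features:
        zp = robust_z_prime(pos[feat], neg[feat])
        prime[feat] = zp
        if zp >= rz_prime_min:
            kept.append(feat)
    if not kept:
        raise EndpointError(
            f"no candidate feature reaches rZ' >= {rz_prime_min}; endpoint unbuildable"
        )
    if len(kept) == 1:
        w = np.array([1.0])
    else:
        xp = pos[kept].to_numpy(dtype=float)
        xn = neg[kept].to_numpy(dtype=float)
        sw = np.cov(xp, rowvar=False) * (len(xp) - 1) + np.cov(xn, rowvar=False) * (len(xn) - 1)
        eps = 1e-6 * np.trace(sw) / len(kept)
        w = np.linalg.solve(sw + eps * np.eye(len(kept)), xp.mean(0) - xn.mean(0))
    proj_pos = pos[kept].to_numpy(dtype=float) @ w
    proj_neg = neg[kept].to_numpy(dtype=float) @ w
    med_p, med_n = float(np.median(proj_pos)), float(np.median(proj_neg))
    if med_p == med_n:
        raise EndpointError("projected control medians coincide; endpoint unbuildable")
    scale = pos_target / (med_p - med_n)
    offset = -scale * med_n
    return CompositeEndpoint(
        name=name,
        features=kept,
        weights=w,
        scale=scale,
        offset=offset,
        metadata={"rz_prime": {k: float(v) for k, v in prime.items()}, "pos_target": pos_target},
    )


# ---------------------------------------------------------------------------
# replicate concordance and crRNA aggregation


def replicate_concordance(rep1: pd.Series, rep2: pd.Series, r2_min: float = 0.2):
    """R^2 of the least-squares fit between matched replicate scores.

    Returns ``(r_squared, usable)``; endpoints with R^2 below ``r2_min``
    are flagged unusable for hit calling.
    """
    joined = pd.concat([rep1, rep2], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("replicate concordance needs >= 3 matched pairs")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2)
    return r2, r2 >= r2_min


def aggregate_crrna(well_scores: pd.Series, pools: pd.Series | None = None):
    """Median-pool well scores per crRNA pool.

    With ``pools`` given, returns a per-pool Series; otherwise the median
    of the provided scores (a single pool).
    """
    if pools is None:
        if len(well_scores) == 0:
            raise ValueError("no contributing wells")
        return float(np.median(np.asarray(well_scores, dtype=float)))
    return well_scores.groupby(pools).median()
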