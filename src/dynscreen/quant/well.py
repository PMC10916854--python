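"""Per-well image quantification: images in, cell records out.

Combines segmentation, spot detection, ring assignment, micronucleus and
MTOC counting and texture extraction into one pass, producing a per-cell
feature table with the same column dictionary as the synthetic
feature-table generator (so downstream plate statistics run unchanged on
either path). Viability and reporter gates are *not* applied here -- they
need NTC calibration across wells and are applied at screen level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .micronuclei import detect_micronuclei
from .regions import RegionGeometry, assign_spots_to_regions
from .segment import segment_cytoplasm, segment_nuclei
from .spots import MTOC_PARAMS, SpotDetectionParams, count_mtoc_puncta, detect_spots
from .texture import FEATURE_NAMES, extract_texture_morphology


def quantify_well(
    images: dict,
    spot_channels=("GFP", "RFP", "EEA1"),
    pixel_size_um: float = 0.65,
    geometry: RegionGeometry | None = None,
    spot_params: dict | SpotDetectionParams | None = None,
    mtoc_params: SpotDetectionParams = MTOC_PARAMS,
    texture_channels=("hoechst",),
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Quantify one well's multi-channel images into per-cell records.

    ``images`` maps channel name to 2-D array and must contain
    ``hoechst``; cytoplasm context is ``tubulin`` when present, else the
    weak Hoechst background. ``spot_params`` may be a single parameter
    set or a per-channel dict (the RFP channel conventionally enables
    rolling-window background subtraction).
    """
    geometry = geometry or RegionGeometry()
    hoechst = np.asarray(images["hoechst"], dtype=float)
    nuclei = segment_nuclei(hoechst, pixel_size_um)
    context = images.get("tubulin", hoechst)
    cells_lbl, border = segment_cytoplasm(context, nuclei, pixel_size_um)
    if nuclei.max() == 0:
        return pd.DataFrame()

    if isinstance(spot_params, SpotDetectionParams) or spot_params is None:
        spot_params = {ch: (spot_params or SpotDetectionParams()) for ch in spot_channels}

    # detect spots once per channel over the full field, then split per cell
    spots_by_channel = {}
    for ch in spot_channels:
        if ch not in images:
            continue
        spots = detect_spots(images[ch], cells_lbl > 0, spot_params[ch], pixel_size_um)
        yy = np.round(spots["y"]).astype(int).clip(0, cells_lbl.shape[0] - 1)
        xx = np.round(spots["x"]).astype(int).clip(0, cells_lbl.shape[1] - 1)
        spots = spots.assign(cell=cells_lbl[yy, xx])
        spots_by_channel[ch] = spots

    records = []
    for label in range(1, int(nuclei.max()) + 1):
        nucleus_mask = nuclei == label
        cell_mask = cells_lbl == label
        if not nucleus_mask.any():
            continue
        is_border = bool(border.get(label, False))
        if exclude_border and is_border:
            continue
        area_px = float(nucleus_mask.sum())
        tex, _ = extract_texture_morphology(hoechst, nucleus_mask, pixel_size_um)
        tex_named = dict(zip(FEATURE_NAMES, tex))
        rec = {
            "cell_id": label,
            "border": is_border,
            "nucleus_area": area_px * pixel_size_um**2,
            "nucleus_roundness": tex_named["roundness"],
            "hoechst_int": float(hoechst[nucleus_mask].sum()),
        }
        for ch in ("GFP", "RFP"):
            if ch in images:
                img = np.asarray(images[ch], dtype=float)
                rec[f"{ch.lower()}_int"] = float(img[cell_mask].mean()) if cell_mask.any() else 0.0
        rec["gfp_int"] = rec.pop("gfp_int", 0.0)
        rec["rfp_int"] = rec.pop("rfp_int", 0.0)

        for ch, spots in spots_by_channel.items():
            cell_spots = spots[spots["cell"] == label]
            counts, _bands = assign_spots_to_regions(
                cell_spots, nucleus_mask, cell_mask, geometry, pixel_size_um
            )
            rec[f"{ch}_spots_total"] = int(len(cell_spots))
            for region, cnt in counts.items():
                rec[f"{ch}_spots_{region}"] = int(cnt)
            mean_int = np.asarray(images[ch], dtype=float)[cell_mask].mean() if cell_mask.any() else 0.0
            rec[f"{ch}_mean_intensity"] = float(mean_int)

        mn_count, _ = detect_micronuclei(hoechst, nucleus_mask, cell_mask, pixel_size_um)
        rec["micronucleus_count"] = mn_count
        if "gamma_tubulin" in images:
            rec["mtoc_count"] = count_mtoc_puncta(
                images["gamma_tubulin"], cell_mask, mtoc_params, pixel_size_um
            )
        for ch in texture_channels:
            if ch in images and ch != "hoechst":
                vec, _ = extract_texture_morphology(images[ch], cell_mask, pixel_size_um)
                for name, v in zip(FEATURE_NAMES, vec):
                    rec[f"{ch}_{name}"] = v
        for name, v in tex_named.items():
            rec[f"hoechst_{name}"] = v
        records.append(rec)
    return pd.DataFrame(records)
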