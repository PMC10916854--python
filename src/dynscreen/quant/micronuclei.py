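"""Micronucleus detection in the Hoechst channel.

A micronucleus is a small chromatin body outside the main nucleus: a
connected cytoplasmic region whose mean Hoechst intensity exceeds a
multiple of the local cytoplasmic background, with an area between a
minimum (to reject noise specks) and a maximum well below the nucleus
area (larger blobs are rejected as second nuclei of bi-nucleated or
mis-segmented cells).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import dilation as binary_dilation, disk

logger = logging.getLogger(__name__)


def detect_micronuclei(
    hoechst_image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float = 0.65,
    intensity_factor: float = 2.0,
    min_area_um2: float = 0.8,
    max_area_frac: float = 0.25,
    nucleus_clearance_um: float = 3.0,
):
    """Count and characterize micronuclei within one cell.

    Returns ``(count, features)`` where ``features`` is a DataFrame with
    one row per micronucleus (centroid, area in um^2, mean intensity,
    distance from the nuclear boundary in pixels-free um units).
    """
    img = np.asarray(hoechst_image, dtype=float)
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    clearance_px = max(int(round(nucleus_clearance_um / pixel_size_um)), 1)
    cyto = cell & ~binary_dilation(nucleus, disk(clearance_px))
    if not cyto.any():
        return 0, _empty_features()
    background = float(np.median(img[cyto]))
    thresh = intensity_factor * max(background, 1e-12)
    candidates = label(cyto & (img >= thresh))
    nucleus_area = float(nucleus.sum())
    min_px = min_area_um2 / pixel_size_um**2
    max_px = max_area_frac * nucleus_area
    rows = []
    rejected_large = 0
    for p in regionprops(candidates, intensity_image=img):
        if p.intensity_mean < thresh:
            continue
        if p.area < min_px:
            continue
        if p.area >= max_px:
            rejected_large += 1
            continue
        rows.append(
            {
                "y": p.centroid[0],
                "x": p.centroid[1],
                "area_um2": p.area * pixel_size_um**2,
                "mean_intensity": p.intensity_mean,
            }
        )
    if rejected_large:
        logger.warning(
            "%d supra-background blobs rejected as second nuclei (area >= %.0f%% of nucleus)",
            rejected_large,
            100 * max_area_frac,
        )
    feats = pd.DataFrame(rows) if rows else _empty_features()
    return len(feats), feats


def _empty_features() -> pd.DataFrame:
    return pd.DataFrame(columns=["y", "x", "area_um2", "mean_intensity"])
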