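"""Population gating: viability and reporter-positivity.

The viability gate removes cells with apoptotic or mitotic features or
abnormal nuclear morphology, using an envelope calibrated on the
non-targeting-control (NTC) cells of the same batch. The default
envelope is median +/- k x 1.4826 x MAD per gated feature, which stays
calibrated even when the NTC population itself contains a few percent
of dying cells; a plain quantile envelope is available as an option.

Reporter gating keeps cells positive for both the GFP and RFP reporter
constructs, with thresholds placed in the valley of the bimodal NTC
log-intensity distribution (Otsu); when the distribution is not
separable a configured absolute threshold is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

VIABILITY_FEATURES = ("nucleus_area", "nucleus_roundness", "hoechst_int")


class CalibrationError(ValueError):
    pass


@dataclass
class ViabilityCalibration:
    bounds: dict[str, tuple[float, float]]
    n_reference: int
    method: str = "mad"
    params: dict = field(default_factory=dict)


def calibrate_viability(
    ntc_cells: pd.DataFrame,
    features=VIABILITY_FEATURES,
    method: str = "mad",
    k: float = 3.5,
    quantiles: tuple[float, float] = (0.005, 0.995),
    min_cells: int = 50,
) -> ViabilityCalibration:
    """Build the per-feature viability envelope from NTC cells."""
    if len(ntc_cells) < min_cells:
        raise CalibrationError(
            f"viability calibration needs >= {min_cells} NTC cells, got {len(ntc_cells)}"
        )
    bounds = {}
    for feat in features:
        x = ntc_cells[feat].to_numpy(dtype=float)
        if method == "mad":
            med = float(np.median(x))
            spread = 1.4826 * float(median_abs_deviation(x))
            bounds[feat] = (med - k * spread, med + k * spread)
        elif method == "quantile":
            bounds[feat] = tuple(np.quantile(x, quantiles))
        else:
            raise ValueError(f"unknown calibration method {method!r}")
    return ViabilityCalibration(
        bounds=bounds,
        n_reference=len(ntc_cells),
        method=method,
        params={"k": k, "quantiles": list(quantiles)},
    )


def gate_viable(cells: pd.DataFrame, calibration: ViabilityCalibration) -> pd.Series:
    """Flag cells whose gated features all fall inside the envelope."""
    ok = pd.Series(True, index=cells.index)
    for feat, (lo, hi) in calibration.bounds.items():
        ok &= cells[feat].between(lo, hi)
    return ok


@dataclass
class ReporterThresholds:
    gfp: float
    rfp: float
    method: str = "otsu"


def calibrate_reporter(
    ntc_cells: pd.DataFrame,
    gfp_col: str = "gfp_int",
    rfp_col: str = "rfp_int",
    fallback_absolute: float = 50.0,
) -> ReporterThresholds:
    """Place GFP/RFP positivity thresholds from the bimodal NTC profile.

    Thresholds are computed by Otsu on log10 intensity. If the split is
    degenerate (either side holds <2% of cells, i.e. no separable
    negative population), the configured absolute threshold is used and
    a warning logged.
    """
    thresholds = {}
    method = "otsu"
    for name, col in (("gfp", gfp_col), ("rfp", rfp_col)):
        x = ntc_cells[col].to_numpy(dtype=float)
        x = x[x > 0]
        logx = np.log10(x)
        if logx.size < 10 or logx.max() - logx.min() < 1e-6:
            thr, method = fallback_absolute, "absolute"
        else:
            t = threshold_otsu(logx)
            lo, hi = logx[logx < t], logx[logx >= t]
            frac_low = lo.size / logx.size
            # bimodality check: the two Otsu classes must be far apart
            # relative to their spreads, otherwise the split is just the
            # middle of a unimodal distribution
            sep = (hi.mean() - lo.mean()) / np.sqrt(
                0.5 * (lo.std() ** 2 + hi.std() ** 2) + 1e-12
            ) if lo.size and hi.size else 0.0
            if frac_low < 0.02 or frac_low > 0.98 or sep < 4.0:
                logger.warning(
                    "%s intensity distribution not separable; absolute threshold used", name
                )
                thr, method = fallback_absolute, "absolute"
            else:
                thr = float(10**t)
        thresholds[name] = thr
    return ReporterThresholds(gfp=thresholds["gfp"], rfp=thresholds["rfp"], method=method)


def gate_reporter_positive(
    cells: pd.DataFrame,
    thresholds: ReporterThresholds,
    gfp_col: str = "gfp_int",
    rfp_col: str = "rfp_int",
) -> pd.Series:
    """Cells positive for both reporters (intensity above both thresholds)."""
    return (cells[gfp_col] > thresholds.gfp) & (cells[rfp_col] > thresholds.rfp)
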