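"""Render synthetic multi-channel well images with ground truth.

Cells are placed on a jittered grid (one cell per grid slot, so cell
bodies never overlap and segmentation remains testable). Per channel:

* ``hoechst`` -- nuclei as bright soft discs over a weak cytoplasmic
  background, plus small bright micronucleus discs in the cytoplasm;
* ``tubulin`` -- diffuse cytoplasm signal (the segmentation context);
* ``gamma_tubulin`` -- MTOC puncta adjacent to the nuclear envelope;
* one channel per cargo marker -- 2-D Gaussian spots whose distances
  from the nuclear boundary are drawn from the same radial mixture as
  the feature-table generator.

The returned ground truth carries nucleus/cell label masks, per-spot
coordinates with their true radial band, and micronucleus/MTOC
coordinates. Rendering is a pure function of the RNG state: a fixed
seed reproduces identical image bytes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..quant.regions import RegionGeometry, band_of_distance
from .effects import EffectSpec, NO_EFFECT
from .population import SimConfig, _effective_pi, sample_radial_distances


class RenderError(ValueError):
    pass


#: rendering amplitudes (arbitrary fluorescence units, images are float)
AMP = {
    "offset": 0.02,
    "nucleus": 1.0,
    "hoechst_cytoplasm": 0.12,
    "tubulin_cytoplasm": 0.45,
    "spot_diffuse": 0.05,
    "spot": 1.0,
    "micronucleus": 0.85,
    "mtoc": 1.0,
}

SPOT_SIGMA_UM = 0.8
MIN_SPOT_SEPARATION_UM = 2.6
EDGE_SOFTNESS_PX = 1.5


def _soft_disc(canvas, cy, cx, radius_px, amplitude):
    r = int(np.ceil(radius_px + 4 * EDGE_SOFTNESS_PX))
    y0, y1 = max(0, cy - r), min(canvas.shape[0], cy + r + 1)
    x0, x1 = max(0, cx - r), min(canvas.shape[1], cx + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rho = np.hypot(yy - cy, xx - cx)
    canvas[y0:y1, x0:x1] += amplitude / (1.0 + np.exp((rho - radius_px) / EDGE_SOFTNESS_PX))


def _gaussian_peak(canvas, y, x, sigma_px, amplitude):
    r = int(np.ceil(4 * sigma_px))
    cy, cx = int(round(y)), int(round(x))
    y0, y1 = max(0, cy - r), min(canvas.shape[0], cy + r + 1)
    x0, x1 = max(0, cx - r), min(canvas.shape[1], cx + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2)
    )


def _place_separated(rng, center, radii_px, existing, min_sep_px, n_tries=100):
    """Sample a point at given radius from center, away from existing points."""
    cy, cx = center
    for _ in range(n_tries):
        theta = rng.uniform(0, 2 * np.pi)
        y = cy + radii_px * np.sin(theta)
        x = cx + radii_px * np.cos(theta)
        if not existing or all(np.hypot(y - ey, x - ex) >= min_sep_px for ey, ex in existing):
            return y, x
    return y, x  # dense field: accept the last draw


def render_well_images(
    cells: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    effect: EffectSpec = NO_EFFECT,
    max_cells: int = 64,
    canvas_margin_px: int = 20,
):
    """Render one well's multi-channel images plus ground truth.

    ``cells`` is a per-cell record table (as produced by
    :func:`~dynscreen.synth.population.sample_cell_population`); the
    renderer uses its nucleus areas, spot totals, micronucleus and MTOC
    counts, and samples explicit spot coordinates from the radial
    mixture for the given ``effect``. Returns ``(images, truth)``.
    """
    n = len(cells)
    if n > max_cells:
        raise RenderError(f"{n} cells exceed the configured density cap ({max_cells})")
    px = config.pixel_size_um
    r_cell_px = config.cytoplasm_radius_um / px
    pitch = int(np.ceil(2 * r_cell_px + canvas_margin_px))
    if n == 0:
        shape = (128, 128)
    else:
        ncols = int(np.ceil(np.sqrt(n)))
        nrows = int(np.ceil(n / ncols))
        shape = (nrows * pitch, ncols * pitch)

    channels = ["hoechst", "tubulin", "gamma_tubulin", *config.channels]
    images = {ch: np.full(shape, AMP["offset"], dtype=float) for ch in channels}
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    geometry = RegionGeometry(
        perinuclear_um=config.band_perinuclear_um,
        intermediate_um=config.band_intermediate_um,
        outer_um=config.band_outer_um,
    )

    nuclei_rows, spot_rows, mn_rows, mtoc_rows = [], {ch: [] for ch in config.channels}, [], []
    yy_full, xx_full = np.mgrid[0 : shape[0], 0 : shape[1]]
    min_sep_px = MIN_SPOT_SEPARATION_UM / px
    sigma_px = SPOT_SIGMA_UM / px

    for i, rec in enumerate(cells.itertuples(index=False)):
        label = i + 1
        gy, gx = divmod(i, int(np.ceil(np.sqrt(n))))
        cy = gy * pitch + pitch // 2 + int(rng.integers(-canvas_margin_px // 4, canvas_margin_px // 4 + 1))
        cx = gx * pitch + pitch // 2 + int(rng.integers(-canvas_margin_px // 4, canvas_margin_px // 4 + 1))
        r_nuc_px = np.sqrt(rec.nucleus_area / np.pi) / px
        rho = np.hypot(yy_full - cy, xx_full - cx)
        nucleus_labels[rho <= r_nuc_px] = label
        cell_labels[rho <= r_cell_px] = label
        nuclei_rows.append({"label": label, "y": cy, "x": cx, "r_nuc_px": r_nuc_px, "r_cell_px": r_cell_px})

        _soft_disc(images["hoechst"], cy, cx, r_cell_px, AMP["hoechst_cytoplasm"])
        _soft_disc(images["hoechst"], cy, cx, r_nuc_px, AMP["nucleus"])
        _soft_disc(images["tubulin"], cy, cx, r_cell_px, AMP["tubulin_cytoplasm"])

        # cargo spots
        for ch in config.channels:
            n_spots = int(getattr(rec, f"{ch}_spots_total"))
            pi = _effective_pi(ch, effect, config)
            d = sample_radial_distances(n_spots, pi, config, rng)
            placed = []
            for d_um in d:
                r_px = r_nuc_px + d_um / px
                y, x = _place_separated(rng, (cy, cx), r_px, placed, min_sep_px)
                placed.append((y, x))
                amp = AMP["spot"] * rng.uniform(0.8, 1.2)
                _gaussian_peak(images[ch], y, x, sigma_px, amp)
                spot_rows[ch].append(
                    {
                        "cell": label,
                        "y": y,
                        "x": x,
                        "d_um": d_um,
                        "band": band_of_distance(d_um, geometry)[0],
                    }
                )
            _soft_disc(images[ch], cy, cx, r_cell_px, AMP["spot_diffuse"])

        # micronuclei (Hoechst channel, mid-cytoplasm)
        placed_mn = []
        for _ in range(int(rec.micronucleus_count)):
            d_um = rng.uniform(10.0, 20.0)
            y, x = _place_separated(rng, (cy, cx), r_nuc_px + d_um / px, placed_mn, 4.0 / px)
            placed_mn.append((y, x))
            _soft_disc(images["hoechst"], int(round(y)), int(round(x)), 1.2 / px, AMP["micronucleus"])
            mn_rows.append({"cell": label, "y": y, "x": x})

        # MTOC puncta adjacent to the nuclear envelope
        placed_mtoc = []
        for _ in range(int(rec.mtoc_count)):
            d_um = rng.uniform(0.5, 2.0)
            y, x = _place_separated(rng, (cy, cx), r_nuc_px + d_um / px, placed_mtoc, 3.0 / px)
            placed_mtoc.append((y, x))
            _gaussian_peak(images["gamma_tubulin"], y, x, 1.0 / px / np.sqrt(2), AMP["mtoc"])
            mtoc_rows.append({"cell": label, "y": y, "x": x})

    # noise model: additive Gaussian readout noise + Poisson shot noise
    for ch in channels:
        img = images[ch]
        if config.render_noise_photons > 0:
            img = rng.poisson(np.clip(img, 0, None) * config.render_noise_photons) / (
                config.render_noise_photons
            )
        if config.render_noise_gaussian > 0:
            img = img + rng.normal(0.0, config.render_noise_gaussian, img.shape)
        images[ch] = img

    truth = {
        "nuclei": pd.DataFrame(nuclei_rows, columns=["label", "y", "x", "r_nuc_px", "r_cell_px"]),
        "spots": {ch: pd.DataFrame(spot_rows[ch], columns=["cell", "y", "x", "d_um", "band"]) for ch in config.channels},
        "micronuclei": pd.DataFrame(mn_rows, columns=["cell", "y", "x"]),
        "mtocs": pd.DataFrame(mtoc_rows, columns=["cell", "y", "x"]),
        "nucleus_labels": nucleus_labels,
        "cell_labels": cell_labels,
    }
    return images, truth
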