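import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dynscreen.quant import (
    RegionGeometry,
    SpotDetectionParams,
    assign_spots_to_regions,
    band_of_distance,
    detect_spots,
    localization_ratio,
)
from dynscreen.quant.spots import SpotConfigError
from tests.conftest import match_spots


def gaussian_spot(canvas, y, x, sigma=1.3, amp=1.0):
    yy, xx = np.mgrid[: canvas.shape[0], : canvas.shape[1]]
    canvas += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return canvas


# ---------------------------------------------------------------- detection


def test_blank_channel_has_no_spots():
    assert len(detect_spots(np.zeros((64, 64)), pixel_size_um=1.0)) == 0


def test_well_separated_spots_all_found_within_one_pixel():
    img = np.zeros((128, 128))
    coords = [(y, x) for y in (20, 50, 80, 110) for x in (20, 60, 100)]
    for y, x in coords:
        gaussian_spot(img, y, x)
    spots = detect_spots(img, params=SpotDetectionParams(), pixel_size_um=1.0)
    truth = pd.DataFrame(coords, columns=["y", "x"])
    n, prec, rec = match_spots(spots, truth, tol_px=1.0)
    assert len(spots) == 12
    assert prec == 1.0 and rec == 1.0


def test_splitting_coefficient_merges_close_peaks():
    params = SpotDetectionParams(splitting_coefficient_um=2.0)
    close = np.zeros((64, 64))
    gaussian_spot(close, 32, 31)
    gaussian_spot(close, 32, 32.8)  # separation below the splitting distance
    assert len(detect_spots(close, params=params, pixel_size_um=1.0)) == 1
    apart = np.zeros((64, 64))
    gaussian_spot(apart, 32, 30)
    gaussian_spot(apart, 32, 33.6)  # doubled separation
    assert len(detect_spots(apart, params=params, pixel_size_um=1.0)) == 2


def test_spots_outside_mask_discarded():
    img = np.zeros((64, 64))
    gaussian_spot(img, 20, 20)
    gaussian_spot(img, 50, 50)
    mask = np.zeros((64, 64), dtype=bool)
    mask[:32, :32] = True
    spots = detect_spots(img, mask, pixel_size_um=1.0)
    assert len(spots) == 1
    assert spots["x"].iloc[0] == pytest.approx(20, abs=1)


def test_subpixel_radius_range_rejected():
    with pytest.raises(SpotConfigError):
        detect_spots(
            np.zeros((32, 32)),
            params=SpotDetectionParams(radius_min_um=0.05, radius_max_um=0.2),
            pixel_size_um=1.0,
        )


# ------------------------------------------------------------------ regions


@pytest.mark.parametrize(
    "distance, band",
    [
        (0.0, "perinuclear"),
        (-7.0, "perinuclear"),
        (7.0, "perinuclear"),
        (10.0, "intermediate"),
        (14.0, "intermediate"),
        (14.01, "outer"),
        (35.0, "outer"),
        (35.5, "out_of_range"),
        (-7.5, "out_of_range"),
    ],
)
def test_band_assignment_half_open_edges(distance, band):
    assert band_of_distance(distance)[0] == band


def test_region_counts_conserve_spots():
    rng = np.random.default_rng(0)
    nucleus = np.zeros((200, 200), dtype=bool)
    yy, xx = np.mgrid[:200, :200]
    nucleus[np.hypot(yy - 100, xx - 100) <= 15] = True
    cell = np.hypot(yy - 100, xx - 100) <= 90
    spots = pd.DataFrame({"x": rng.uniform(0, 200, 100), "y": rng.uniform(0, 200, 100)})
    counts, bands = assign_spots_to_regions(spots, nucleus, cell, pixel_size_um=1.0)
    in_cell = int((bands != "outside_cell").sum())
    assert sum(counts.values()) == in_cell
    assert in_cell + int((bands == "outside_cell").sum()) == 100


def test_region_assignment_invariant_to_translation_and_rotation():
    nucleus = np.zeros((128, 128), dtype=bool)
    yy, xx = np.mgrid[:128, :128]
    nucleus[np.hypot(yy - 50, xx - 40) <= 10] = True
    cell = np.hypot(yy - 50, xx - 40) <= 45
    spots = pd.DataFrame({"x": [40.0, 52.0, 60.0, 80.0], "y": [50.0, 50.0, 50.0, 50.0]})
    base, _ = assign_spots_to_regions(spots, nucleus, cell, pixel_size_um=1.0)
    # translate everything by (7, 11)
    t_nuc = np.roll(np.roll(nucleus, 7, axis=0), 11, axis=1)
    t_cell = np.roll(np.roll(cell, 7, axis=0), 11, axis=1)
    t_spots = spots.assign(x=spots["x"] + 11, y=spots["y"] + 7)
    trans, _ = assign_spots_to_regions(t_spots, t_nuc, t_cell, pixel_size_um=1.0)
    assert trans == base
    # rotate by 90 degrees
    r_nuc = np.rot90(nucleus)
    r_cell = np.rot90(cell)
    r_spots = spots.assign(x=spots["y"], y=127 - spots["x"])
    rot, _ = assign_spots_to_regions(r_spots, r_nuc, r_cell, pixel_size_um=1.0)
    assert rot == base


def test_two_zone_scheme_splits_by_area_fraction():
    nucleus = np.zeros((128, 128), dtype=bool)
    yy, xx = np.mgrid[:128, :128]
    nucleus[np.hypot(yy - 64, xx - 64) <= 10] = True
    cell = np.hypot(yy - 64, xx - 64) <= 50
    spots = pd.DataFrame({"x": [64.0, 70.0, 110.0], "y": [64.0, 64.0, 64.0]})
    geometry = RegionGeometry(scheme="two_zone", inner_area_frac=0.5)
    counts, bands = assign_spots_to_regions(spots, nucleus, cell, geometry, pixel_size_um=1.0)
    assert counts["inner"] == 2
    assert counts["peripheral"] == 1


# --------------------------------------------------------- localization ratio


@pytest.mark.parametrize(
    "inner, peripheral, expected",
    [(10, 10, 1.0), (9, 3, 3.0), (5, 0, 6.0), (0, 0, 1.0), (0, 4, 0.0)],
)
def test_localization_ratio_values(inner, peripheral, expected):
    assert localization_ratio(inner, peripheral) == pytest.approx(expected)


def test_localization_ratio_rejects_negative_counts():
    with pytest.raises(ValueError):
        localization_ratio(-1, 5)


@given(
    inner=st.integers(min_value=0, max_value=1000),
    peripheral=st.integers(min_value=1, max_value=1000),
    factor=st.integers(min_value=1, max_value=50),
)
def test_localization_ratio_scale_invariant(inner, peripheral, factor):
    # uniform multiplication of both counts leaves the ratio unchanged
    assert localization_ratio(inner * factor, peripheral * factor) == pytest.approx(
        localization_ratio(inner, peripheral)
    )
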