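import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from dynscreen.synth import SimConfig, render_well_images, sample_cell_population
from dynscreen.synth.effects import NO_EFFECT

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


NTC_WELL = {"plate_id": "P001", "row": 1, "col": 1, "role": "NTC"}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(cells_per_well_mean=120, seed=7)


@pytest.fixture(scope="session")
def render_config():
    # micronucleus rate raised so the rendered fixture contains examples
    return SimConfig(cells_per_well_mean=40, spot_mean=12, micronucleus_rate=0.5, seed=3)


def _render(config, noise=False):
    import dataclasses

    if noise:
        config = dataclasses.replace(
            config, render_noise_gaussian=0.02, render_noise_photons=2000
        )
    rng = np.random.default_rng(5)
    cells = sample_cell_population(NTC_WELL, NO_EFFECT, config, rng)
    cells = cells[cells.truth_viable].head(6).reset_index(drop=True)
    images, truth = render_well_images(cells, config, np.random.default_rng(7))
    return cells, images, truth


@pytest.fixture(scope="session")
def rendered_well(render_config):
    """Noise-free six-cell well with full ground truth."""
    return _render(render_config, noise=False)


@pytest.fixture(scope="session")
def noisy_well(render_config):
    """Same well rendered with shot + readout noise."""
    return _render(render_config, noise=True)


def truth_to_segmented_labels(nucleus_labels: np.ndarray, truth: dict) -> dict:
    """Map ground-truth cell labels to segmented labels via nucleus centers."""
    mapping = {}
    for rec in truth["nuclei"].itertuples(index=False):
        mapping[rec.label] = int(nucleus_labels[int(round(rec.y)), int(round(rec.x))])
    return mapping


def match_spots(detected: pd.DataFrame, truth: pd.DataFrame, tol_px: float = 2.0):
    """Greedy nearest matching; returns (n_matched, precision, recall)."""
    if len(detected) == 0:
        return 0, 1.0 if len(truth) == 0 else 0.0, 0.0 if len(truth) else 1.0
    if len(truth) == 0:
        return 0, 0.0, 1.0
    tree = cKDTree(truth[["x", "y"]].to_numpy())
    d, idx = tree.query(detected[["x", "y"]].to_numpy())
    matched_truth = set()
    n_matched = 0
    for dist, j in sorted(zip(d, idx)):
        if dist <= tol_px and j not in matched_truth:
            matched_truth.add(j)
            n_matched += 1
    return n_matched, n_matched / len(detected), n_matched / len(truth)
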