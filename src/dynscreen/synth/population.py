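"""Generative model for per-cell feature tables of a synthetic screen.

Each well draws a cell population whose readouts mimic the statistical
structure of a dynein-cargo relocalization screen:

* cell count ~ Poisson(mean x viability multiplier x well random effect);
* spots per cell per channel ~ negative binomial (mean ``spot_mean``,
  shape ``spot_dispersion``);
* each spot's distance from the nuclear boundary follows a two-component
  mixture: with probability ``pi_clustered`` an exponential decay of
  length ``decay_length_um`` (perinuclear clustering at the MTOC), else
  uniform over the cytoplasm area. Dispersion effects lower pi_c,
  hyperclustering raises it;
* micronucleus counts ~ Poisson with a class-dependent rate; MTOC counts
  multinomial over {0, 1, >=2} cells;
* a fraction of cells carries apoptotic/mitotic nuclear morphology
  (small, dense, very round nuclei) for the viability gate to remove.

Spot region counts are drawn directly from the closed-form band
probabilities of the radial mixture (distribution-identical to sampling
individual spot positions); the image renderer samples explicit
coordinates from the same mixture.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..quant.regions import localization_ratio
from .effects import (
    CONTROL_EFFECTS,
    DISPERSION_CHANNELS,
    NO_EFFECT,
    VIABILITY_MULTIPLIER,
    EffectSpec,
    GroundTruth,
)

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the synthetic-screen generative model.

    Lengths are in micrometres. Defaults reflect the screening conditions
    the generator emulates: ~1,500 cells seeded per 384-well plate well,
    four imaged fields per well, and a perinuclear-clustered spot
    distribution with a short exponential decay from the nuclear envelope.
    """

    cells_per_well_mean: float = 1500.0
    fields_per_well: int = 4
    channels: tuple = ("GFP", "RFP", "EEA1")
    # negative-binomial spot counts: var = m + m^2 / spot_dispersion
    spot_mean: float = 30.0
    spot_dispersion: float = 8.0
    # radial mixture
    pi_clustered: float = 0.70
    decay_length_um: float = 4.0
    nucleus_radius_um: float = 8.0
    cytoplasm_radius_um: float = 35.0
    # region bands (match the three-ring quantification geometry)
    band_perinuclear_um: float = 7.0
    band_intermediate_um: float = 14.0
    band_outer_um: float = 35.0
    # per-well random effects
    well_sigma_logit_pi: float = 0.10
    well_sigma_log_count: float = 0.05
    # nuclear morphology (viable vs apoptotic/mitotic-like populations)
    apoptotic_fraction: float = 0.08
    nucleus_area_mean: float = 160.0
    nucleus_area_sd: float = 25.0
    apoptotic_area_mean: float = 35.0
    apoptotic_area_sd: float = 6.0
    roundness_mean: float = 0.90
    roundness_sd: float = 0.03
    # reporter expression
    reporter_positive_fraction: float = 0.90
    reporter_intensity_mean: float = 500.0
    reporter_intensity_cv: float = 0.25
    reporter_negative_factor: float = 0.05
    # nuclear phenotypes
    micronucleus_rate: float = 0.04
    micronucleus_effect_rate: float = 0.45
    mtoc_probs: tuple = (0.08, 0.87, 0.05)
    # image rendering
    pixel_size_um: float = 0.65
    render_noise_gaussian: float = 0.0
    render_noise_photons: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pi_clustered < 1:
            raise ValueError("pi_clustered must be in (0, 1)")
        if not 0 <= self.apoptotic_fraction < 1:
            raise ValueError("apoptotic_fraction must be in [0, 1)")
        if abs(sum(self.mtoc_probs) - 1.0) > 1e-9:
            raise ValueError("mtoc_probs must sum to 1")
        if self.decay_length_um <= 0 or self.cytoplasm_radius_um <= self.nucleus_radius_um:
            raise ValueError("invalid radial geometry")


def well_rng(seed: int, plate_id, row: int, col: int) -> np.random.Generator:
    """One RNG stream per well, keyed by (seed, plate, row, col).

    Layout regeneration order therefore never changes a well's draws.
    """
    if isinstance(plate_id, str):
        plate_key = zlib.crc32(plate_id.encode())
    else:
        plate_key = int(plate_id)
    return np.random.default_rng([int(seed), plate_key, int(row), int(col)])


def band_probabilities(pi_c: float, config: SimConfig) -> np.ndarray:
    """Closed-form band probabilities of the radial spot mixture.

    Returns probabilities for (perinuclear, intermediate, outer,
    out_of_range), in the three-ring geometry measured as distance from
    the nuclear boundary. The exponential component is truncated at the
    cytoplasm edge and renormalized.
    """
    lam = config.decay_length_um
    r_n = config.nucleus_radius_um
    span = config.cytoplasm_radius_um - r_n  # max distance from the boundary
    b1, b2, b3 = (
        config.band_perinuclear_um,
        config.band_intermediate_um,
        config.band_outer_um,
    )

    def exp_cdf(x):
        x = min(x, span)
        return (1.0 - np.exp(-x / lam)) / (1.0 - np.exp(-span / lam))

    def area_cdf(x):
        x = min(x, span)
        return ((r_n + x) ** 2 - r_n**2) / ((r_n + span) ** 2 - r_n**2)

    probs = []
    for cdf in (exp_cdf, area_cdf):
        c1, c2, c3 = cdf(b1), cdf(b2), cdf(b3)
        probs.append([c1, c2 - c1, c3 - c2, 1.0 - c3])
    clustered, uniform = probs
    return pi_c * np.asarray(clustered) + (1.0 - pi_c) * np.asarray(uniform)


def sample_radial_distances(n: int, pi_c: float, config: SimConfig, rng) -> np.ndarray:
    """Sample spot distances from the nuclear boundary (for rendering)."""
    lam = config.decay_length_um
    r_n = config.nucleus_radius_um
    span = config.cytoplasm_radius_um - r_n
    clustered = rng.random(n) < pi_c
    d = np.empty(n)
    # truncated exponential via inverse CDF
    u = rng.random(n)
    d[clustered] = -lam * np.log1p(-u[clustered] * (1.0 - np.exp(-span / lam)))
    # area-uniform over the cytoplasmic annulus
    r2 = r_n**2 + u[~clustered] * ((r_n + span) ** 2 - r_n**2)
    d[~clustered] = np.sqrt(r2) - r_n
    return d


def _effective_pi(channel: str, effect: EffectSpec, config: SimConfig) -> float:
    pi = config.pi_clustered
    chans = DISPERSION_CHANNELS.get(effect.effect_class, ())
    if channel in chans:
        s = min(effect.effect_size, 1.0)
        if s != effect.effect_size:
            logger.warning(
                "effect_size %.3f for %s clamped to 1", effect.effect_size, effect.gene_id
            )
        if effect.effect_class == "hyperclustering_EEA1":
            pi = pi + (1.0 - pi) * s
        else:
            pi = pi * (1.0 - s)
    return float(np.clip(pi, 1e-4, 1.0 - 1e-4))


def _viability_multiplier(role: str, effect: EffectSpec) -> float:
    if effect.effect_class == "lethal":
        base = VIABILITY_MULTIPLIER["lethal"]
        return 1.0 - (1.0 - base) * min(effect.effect_size, 1.0)
    return VIABILITY_MULTIPLIER.get(role, 1.0)


def sample_cell_population(
    well,
    effect: EffectSpec | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the per-cell feature records of one well.

    ``well`` is a plate-layout row (needs ``plate_id, row, col, role``).
    ``effect`` defaults to the built-in control effect for control roles
    and to no effect otherwise. Columns prefixed ``truth_`` carry planted
    ground truth that downstream gates are expected to recover.
    """
    role = well["role"] if isinstance(well, (dict, pd.Series)) else well.role
    if effect is None:
        effect = CONTROL_EFFECTS.get(role, NO_EFFECT)

    viab = _viability_multiplier(role, effect)
    well_count_factor = np.exp(rng.normal(0.0, config.well_sigma_log_count))
    n = int(rng.poisson(config.cells_per_well_mean * viab * well_count_factor))
    cols: dict[str, np.ndarray] = {}

    # nuclear morphology: viable vs apoptotic/mitotic-like populations
    apoptotic = rng.random(n) < config.apoptotic_fraction
    area = np.where(
        apoptotic,
        rng.normal(config.apoptotic_area_mean, config.apoptotic_area_sd, n),
        rng.normal(config.nucleus_area_mean, config.nucleus_area_sd, n),
    )
    area = np.clip(area, 5.0, None)
    roundness = np.where(
        apoptotic,
        rng.normal(0.97, 0.015, n),
        rng.normal(config.roundness_mean, config.roundness_sd, n),
    )
    roundness = np.clip(roundness, 0.0, 1.0)
    density = np.where(apoptotic, 2.5, 1.0) * np.exp(rng.normal(0.0, 0.08, n))
    cols["truth_viable"] = ~apoptotic
    cols["nucleus_area"] = area
    cols["nucleus_roundness"] = roundness
    cols["hoechst_int"] = area * density

    # reporter expression (bimodal intensities)
    positive = rng.random(n) < config.reporter_positive_fraction
    cols["truth_reporter_positive"] = positive
    for ch_int in ("gfp_int", "rfp_int"):
        base = config.reporter_intensity_mean * np.exp(
            rng.normal(0.0, config.reporter_intensity_cv, n)
        )
        cols[ch_int] = np.where(positive, base, base * config.reporter_negative_factor)

    # spots per channel, split over radial bands
    logit_shift = rng.normal(0.0, config.well_sigma_logit_pi)
    count_factor = np.exp(rng.normal(0.0, config.well_sigma_log_count))
    k = config.spot_dispersion
    for ch in config.channels:
        pi = _effective_pi(ch, effect, config)
        pi = 1.0 / (1.0 + np.exp(-(np.log(pi / (1 - pi)) + logit_shift)))
        m = config.spot_mean * count_factor
        total = rng.negative_binomial(k, k / (k + m), n)
        p1, p2, p3, p_oor = band_probabilities(pi, config)
        peri = rng.binomial(total, p1)
        rest = total - peri
        inter = rng.binomial(rest, p2 / (1.0 - p1))
        rest2 = rest - inter
        if p_oor > 1e-12:
            outer = rng.binomial(rest2, p3 / (p3 + p_oor))
        else:
            outer = rest2
        cols[f"{ch}_spots_total"] = total
        cols[f"{ch}_spots_perinuclear"] = peri
        cols[f"{ch}_spots_intermediate"] = inter
        cols[f"{ch}_spots_outer"] = outer
        cols[f"{ch}_spots_out_of_range"] = total - peri - inter - outer
        # texture surrogates: one feature tracks the clustering state of
        # the channel, one is pure measurement noise
        cols[f"{ch}_texture_contrast"] = rng.normal(
            2.0 * (config.pi_clustered - pi), 1.0, n
        )
        cols[f"{ch}_texture_noise"] = rng.normal(0.0, 1.0, n)

    # micronuclei
    mn_rate = config.micronucleus_rate
    if effect.effect_class == "micronucleus":
        mn_rate = mn_rate + config.micronucleus_effect_rate * min(effect.effect_size, 1.0)
    cols["micronucleus_count"] = rng.poisson(mn_rate, n)

    # MTOC counts over {0, 1, >=2}
    p = np.asarray(config.mtoc_probs, dtype=float)
    s = min(effect.effect_size, 1.0)
    if effect.effect_class == "mtoc_loss":
        p = (1 - s) * p + s * np.array([0.75, 0.20, 0.05])
    elif effect.effect_class == "mtoc_gain":
        p = (1 - s) * p + s * np.array([0.05, 0.25, 0.70])
    cols["mtoc_count"] = rng.choice([0, 1, 2], size=n, p=p / p.sum())

    df = pd.DataFrame(cols)
    df.insert(0, "plate_id", well["plate_id"])
    df.insert(1, "row", well["row"])
    df.insert(2, "col", well["col"])
    return df


def simulate_screen(
    layout: pd.DataFrame, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Simulate cell tables for every well of a layout.

    Each well uses an independent RNG stream keyed by
    ``(seed, plate, row, col)``, so any well can be regenerated in
    isolation. Realized per-well cell counts are recorded in ``truth``.
    """
    frames = []
    for well in layout.itertuples(index=False):
        rng = well_rng(config.seed, well.plate_id, well.row, well.col)
        if well.role == "LIBRARY":
            effect = truth.effect_for(well.gene)
        else:
            effect = CONTROL_EFFECTS.get(well.role, NO_EFFECT)
        cells = sample_cell_population(well._asdict(), effect, config, rng)
        truth.well_cell_counts[(well.plate_id, well.row, well.col)] = len(cells)
        frames.append(cells)
    return pd.concat(frames, ignore_index=True)


def well_log_loc_ratio(cells: pd.DataFrame, channel: str) -> float:
    """Log of the well-mean localization ratio (perinuclear vs outside).

    The log is taken after averaging over cells: per-cell ratios can be
    zero, but the well mean over a realistic population is strictly
    positive, and the log makes the endpoint distribution symmetric.
    """
    inner = cells[f"{channel}_spots_perinuclear"].to_numpy()
    periph = (
        cells[f"{channel}_spots_intermediate"].to_numpy()
        + cells[f"{channel}_spots_outer"].to_numpy()
    )
    return float(np.log(np.mean(localization_ratio(inner, periph))))


def calibrate_dispersion_effect(
    config: SimConfig,
    target_sd_multiple: float,
    channel: str = "EEA1",
    dispersion_class: str = "dispersion_all",
    n_ntc_wells: int = 120,
    cells_per_eval: int = 4000,
    seed: int = 0,
) -> float:
    """Find the effect size shifting the well endpoint by k NTC SDs.

    The endpoint is the log of the well-mean localization ratio.
    NTC well-to-well spread is estimated by simulation under ``config``;
    the dispersion effect size is then solved by bisection on the
    expected endpoint (evaluated with common random numbers, no
    well-level noise) so the true shift equals
    ``target_sd_multiple x SD(NTC wells)``.
    """
    ntc_well = {"plate_id": "CAL", "row": 1, "col": 1, "role": "NTC"}
    vals = []
    for i in range(n_ntc_wells):
        rng = np.random.default_rng([seed, 555, i])
        cells = sample_cell_population(ntc_well, NO_EFFECT, config, rng)
        vals.append(well_log_loc_ratio(cells, channel))
    m0, s0 = float(np.mean(vals)), float(np.std(vals, ddof=1))
    target = m0 - target_sd_multiple * s0

    eval_cfg = dataclasses.replace(
        config,
        well_sigma_logit_pi=0.0,
        well_sigma_log_count=0.0,
        cells_per_well_mean=float(cells_per_eval),
        apoptotic_fraction=0.0,
    )

    def endpoint(size: float) -> float:
        rng = np.random.default_rng([seed, 777])
        eff = EffectSpec("CAL", dispersion_class, size)
        cells = sample_cell_population(ntc_well, eff, eval_cfg, rng)
        return well_log_loc_ratio(cells, channel)

    lo, hi = 0.0, 1.0
    if endpoint(1.0) > target:
        logger.warning("target shift unreachable; effect size clamped to 1")
        return 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if endpoint(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
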