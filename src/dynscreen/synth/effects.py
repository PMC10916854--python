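"""Planted phenotype classes and ground truth for synthetic screens.

Each library gene is assigned an :class:`EffectSpec` describing how its
disruption perturbs the generative model: dispersion of all cargoes or of
a single cargo, excessive perinuclear clustering of early endosomes,
lethality, micronucleus induction, or loss/gain of MTOCs. Control wells
carry built-in effects (crLIS1 = cargo dispersion plus a mild viability
loss; crPLK1 = near-total loss of viable cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EFFECT_CLASSES = (
    "none",
    "dispersion_all",
    "dispersion_PEX_only",
    "dispersion_EEA1_only",
    "hyperclustering_EEA1",
    "lethal",
    "micronucleus",
    "mtoc_loss",
    "mtoc_gain",
)

#: cargo channels affected by each dispersion-type class
DISPERSION_CHANNELS = {
    "dispersion_all": ("GFP", "RFP", "EEA1", "TGN46", "LAMP1"),
    "dispersion_PEX_only": ("GFP", "RFP"),
    "dispersion_EEA1_only": ("EEA1",),
    "hyperclustering_EEA1": ("EEA1",),
}


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect for one gene (or control pool).

    ``effect_size`` is a dimensionless multiplier in [0, 1] acting on the
    generative parameter the class perturbs: for dispersion classes the
    clustered fraction pi_c is scaled by ``1 - effect_size``; for
    hyperclustering pi_c is pushed toward 1 by the same amount; lethality
    and the other classes use class-specific parameter maps in the
    population sampler.
    """

    gene_id: str
    effect_class: str = "none"
    effect_size: float = 0.0
    module_id: str | None = None

    def __post_init__(self):
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


NO_EFFECT = EffectSpec(gene_id="", effect_class="none")

#: built-in control effects; magnitudes are generator defaults, chosen so
#: crLIS1 gives a strong but sub-maximal dispersion plus partial viability
#: loss and crPLK1 removes nearly all viable cells.
CONTROL_EFFECTS = {
    "POS_LIS1": EffectSpec("crLIS1", "dispersion_all", 0.85),
    "EDIT_PLK1": EffectSpec("crPLK1", "lethal", 1.0),
    "NOCODAZOLE": EffectSpec("NOC", "dispersion_all", 0.95),
    "NTC": NO_EFFECT,
    "VEHICLE": NO_EFFECT,
}

#: viability multipliers on the mean well cell count, per effect class /
#: control role; the lethal class leaves <= 10% of the NTC cell count.
VIABILITY_MULTIPLIER = {"lethal": 0.05, "POS_LIS1": 0.70}


@dataclass
class GroundTruth:
    """Planted truth for a synthetic screen.

    ``genes`` maps every library gene to its effect; ``well_cell_counts``
    is filled in by the screen simulator with the realized per-well cell
    count (keyed by ``(plate_id, row, col)``).
    """

    genes: dict[str, EffectSpec]
    well_cell_counts: dict[tuple, int] = field(default_factory=dict)

    def effect_for(self, gene_id: str) -> EffectSpec:
        return self.genes.get(gene_id, NO_EFFECT)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, e.effect_class, e.effect_size, e.module_id or "")
            for g, e in sorted(self.genes.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "effect_class", "effect_size", "module_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        genes = {
            r.gene: EffectSpec(r.gene, r.effect_class, float(r.effect_size), r.module_id or None)
            for r in df.itertuples()
        }
        return cls(genes=genes)


def plant_effects(
    library_genes,
    rng,
    dispersion_frac: float = 0.10,
    lethal_frac: float = 0.05,
    micronucleus_frac: float = 0.0,
    mtoc_loss_frac: float = 0.0,
    mtoc_gain_frac: float = 0.0,
    dispersion_class: str = "dispersion_all",
    effect_size: float = 0.5,
    lethal_effect_size: float = 1.0,
    other_effect_size: float = 1.0,
) -> GroundTruth:
    """Randomly assign planted effect classes over the library genes.

    Fractions are of the total gene list and must sum to <= 1; the
    remainder is assigned ``none``. ``effect_size`` applies to the
    dispersion class (it is typically calibrated to a target endpoint
    shift); lethality and the nuclear/MTOC classes use their own sizes,
    defaulting to full-strength phenotypes. Assignment order
    (dispersion, lethal, micronucleus, mtoc_loss, mtoc_gain) over a
    single RNG permutation keeps the draw deterministic under a fixed
    seed.
    """
    genes = list(dict.fromkeys(library_genes))
    fracs = [dispersion_frac, lethal_frac, micronucleus_frac, mtoc_loss_frac, mtoc_gain_frac]
    if sum(fracs) > 1 + 1e-9:
        raise ValueError("planted-effect fractions sum to more than 1")
    classes = [dispersion_class, "lethal", "micronucleus", "mtoc_loss", "mtoc_gain"]
    sizes = [effect_size, lethal_effect_size] + [other_effect_size] * 3
    perm = rng.permutation(len(genes))
    truth: dict[str, EffectSpec] = {}
    i = 0
    for cls_name, frac, size in zip(classes, fracs, sizes):
        n = int(round(frac * len(genes)))
        for j in perm[i : i + n]:
            truth[genes[j]] = EffectSpec(genes[j], cls_name, size)
        i += n
    for j in perm[i:]:
        truth[genes[j]] = EffectSpec(genes[j], "none", 0.0)
    return GroundTruth(genes=truth)


def sample_module_fingerprints(
    rng,
    n_modules: int = 6,
    genes_per_module: int = 8,
    n_features: int = 60,
    separation: float = 3.0,
    noise_sd: float = 1.0,
):
    """Sample phenotypic fingerprints with planted co-functional modules.

    Genes within a module share one effect direction (per-feature loadings
    drawn once per module with SD ``separation * noise_sd``) and receive
    independent Gaussian noise. ``separation`` is therefore the
    module-signal : noise SD ratio.

    Returns ``(fingerprints, labels)`` where fingerprints is a genes x
    features DataFrame and labels a Series of module ids.
    """
    directions = rng.normal(0.0, separation * noise_sd, size=(n_modules, n_features))
    rows, labels, names = [], [], []
    for m in range(n_modules):
        for g in range(genes_per_module):
            rows.append(directions[m] + rng.normal(0.0, noise_sd, n_features))
            labels.append(f"M{m + 1}")
            names.append(f"G{m + 1:02d}_{g + 1:02d}")
    fp = pd.DataFrame(
        np.asarray(rows), index=names, columns=[f"f{i:03d}" for i in range(n_features)]
    )
    return fp, pd.Series(labels, index=names, name="module")
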