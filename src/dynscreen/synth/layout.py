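"""384-well plate layouts for arrayed CRISPR screens.

A plate has 16 rows x 24 columns. Each well carries a reagent role:
non-targeting control (NTC), the LIS1-targeting positive control
(POS_LIS1), the PLK1-targeting editing/lethality control (EDIT_PLK1),
a library crRNA pool, or a chemical control (nocodazole / vehicle).
The default control design mirrors a genome-wide dynein-cargo screen:
38 NTC, 13 crLIS1 and 13 crPLK1 wells per plate, with the remaining
320 wells taken by library pools.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24
N_WELLS = N_ROWS * N_COLS

ROLES = ("NTC", "POS_LIS1", "EDIT_PLK1", "LIBRARY", "NOCODAZOLE", "VEHICLE")

#: wells per plate for each control role in the genome-wide screen design
DEFAULT_CONTROL_DESIGN = {"NTC": 38, "POS_LIS1": 13, "EDIT_PLK1": 13}

CONTROL_POOLS = {
    "NTC": "NTC",
    "POS_LIS1": "crLIS1",
    "EDIT_PLK1": "crPLK1",
    "NOCODAZOLE": "NOC",
    "VEHICLE": "DMSO",
}

LAYOUT_COLUMNS = ["plate_id", "row", "col", "role", "crrna_pool", "gene"]


class LayoutConfigError(ValueError):
    """Raised when a control design cannot fit on a 384-well plate."""


def generate_plate_layout(
    library_genes,
    n_plates: int = 1,
    control_design: dict | None = None,
    wells_per_gene: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate deterministic plate layouts with dispersed control wells.

    Parameters
    ----------
    library_genes : sequence of str
        Genes to distribute over the library wells. Each gene occupies
        ``wells_per_gene`` consecutive library wells; the list is recycled
        across plates when the screen has more library wells than genes.
    n_plates : int
        Number of 384-well plates.
    control_design : dict, optional
        Mapping role -> wells per plate. Defaults to
        :data:`DEFAULT_CONTROL_DESIGN`.
    wells_per_gene : int
        Replicate wells per library crRNA pool.
    seed : int
        Seed for the per-plate RNG that disperses control positions.

    Returns
    -------
    pandas.DataFrame
        Columns ``plate_id, row, col, role, crrna_pool, gene`` with
        ``n_plates * 384`` rows.
    """
    control_design = dict(DEFAULT_CONTROL_DESIGN if control_design is None else control_design)
    for role in control_design:
        if role not in ROLES or role == "LIBRARY":
            raise LayoutConfigError(f"unknown control role: {role!r}")
        if control_design[role] < 0:
            raise LayoutConfigError(f"negative well count for role {role!r}")
    n_control = sum(control_design.values())
    if n_control > N_WELLS:
        raise LayoutConfigError(
            f"control design occupies {n_control} wells; a plate has {N_WELLS}"
        )
    n_library = N_WELLS - n_control
    library_genes = list(library_genes)
    if n_library > 0 and not library_genes:
        raise LayoutConfigError("library wells present but no library genes supplied")
    if wells_per_gene < 1:
        raise LayoutConfigError("wells_per_gene must be >= 1")

    # one entry per library well, cycling through the gene list
    gene_cycle = itertools.cycle(
        g for g in library_genes for _ in range(wells_per_gene)
    )

    positions = [(r, c) for r in range(1, N_ROWS + 1) for c in range(1, N_COLS + 1)]
    records = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        rng = np.random.default_rng([seed, p])
        order = rng.permutation(N_WELLS)
        roles = np.empty(N_WELLS, dtype=object)
        roles[:] = "LIBRARY"
        i = 0
        for role, count in control_design.items():
            roles[order[i : i + count]] = role
            i += count
        for (row, col), role in zip(positions, roles):
            if role == "LIBRARY":
                gene = next(gene_cycle)
                pool = f"cr{gene}"
            else:
                gene = ""
                pool = CONTROL_POOLS[role]
            records.append((plate_id, row, col, role, pool, gene))
    return pd.DataFrame(records, columns=LAYOUT_COLUMNS)


def validate_layout(layout: pd.DataFrame) -> list[str]:
    """Return a list of schema violations (empty when the layout is valid)."""
    errors: list[str] = []
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        return [f"missing columns: {missing}"]
    if not layout["row"].between(1, N_ROWS).all():
        errors.append(f"row values outside 1..{N_ROWS}")
    if not layout["col"].between(1, N_COLS).all():
        errors.append(f"col values outside 1..{N_COLS}")
    dup = layout.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        errors.append(f"{int(dup.sum())} duplicate (plate, row, col) positions")
    bad_roles = set(layout["role"]) - set(ROLES)
    if bad_roles:
        errors.append(f"unknown roles: {sorted(bad_roles)}")
    lib = layout[layout["role"] == "LIBRARY"]
    if (lib["gene"].astype(str) == "").any():
        errors.append("LIBRARY wells with empty gene_id")
    for plate_id, plate in layout.groupby("plate_id"):
        if len(plate) != N_WELLS:
            errors.append(f"plate {plate_id} has {len(plate)} wells, expected {N_WELLS}")
    return errors
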