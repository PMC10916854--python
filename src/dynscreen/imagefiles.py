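"""Well-image file interface: multi-page TIFF + channel-map sidecar.

Each well is stored as one multi-page TIFF (one page per channel, float32)
with a JSON sidecar of the same stem recording the channel order, the
pixel size and the well address, so the channel order is never implicit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def well_stem(plate_id: str, row: int, col: int) -> str:
    return f"{plate_id}_r{int(row):02d}_c{int(col):02d}"


def write_well_images(
    images: dict,
    directory,
    plate_id: str,
    row: int,
    col: int,
    pixel_size_um: float,
) -> Path:
    """Write one well's channels as a multi-page TIFF + sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = list(images)
    stack = np.stack([np.asarray(images[ch], dtype=np.float32) for ch in channels])
    path = directory / f"{well_stem(plate_id, row, col)}.tif"
    tifffile.imwrite(path, stack)
    sidecar = {
        "plate_id": plate_id,
        "row": int(row),
        "col": int(col),
        "channels": channels,
        "pixel_size_um": pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_well_images(tiff_path):
    """Read a well TIFF written by :func:`write_well_images`.

    Returns ``(images, meta)`` where ``images`` maps channel name to a
    2-D float array and ``meta`` is the sidecar dict.
    """
    tiff_path = Path(tiff_path)
    sidecar = tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing channel-map sidecar for {tiff_path}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    if len(meta["channels"]) != len(stack):
        raise ValueError(
            f"{tiff_path}: sidecar lists {len(meta['channels'])} channels, "
            f"TIFF has {len(stack)} pages"
        )
    images = {ch: np.asarray(page, dtype=float) for ch, page in zip(meta["channels"], stack)}
    return images, meta
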