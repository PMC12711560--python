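"""Tagged-grid file round-tripping.

Layers are stored as single-band float32 TIFF with nodata encoded as NaN and
the grid metadata (tag, cell area, optional categorical level registry) in a
JSON document carried in the image description tag. Values survive the
round trip bit-exactly for float32 payloads; the mask and tags always do.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import WildmeatError
from .grids import Grid


def write_grid(grid: Grid, path: str | Path, levels: dict[int, str] | None = None) -> Path:
    """Write a grid to ``path`` as float32 TIFF with JSON metadata."""
    path = Path(path)
    payload = grid.values.astype(np.float32)
    payload = np.where(grid.mask, np.float32(np.nan), payload)
    meta = {"tag": grid.tag, "cell_area": grid.cell_area, "nodata": "nan"}
    if levels is not None:
        meta["levels"] = {str(k): v for k, v in levels.items()}
    try:
        tifffile.imwrite(path, payload, description=json.dumps(meta))
    except OSError as exc:
        raise WildmeatError(f"cannot write grid to {path}: {exc}") from exc
    return path


def read_grid(path: str | Path) -> tuple[Grid, dict[int, str] | None]:
    """Read a grid written by :func:`write_grid`; returns (grid, levels)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            payload = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
    except (OSError, ValueError) as exc:
        raise WildmeatError(f"cannot read grid from {path}: {exc}") from exc
    mask = np.isnan(payload)
    values = np.where(mask, 0.0, payload).astype(float)
    grid = Grid(values, mask, float(meta.get("cell_area", 100.0)), str(meta.get("tag", "")))
    levels = meta.get("levels")
    if levels is not None:
        levels = {int(k): v for k, v in levels.items()}
    return grid, levels
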