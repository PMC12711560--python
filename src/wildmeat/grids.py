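"""Gridded-landscape bookkeeping.

All spatial quantities live on a common rectangular lattice of square cells
(nominally 10 x 10 km, i.e. 100 km^2 per cell). A :class:`Grid` couples a 2D
float array with a nodata mask; a :class:`GridStack` bundles the covariate
layers of one landscape, distinguishing static layers, time-varying layers
(held at a set of epoch snapshots) and categorical layers (integer level
codes plus a level registry).

Real-world reprojection and resampling are out of scope: layers are required
to arrive pre-aligned on the common lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    AlignmentError,
    EpochLookupError,
    ExtractionError,
)

DEFAULT_CELL_AREA_KM2 = 100.0

#: Epoch snapshots available for the time-varying covariates: habitat loss
#: has 5-year snapshots from 1985, the productivity/greenness layers from 2000.
DEFAULT_EPOCHS: dict[str, tuple[int, ...]] = {
    "habitat_loss": tuple(range(1985, 2021, 5)),
    "evi": tuple(range(2000, 2021, 5)),
    "gpp": tuple(range(2000, 2021, 5)),
    "npp": tuple(range(2000, 2021, 5)),
}


@dataclass
class Grid:
    """A single 2D layer with nodata mask and physical cell area.

    Parameters
    ----------
    values : 2D float array. Entries under the mask are ignored.
    mask : 2D bool array, True where the cell carries no data.
    cell_area : cell area in km^2 (default 100, i.e. a 10 x 10 km cell).
    tag : layer name.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    cell_area: float = DEFAULT_CELL_AREA_KM2
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise AlignmentError(
                    f"mask shape {self.mask.shape} != values shape {self.values.shape}"
                )
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError(f"non-finite values outside mask in layer {self.tag!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.mask.copy(), self.cell_area, self.tag)

    def total(self) -> float:
        """Sum of unmasked cell values."""
        return float(self.values[~self.mask].sum())

    def with_values(self, values: np.ndarray, tag: str | None = None) -> "Grid":
        return Grid(values, self.mask.copy(), self.cell_area,
                    self.tag if tag is None else tag)


def require_aligned(*grids: Grid) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise AlignmentError(f"grids not on a common lattice: shapes {sorted(shapes)}")
    areas = {g.cell_area for g in grids}
    if len(areas) > 1:
        raise AlignmentError(f"grids disagree on cell area: {sorted(areas)}")


@dataclass
class GridStack:
    """Aligned covariate layers of one landscape.

    ``static`` maps tag -> Grid; ``temporal`` maps tag -> {epoch year -> Grid};
    ``levels`` registers categorical layers as tag -> {code -> label}.
    """

    static: dict[str, Grid] = field(default_factory=dict)
    temporal: dict[str, dict[int, Grid]] = field(default_factory=dict)
    levels: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        require_aligned(*self.all_grids())

    def all_grids(self) -> list[Grid]:
        out = list(self.static.values())
        for snaps in self.temporal.values():
            out.extend(snaps.values())
        return out

    @property
    def shape(self) -> tuple[int, int]:
        return self.all_grids()[0].shape

    @property
    def tags(self) -> list[str]:
        return list(self.static) + list(self.temporal)

    def epoch_table(self) -> dict[str, tuple[int, ...]]:
        return {tag: tuple(sorted(snaps)) for tag, snaps in self.temporal.items()}

    def layer(self, tag: str, epoch: int | None = None) -> Grid:
        if tag in self.static:
            return self.static[tag]
        if tag in self.temporal:
            snaps = self.temporal[tag]
            if epoch is None:
                epoch = max(snaps)
            if epoch not in snaps:
                raise EpochLookupError(f"layer {tag!r} has no epoch {epoch}")
            return snaps[epoch]
        raise KeyError(f"no layer tagged {tag!r}")

    def is_categorical(self, tag: str) -> bool:
        return tag in self.levels


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def gap_fill(grid: Grid, max_passes: int = 50) -> Grid:
    """Fill nodata cells from the mean of their available 8-neighbours.

    Passes are applied Jacobi-style: on each pass every still-missing cell
    with at least one available neighbour receives the mean of the available
    neighbour values, and becomes available for the next pass. Iteration
    stops at convergence (no fillable cell remains) or after ``max_passes``.
    Observed cells are never altered; cells that no pass can reach stay
    masked. Because each fill is an average of earlier values, filled cells
    never exceed the observed min/max (discrete maximum principle).
    """
    values = grid.values.copy()
    available = ~grid.mask
    for _ in range(max_passes):
        if available.all():
            break
        padded = np.where(available, values, 0.0)
        neigh_sum = ndimage.convolve(padded, _NEIGHBOUR_KERNEL, mode="constant")
        neigh_n = ndimage.convolve(
            available.astype(float), _NEIGHBOUR_KERNEL, mode="constant"
        )
        fillable = ~available & (neigh_n > 0)
        if not fillable.any():
            break
        values[fillable] = neigh_sum[fillable] / neigh_n[fillable]
        available |= fillable
    values[~available] = np.nan
    values = np.where(available, values, 0.0)
    return Grid(values, ~available, grid.cell_area, grid.tag)


# ---------------------------------------------------------------------------
# Epoch matching
# ---------------------------------------------------------------------------

def match_epoch(
    record_year: int,
    tag: str,
    epoch_table: Mapping[str, Sequence[int]] | None = None,
) -> int:
    """Snap a record year to the nearest available covariate snapshot.

    Years earlier than the first epoch clamp to it (e.g. a 1966 record uses
    the 1985 habitat-loss snapshot) and years past the last epoch clamp to
    the last (post-2018 records use 2020); in between, the nearest epoch
    wins (1991 -> 1990, 2001 -> 2000).
    """
    table = DEFAULT_EPOCHS if epoch_table is None else epoch_table
    if tag not in table:
        raise EpochLookupError(f"no epoch entry for variable {tag!r}")
    epochs = np.asarray(sorted(table[tag]))
    if epochs.size == 0:
        raise EpochLookupError(f"variable {tag!r} has an empty epoch list")
    idx = int(np.argmin(np.abs(epochs - record_year)))
    return int(epochs[idx])


# ---------------------------------------------------------------------------
# Rural population (APPS) and rural hunters (RHPS)
# ---------------------------------------------------------------------------

def derive_apps(population: Grid, urban_mask: np.ndarray, boundary_mask: np.ndarray) -> Grid:
    """Rural population grid: total population with urban cells removed.

    Cells outside the study boundary are masked; urban cells inside it are
    zeroed. The unmasked total therefore never exceeds the population total.
    """
    urban_mask = np.asarray(urban_mask, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if urban_mask.shape != population.shape or boundary_mask.shape != population.shape:
        raise AlignmentError("urban/boundary masks must match the population grid")
    values = np.where(boundary_mask & ~urban_mask, population.values, 0.0)
    mask = population.mask | ~boundary_mask
    values = np.where(mask, 0.0, values)
    return Grid(values, mask, population.cell_area, "apps")


def derive_rhps(apps: Grid, ratios: Mapping[str, float]) -> dict[str, Grid]:
    """Rural-hunter grids: APPS scaled by each hunters-to-consumers ratio.

    One grid per ratio quantile (the headline uses the median ratio). Totals
    scale exactly linearly: total hunters = ratio x total APPS.
    """
    out: dict[str, Grid] = {}
    for label, ratio in ratios.items():
        # ratio 0 is allowed as a degenerate no-hunters scenario
        if not 0.0 <= ratio < 1.0:
            raise ValueError(
                f"hunters-to-consumers ratio {label!r}={ratio} outside [0, 1)"
            )
        out[label] = apps.with_values(apps.values * ratio, tag=f"rhps_{label}")
    return out


# ---------------------------------------------------------------------------
# Feature extraction at localities
# ---------------------------------------------------------------------------

def extract_features(
    stack: GridStack,
    localities: pd.DataFrame,
    years: pd.Series | Mapping | None = None,
    epoch_table: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Extract every covariate at each locality, one row per locality x year.

    ``localities`` needs columns ``locality_id``, ``row``, ``col``. ``years``
    maps locality_id to one or more record years (default: a single row per
    locality at the latest epoch). Time-varying layers are resolved per year
    via :func:`match_epoch`; categorical layers come back as integer level
    codes. A locality on a masked cell raises :class:`ExtractionError`.
    """
    table = stack.epoch_table() if epoch_table is None else epoch_table
    rows = []
    for loc in localities.itertuples(index=False):
        r, c = int(loc.row), int(loc.col)
        if years is None:
            loc_years = [max(max(v) for v in table.values())] if table else [0]
        else:
            y = years[loc.locality_id] if not isinstance(years, pd.Series) else years.loc[loc.locality_id]
            loc_years = list(np.atleast_1d(y))
        for year in loc_years:
            feat: dict[str, object] = {"locality_id": loc.locality_id, "year": int(year)}
            for tag, grid in stack.static.items():
                if grid.mask[r, c]:
                    raise ExtractionError(
                        f"locality {loc.locality_id!r} falls on a masked cell of {tag!r}"
                    )
                value = grid.values[r, c]
                feat[tag] = int(value) if stack.is_categorical(tag) else float(value)
            for tag in stack.temporal:
                epoch = match_epoch(int(year), tag, table)
                grid = stack.temporal[tag][epoch]
                if grid.mask[r, c]:
                    raise ExtractionError(
                        f"locality {loc.locality_id!r} falls on a masked cell of {tag!r}"
                    )
                feat[tag] = float(grid.values[r, c])
            rows.append(feat)
    return pd.DataFrame(rows)
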