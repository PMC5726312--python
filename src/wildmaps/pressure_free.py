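"""Delineation of pressure-free lands (wilderness) per epoch.

Wilderness is every contiguous region of cells completely free of mapped
human pressure (score 0) whose area exceeds 10,000 km^2.  Large zero regions
separated by even a thin line of nonzero cells are discrete blocks, each
filtered on its own area.

Because wilderness, once lost, is effectively unrestorable, the 2009 map is
made temporally comparable with 1993 by excluding, at cell level, every
location that carried pressure in 1993 but none in 2009; the maps then
measure loss, never apparent gain.  Antarctica and other excluded regions
are represented as nodata in the input grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_core import (
    DEFAULT_CONNECTIVITY,
    MIN_BLOCK_AREA_KM2,
    Block,
    GridError,
    PressureGrid,
    label_components,
)


@dataclass
class WildernessMap:
    """Pressure-free lands for one epoch (optionally temporally comparable)."""

    epoch: str
    variant: str                      # "1993" | "2009_comparable" | free-form
    blocks: list[Block]
    min_area_km2: float
    source_epochs: tuple[str, ...]
    grid_shape: tuple[int, int]
    connectivity: int = DEFAULT_CONNECTIVITY

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def total_area_km2(self) -> float:
        return float(sum(b.area_km2 for b in self.blocks))

    def cell_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for b in self.blocks:
            m[b.cells[:, 0], b.cells[:, 1]] = True
        return m


def _filter_blocks(blocks: list[Block], min_area_km2: float) -> list[Block]:
    # strict ">": a block of exactly min_area_km2 is excluded
    return [b for b in blocks if b.area_km2 > min_area_km2]


def map_pressure_free(
    grid: PressureGrid,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_area_km2: float = MIN_BLOCK_AREA_KM2,
    variant: str | None = None,
) -> WildernessMap:
    """Map wilderness as contiguous score-0 regions larger than the threshold.

    Components are labeled before the size filter, so a zero region split by
    a nonzero line yields separate blocks, each judged on its own area.
    """
    blocks = label_components(
        grid.zero_mask(),
        connectivity=connectivity,
        cell_area_km2=grid.cell_area_km2,
        epoch=grid.epoch,
    )
    return WildernessMap(
        epoch=grid.epoch,
        variant=variant if variant is not None else grid.epoch,
        blocks=_filter_blocks(blocks, min_area_km2),
        min_area_km2=min_area_km2,
        source_epochs=(grid.epoch,),
        grid_shape=grid.shape,
        connectivity=connectivity,
    )


def comparable_2009_mask(grid_1993: PressureGrid, grid_2009: PressureGrid) -> np.ndarray:
    """Cells pressure free in both epochs.

    True exactly where both scores are 0: a cell with pressure in 1993 but
    none in 2009 is excluded, so the later map never shows apparent
    wilderness gain.  The grids must share extent and nodata mask.
    """
    if grid_1993.shape != grid_2009.shape:
        raise GridError("epoch grids differ in extent")
    if not np.array_equal(grid_1993.land_mask, grid_2009.land_mask):
        raise GridError("epoch grids differ in nodata mask")
    return grid_1993.zero_mask() & grid_2009.zero_mask()


def map_pressure_free_comparable(
    grid_1993: PressureGrid,
    grid_2009: PressureGrid,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_area_km2: float = MIN_BLOCK_AREA_KM2,
) -> WildernessMap:
    """Temporally comparable 2009 wilderness map.

    The exclusion is applied at cell level before labeling, so blocks may
    split or shrink relative to the raw 1993 map — the intended behaviour.
    """
    mask = comparable_2009_mask(grid_1993, grid_2009)
    blocks = label_components(
        mask,
        connectivity=connectivity,
        cell_area_km2=grid_2009.cell_area_km2,
        epoch=grid_2009.epoch,
    )
    return WildernessMap(
        epoch=grid_2009.epoch,
        variant="2009_comparable",
        blocks=_filter_blocks(blocks, min_area_km2),
        min_area_km2=min_area_km2,
        source_epochs=(grid_1993.epoch, grid_2009.epoch),
        grid_shape=grid_2009.shape,
        connectivity=connectivity,
    )
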