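"""Grid data model, score truncation, contiguity analysis and area accounting.

The Human Footprint is a globally standardised index of cumulative human
pressure: eight pressure layers (built environments, crop lands, pasture,
population density, night lights, railways, roads, navigable waterways) each
scored 0-10 and summed, giving an integer 0-50 per ~1 km^2 grid cell.  All
downstream mapping stages (pressure-free wilderness, Last of the Wild) work
on this integer raster, so the shared data model lives here:

* :class:`PressureGrid` -- the integer 0-50 raster with nodata and per-cell
  area (areas are supplied, not derived from geodesy; real-world inputs are
  presumed to be on an equal-area projection such as Mollweide).
* :class:`RealmMap` -- a categorical partition of the grid into biorealms
  (biome x biogeographic-realm units).
* :class:`Block` -- one contiguous region of qualifying cells.

Connected-component labeling is delegated to :func:`scipy.ndimage.label`;
block identifiers are renumbered into first-encounter (row-major) order so
that labeling output is deterministic and independent of scipy internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Score scale of the cumulative pressure index.
SCORE_MIN = 0
SCORE_MAX = 50

# Domain defaults shared across the pipeline.
DEFAULT_NODATA = -1
DEFAULT_CONNECTIVITY = 8        # diagonal neighbours are contiguous
MIN_BLOCK_AREA_KM2 = 10_000.0   # strict ">" filter for wilderness blocks
LOW_FRACTION = 0.10             # lowest-pressure share per biorealm
LOW_TOP_K = 10                  # largest blocks retained per biorealm
AGREEMENT_TOLERANCE = 0.2       # "within 20%" band on the normalised scale


class GridError(ValueError):
    """Malformed grid input (score range, extent or mask mismatch)."""


@dataclass
class PressureGrid:
    """Integer cumulative-pressure scores on a regular grid.

    Parameters
    ----------
    scores
        2-D integer array; valid cells hold values in ``{0..50}``, nodata
        cells hold ``nodata_value``.
    cell_area_km2
        Uniform cell area (scalar) or a per-cell array of positive areas.
    epoch
        Label for the epoch the scores describe (e.g. ``"1993"``).
    nodata_value
        Integer outside ``{0..50}`` marking cells without data
        (e.g. ocean, Antarctica).
    xll, yll, cellsize_m
        Optional georeference of the lower-left corner and the cell size in
        metres, used only for round-tripping file formats and polygon output.
    """

    scores: np.ndarray
    cell_area_km2: float | np.ndarray = 1.0
    epoch: str = ""
    nodata_value: int = DEFAULT_NODATA
    xll: float = 0.0
    yll: float = 0.0
    cellsize_m: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise GridError(f"scores must be 2-D, got shape {self.scores.shape}")
        if not np.issubdtype(self.scores.dtype, np.integer):
            raise GridError("scores must be an integer array")
        if SCORE_MIN <= self.nodata_value <= SCORE_MAX:
            raise GridError("nodata_value must lie outside the 0-50 score range")
        valid = self.scores != self.nodata_value
        bad = valid & ((self.scores < SCORE_MIN) | (self.scores > SCORE_MAX))
        if bad.any():
            raise GridError(
                f"{int(bad.sum())} cells outside the {SCORE_MIN}-{SCORE_MAX} score range"
            )
        areas = np.asarray(self.cell_area_km2, dtype=float)
        if (areas <= 0).any():
            raise GridError("cell areas must be strictly positive")
        if areas.ndim not in (0, 2):
            raise GridError("cell_area_km2 must be a scalar or a 2-D array")
        if areas.ndim == 2 and areas.shape != self.scores.shape:
            raise GridError("per-cell area shape must match the score grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    @property
    def land_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.scores != self.nodata_value

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def cell_areas(self) -> np.ndarray:
        """Per-cell area array (broadcast if the grid uses a uniform area)."""
        areas = np.asarray(self.cell_area_km2, dtype=float)
        if areas.ndim == 0:
            return np.full(self.shape, float(areas))
        return areas

    def land_area_km2(self) -> float:
        return float(self.cell_areas()[self.land_mask].sum())

    def zero_mask(self) -> np.ndarray:
        """Cells that are completely free of mapped human pressure."""
        return self.land_mask & (self.scores == 0)

    def normalized(self) -> np.ndarray:
        """Scores rescaled to [0, 1] (nodata cells become NaN)."""
        out = np.full(self.shape, np.nan)
        m = self.land_mask
        out[m] = self.scores[m] / SCORE_MAX
        return out


@dataclass
class RealmMap:
    """Categorical partition of the grid into biorealm identifiers.

    ``realm_ids`` holds positive integers on assigned cells and 0 on
    unassigned (nodata) cells.  ``seed_cells`` optionally records the
    generating seed cell of each realm (realm i at row i-1) when the
    partition came from a nearest-seed tessellation.
    """

    realm_ids: np.ndarray
    realm_names: dict[int, str] | None = None
    seed_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.realm_ids = np.asarray(self.realm_ids)
        if self.realm_ids.ndim != 2:
            raise GridError("realm_ids must be 2-D")
        if not np.issubdtype(self.realm_ids.dtype, np.integer):
            raise GridError("realm_ids must be integer")
        if (self.realm_ids < 0).any():
            raise GridError("realm ids must be >= 0 (0 marks unassigned)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.realm_ids.shape

    @property
    def land_mask(self) -> np.ndarray:
        return self.realm_ids > 0

    def realms(self) -> list[int]:
        """Sorted list of realm ids present on the map."""
        ids = np.unique(self.realm_ids)
        return [int(i) for i in ids if i > 0]

    def check_compatible(self, grid: PressureGrid) -> None:
        """Require identical extent and land/nodata mask as ``grid``."""
        if self.shape != grid.shape:
            raise GridError(
                f"realm map shape {self.shape} != grid shape {grid.shape}"
            )
        if not np.array_equal(self.land_mask, grid.land_mask):
            raise GridError("realm map land mask differs from grid land mask")


@dataclass
class Block:
    """One contiguous region of qualifying cells.

    ``cells`` is an ``(n, 2)`` array of 0-based ``(row, col)`` indices,
    row-major sorted.  ``area_km2`` is the sum of member cell areas.
    """

    block_id: int
    cells: np.ndarray
    area_km2: float
    realm_id: int | None = None
    epoch: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2 or self.cells.shape[1] != 2 or len(self.cells) == 0:
            raise GridError("block cells must be a non-empty (n, 2) array")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.cells}

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.cells[:, 0], self.cells[:, 1]] = True
        return m


def truncate_scores(
    continuous: np.ndarray,
    nodata_mask: np.ndarray | None = None,
    *,
    cell_area_km2: float | np.ndarray = 1.0,
    epoch: str = "",
    nodata_value: int = DEFAULT_NODATA,
) -> PressureGrid:
    """Convert a continuous pressure surface to the integer 0-50 scale.

    Values are truncated toward zero (floor; inputs are non-negative), the
    convention used to derive the integer Human Footprint from the continuous
    product.  Non-nodata values must lie in ``[0, 51)``.
    """
    arr = np.asarray(continuous, dtype=float)
    if nodata_mask is None:
        nodata_mask = np.zeros(arr.shape, dtype=bool)
    nodata_mask = np.asarray(nodata_mask, dtype=bool)
    valid = ~nodata_mask
    if (arr[valid] < 0).any() or (arr[valid] >= SCORE_MAX + 1).any():
        raise GridError("continuous scores must lie in [0, 51)")
    out = np.full(arr.shape, nodata_value, dtype=np.int16)
    out[valid] = np.floor(arr[valid]).astype(np.int16)
    return PressureGrid(
        out, cell_area_km2=cell_area_km2, epoch=epoch, nodata_value=nodata_value
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _first_encounter_order(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels into row-major first-encounter order.

    Returns a relabeled copy; label k in the output is the k-th distinct
    component met when scanning the grid row by row.
    """
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    ids, first = ids[keep], first[keep]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(ids.max()) + 1 if len(ids) else 1, dtype=labels.dtype)
    mapping[ids[order]] = np.arange(1, len(ids) + 1)
    return mapping[labels]


def label_grid(
    mask: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    realms: RealmMap | None = None,
) -> np.ndarray:
    """Label connected components of ``mask`` as an integer image.

    Components never straddle realm boundaries when ``realms`` is given:
    each realm is labeled independently and the results are merged, then all
    ids are renumbered into first-encounter (row-major) order.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = _structure(connectivity)
    if realms is None:
        labels, _ = ndimage.label(mask, structure=structure)
        return _first_encounter_order(labels)
    if realms.shape != mask.shape:
        raise GridError("realm map shape must match the mask")
    combined = np.zeros(mask.shape, dtype=np.int64)
    offset = 0
    for rid in realms.realms():
        sub, n = ndimage.label(mask & (realms.realm_ids == rid), structure=structure)
        combined[sub > 0] = sub[sub > 0] + offset
        offset += n
    return _first_encounter_order(combined)


def label_components(
    mask: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    realms: RealmMap | None = None,
    cell_area_km2: float | np.ndarray = 1.0,
    epoch: str = "",
) -> list[Block]:
    """Decompose a boolean grid into contiguous :class:`Block` objects.

    Every true cell belongs to exactly one block (the labeling is a
    partition); block ids follow first-encounter row-major order.  Large
    regions separated even by a single false cell (under the chosen
    connectivity) are discrete blocks.
    """
    labels = label_grid(mask, connectivity, realms)
    n_blocks = int(labels.max())
    if n_blocks == 0:
        return []
    areas = np.asarray(cell_area_km2, dtype=float)
    flat_idx = np.flatnonzero(labels)
    lab_vals = labels.ravel()[flat_idx]
    order = np.argsort(lab_vals, kind="stable")
    flat_idx = flat_idx[order]
    counts = np.bincount(lab_vals, minlength=n_blocks + 1)[1:]
    splits = np.split(flat_idx, np.cumsum(counts)[:-1])
    ncols = mask.shape[1]
    blocks: list[Block] = []
    for bid, idx in enumerate(splits, start=1):
        rows, cols = np.divmod(idx, ncols)
        cells = np.column_stack([rows, cols])
        if areas.ndim == 0:
            area = float(areas) * len(cells)
        else:
            area = float(areas[rows, cols].sum())
        realm_id = None
        if realms is not None:
            realm_id = int(realms.realm_ids[rows[0], cols[0]])
        blocks.append(Block(bid, cells, area, realm_id=realm_id, epoch=epoch))
    return blocks


def block_area(block: Block, grid: PressureGrid) -> float:
    """Area of a block in km^2: the sum of its member cell areas."""
    rows, cols = block.cells[:, 0], block.cells[:, 1]
    nrow, ncol = grid.shape
    if (rows < 0).any() or (rows >= nrow).any() or (cols < 0).any() or (cols >= ncol).any():
        raise GridError("block contains cells outside the grid extent")
    return float(grid.cell_areas()[rows, cols].sum())
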