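"""Per-biorealm lowest-pressure thresholds and Last of the Wild selection.

The Last of the Wild identifies, within each biorealm (a biome crossed with
a biogeographic realm), the 10% of land area with the lowest cumulative
pressure, then keeps the ten largest contiguous blocks plus every block
larger than 10,000 km^2.  Three map variants are produced:

* ``LoW_1993`` — 1993 scores against thresholds computed on the 1993 grid;
* ``LoW_2009_comparable`` — 2009 scores against the *1993* thresholds, so
  extent change across epochs is directly comparable;
* ``LoW_2009_current`` — 2009 scores against thresholds recomputed on the
  2009 grid: not comparable with 1993, but the best remaining habitat today.

Thresholds are minimal on the integer score scale: t_r is the smallest
score whose cumulative captured area reaches the target fraction of realm
area ("at least 10%"); on an integer scale the captured area can overshoot
the fraction substantially, so it is recorded per realm for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_core import (
    DEFAULT_CONNECTIVITY,
    LOW_FRACTION,
    LOW_TOP_K,
    MIN_BLOCK_AREA_KM2,
    SCORE_MAX,
    Block,
    GridError,
    PressureGrid,
    RealmMap,
    label_components,
)

# float-weight cumulative sums need a little slack at the fraction boundary
_AREA_EPS = 1e-9


@dataclass(frozen=True)
class ThresholdEntry:
    threshold: int
    realm_area_km2: float
    captured_area_km2: float


@dataclass
class ThresholdTable:
    """Per-realm minimal pressure thresholds capturing >= fraction of area."""

    baseline_epoch: str
    fraction: float
    entries: dict[int, ThresholdEntry]

    def threshold(self, realm_id: int) -> int:
        if realm_id not in self.entries:
            raise GridError(f"realm {realm_id} missing from threshold table")
        return self.entries[realm_id].threshold

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ThresholdTable):
            return NotImplemented
        return (
            self.baseline_epoch == other.baseline_epoch
            and self.fraction == other.fraction
            and self.entries == other.entries
        )


@dataclass
class LastOfWildMap:
    """Selected Last of the Wild blocks for one variant."""

    variant: str                      # "LoW_1993" | "LoW_2009_comparable" | "LoW_2009_current"
    thresholds: ThresholdTable
    blocks: list[Block]
    top_k: int
    min_area_km2: float
    grid_shape: tuple[int, int]
    epoch: str = ""
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


@dataclass
class LowSuite:
    """The three Last of the Wild maps and the two threshold tables."""

    thresholds_1993: ThresholdTable
    thresholds_2009: ThresholdTable
    low_1993: LastOfWildMap
    low_2009_comparable: LastOfWildMap
    low_2009_current: LastOfWildMap

    def maps(self) -> dict[str, LastOfWildMap]:
        return {
            "LoW_1993": self.low_1993,
            "LoW_2009_comparable": self.low_2009_comparable,
            "LoW_2009_current": self.low_2009_current,
        }


def compute_realm_thresholds(
    grid: PressureGrid,
    realms: RealmMap,
    fraction: float = LOW_FRACTION,
) -> ThresholdTable:
    """Tabulate area per score per biorealm and find the minimal threshold.

    For each realm, t_r = min { s in 0..50 : area(score <= s) >= fraction *
    realm area }.  Every realm must have positive land area.
    """
    realms.check_compatible(grid)
    if not 0.0 < fraction <= 1.0:
        raise GridError("fraction must lie in (0, 1]")
    areas = grid.cell_areas()
    entries: dict[int, ThresholdEntry] = {}
    for rid in realms.realms():
        sel = realms.realm_ids == rid
        realm_area = float(areas[sel].sum())
        if realm_area <= 0:
            raise GridError(f"realm {rid} has zero land area")
        hist = np.bincount(
            grid.scores[sel], weights=areas[sel], minlength=SCORE_MAX + 1
        )
        cum = np.cumsum(hist)
        target = fraction * realm_area
        t_r = int(np.argmax(cum >= target - _AREA_EPS))
        entries[rid] = ThresholdEntry(
            threshold=t_r,
            realm_area_km2=realm_area,
            captured_area_km2=float(cum[t_r]),
        )
    return ThresholdTable(
        baseline_epoch=grid.epoch, fraction=fraction, entries=entries
    )


def select_wild_blocks(
    grid: PressureGrid,
    realms: RealmMap,
    thresholds: ThresholdTable,
    top_k: int = LOW_TOP_K,
    min_area_km2: float = MIN_BLOCK_AREA_KM2,
    connectivity: int = DEFAULT_CONNECTIVITY,
    variant: str = "",
) -> LastOfWildMap:
    """Select the Last of the Wild blocks for one scoring grid.

    Per realm, candidate blocks are the within-realm connected components of
    {score <= t_r}; the retained set is the union of the ``top_k`` largest
    (area ties broken by block id, i.e. first-encounter order) and every
    block larger than ``min_area_km2``.  The union can retain more than
    ``top_k`` blocks per realm.
    """
    realms.check_compatible(grid)
    present = set(realms.realms())
    missing = present - set(thresholds.entries)
    if missing:
        raise GridError(f"realms {sorted(missing)} missing from threshold table")
    thr_img = np.full(grid.shape, -1, dtype=np.int64)
    for rid in present:
        thr_img[realms.realm_ids == rid] = thresholds.entries[rid].threshold
    mask = grid.land_mask & (grid.scores <= thr_img) & (thr_img >= 0)
    candidates = label_components(
        mask,
        connectivity=connectivity,
        realms=realms,
        cell_area_km2=grid.cell_area_km2,
        epoch=grid.epoch,
    )
    retained: list[Block] = []
    for rid in sorted(present):
        realm_blocks = [b for b in candidates if b.realm_id == rid]
        ranked = sorted(realm_blocks, key=lambda b: (-b.area_km2, b.block_id))
        keep_ids = {b.block_id for b in ranked[:top_k]}
        keep_ids |= {b.block_id for b in realm_blocks if b.area_km2 > min_area_km2}
        retained.extend(b for b in realm_blocks if b.block_id in keep_ids)
    retained.sort(key=lambda b: b.block_id)
    return LastOfWildMap(
        variant=variant,
        thresholds=thresholds,
        blocks=retained,
        top_k=top_k,
        min_area_km2=min_area_km2,
        grid_shape=grid.shape,
        epoch=grid.epoch,
        connectivity=connectivity,
    )


def build_low_suite(
    grid_1993: PressureGrid,
    grid_2009: PressureGrid,
    realms: RealmMap,
    fraction: float = LOW_FRACTION,
    top_k: int = LOW_TOP_K,
    min_area_km2: float = MIN_BLOCK_AREA_KM2,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> LowSuite:
    """Build the three-map Last of the Wild suite.

    The comparable 2009 map reuses the 1993 threshold table unchanged; the
    current 2009 map recomputes thresholds on the 2009 scores.
    """
    if grid_1993.shape != grid_2009.shape:
        raise GridError("epoch grids differ in extent")
    thr_93 = compute_realm_thresholds(grid_1993, realms, fraction)
    thr_09 = compute_realm_thresholds(grid_2009, realms, fraction)
    kw = dict(top_k=top_k, min_area_km2=min_area_km2, connectivity=connectivity)
    return LowSuite(
        thresholds_1993=thr_93,
        thresholds_2009=thr_09,
        low_1993=select_wild_blocks(
            grid_1993, realms, thr_93, variant="LoW_1993", **kw
        ),
        low_2009_comparable=select_wild_blocks(
            grid_2009, realms, thr_93, variant="LoW_2009_comparable", **kw
        ),
        low_2009_current=select_wild_blocks(
            grid_2009, realms, thr_09, variant="LoW_2009_current", **kw
        ),
    )
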