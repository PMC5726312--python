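"""Synthetic pressure rasters, biorealm partitions and visual-validation plots.

The generator emulates the statistical structure the mapping stages assume:

* a spatially autocorrelated integer 0-50 pressure surface with a large
  share of score-0 ("pressure free") cells, built by smoothing white noise
  and rank-mapping it monotonically onto the target score distribution;
* a second epoch derived by mostly-monotone per-cell score increases with
  occasional decreases, so the temporal-comparability exclusion rule
  (pressure present in epoch 1 but absent in epoch 2) is exercised;
* a contiguous multi-realm partition from a nearest-seed (Voronoi) tessellation;
* validation plots whose visually interpreted score is the true normalised
  score plus bounded Gaussian noise, flagged certain/uncertain.

All randomness flows from a single integer seed through named substreams, so
e.g. requesting more plots never perturbs the generated grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid_core import DEFAULT_NODATA, SCORE_MAX, GridError, PressureGrid, RealmMap
from .validation import ValidationPlot

# Substream indices off the root SeedSequence; fixed so streams are stable.
_STREAMS = {"grid": 0, "evolve": 1, "partition": 2, "plots": 3, "nodata": 4}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study system.

    Attributes
    ----------
    grid_shape
        (rows, cols) of the raster.
    cell_area_km2
        Uniform area of one cell, km^2.
    n_realms
        Number of biorealms in the partition.
    zero_fraction
        Target share of score-0 cells among land cells in epoch 1.
    smoothness
        Gaussian kernel width (cells) controlling spatial autocorrelation.
    increase_rate, decrease_rate
        Per-cell probabilities of a score increase / decrease between epochs.
    plot_noise_sd
        Standard deviation of visual-score noise on the normalised 0-1 scale.
    certain_fraction
        Probability a plot is flagged as certain.
    nodata_fraction
        Share of cells masked out as nodata (a smoothed random region,
        standing in for ocean / excluded areas).
    seed
        Root seed; identical configs yield bit-identical outputs.
    """

    grid_shape: tuple[int, int] = (64, 64)
    cell_area_km2: float = 1.0
    n_realms: int = 4
    zero_fraction: float = 0.3
    smoothness: float = 3.0
    increase_rate: float = 0.1
    decrease_rate: float = 0.01
    plot_noise_sd: float = 0.05
    certain_fraction: float = 0.9
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape dimensions must be >= 1")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be positive")
        if self.n_realms < 1:
            raise ValueError("n_realms must be positive")
        for name in ("zero_fraction", "increase_rate", "decrease_rate",
                     "certain_fraction", "nodata_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if self.plot_noise_sd < 0:
            raise ValueError("plot_noise_sd must be non-negative")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _smooth_field(shape: tuple[int, int], smoothness: float,
                  rng: np.random.Generator) -> np.ndarray:
    field = rng.standard_normal(shape)
    return ndimage.gaussian_filter(field, sigma=smoothness, mode="wrap")


def _nodata_mask(config: SimConfig) -> np.ndarray:
    if config.nodata_fraction <= 0:
        return np.zeros(config.grid_shape, dtype=bool)
    rng = _rng(config, "nodata")
    field = _smooth_field(config.grid_shape, config.smoothness, rng)
    n_nodata = int(round(config.nodata_fraction * field.size))
    order = np.argsort(field, axis=None, kind="stable")
    mask = np.zeros(field.size, dtype=bool)
    mask[order[:n_nodata]] = True
    return mask.reshape(field.shape)


def generate_pressure_grid(config: SimConfig) -> PressureGrid:
    """Generate the epoch-1 integer pressure raster.

    White noise is smoothed with a Gaussian kernel of width ``smoothness``
    and mapped monotonically (by rank) onto the 0-50 scale so that the
    realised fraction of score-0 land cells matches ``zero_fraction`` up to
    rounding: the lowest-ranked cells become 0, the remainder spread evenly
    over scores 1..50.
    """
    nodata = _nodata_mask(config)
    n_land = int((~nodata).sum())
    if n_land == 0:
        raise GridError("no land cells: the target zero_fraction is unachievable")
    rng = _rng(config, "grid")
    field = _smooth_field(config.grid_shape, config.smoothness, rng)
    land_vals = field[~nodata]
    order = np.argsort(land_vals, kind="stable")
    ranks = np.empty(n_land, dtype=np.int64)
    ranks[order] = np.arange(n_land)
    n_zero = int(round(config.zero_fraction * n_land))
    scores_land = np.zeros(n_land, dtype=np.int16)
    nonzero = ranks >= n_zero
    n_nonzero = n_land - n_zero
    if n_nonzero > 0:
        # quantile within the nonzero tail, mapped uniformly onto 1..50
        q = (ranks[nonzero] - n_zero) / n_nonzero
        scores_land[nonzero] = 1 + np.minimum(
            (q * SCORE_MAX).astype(np.int16), SCORE_MAX - 1
        )
    scores = np.full(config.grid_shape, DEFAULT_NODATA, dtype=np.int16)
    scores[~nodata] = scores_land
    return PressureGrid(
        scores,
        cell_area_km2=config.cell_area_km2,
        epoch="1993",
        nodata_value=DEFAULT_NODATA,
    )


def generate_grid_pair(config: SimConfig) -> tuple[PressureGrid, PressureGrid]:
    """Generate the (epoch-1, epoch-2) raster pair.

    Epoch 2 applies, per land cell, an increment of +1..+5 (capped at 50)
    with probability ``increase_rate``, else a decrement of -1..-score
    (floored at 0) with probability ``decrease_rate``, else no change.
    Nodata masks are identical across epochs.
    """
    if config.increase_rate + config.decrease_rate > 1:
        raise ValueError("increase_rate + decrease_rate must be <= 1")
    grid1 = generate_pressure_grid(config)
    rng = _rng(config, "evolve")
    land = grid1.land_mask
    s1 = grid1.scores[land].astype(np.int64)
    u = rng.random(s1.shape)
    inc_draw = rng.integers(1, 6, size=s1.shape)
    dec_frac = rng.random(s1.shape)
    s2 = s1.copy()
    inc = u < config.increase_rate
    s2[inc] = np.minimum(s1[inc] + inc_draw[inc], SCORE_MAX)
    dec = (~inc) & (u < config.increase_rate + config.decrease_rate) & (s1 > 0)
    # uniform decrement on 1..score
    dec_amount = 1 + np.floor(dec_frac[dec] * s1[dec]).astype(np.int64)
    s2[dec] = np.maximum(s1[dec] - dec_amount, 0)
    scores2 = np.full(config.grid_shape, DEFAULT_NODATA, dtype=np.int16)
    scores2[land] = s2.astype(np.int16)
    grid2 = PressureGrid(
        scores2,
        cell_area_km2=config.cell_area_km2,
        epoch="2009",
        nodata_value=DEFAULT_NODATA,
    )
    return grid1, grid2


def generate_realm_partition(config: SimConfig,
                             grid: PressureGrid | None = None) -> RealmMap:
    """Partition the land cells into ``n_realms`` contiguous biorealms.

    Seed cells are sampled uniformly without replacement from the land
    cells; every land cell is assigned to the nearest seed (Euclidean in
    cell coordinates, ties to the lowest realm id).  Each realm is
    non-empty because every seed cell is at distance 0 from itself.
    """
    nodata = _nodata_mask(config) if grid is None else ~grid.land_mask
    land_idx = np.argwhere(~nodata)
    n_land = len(land_idx)
    if config.n_realms > n_land:
        raise GridError(
            f"n_realms={config.n_realms} exceeds the {n_land} land cells"
        )
    rng = _rng(config, "partition")
    pick = rng.choice(n_land, size=config.n_realms, replace=False)
    seeds = land_idx[pick]                       # (n_realms, 2)
    diff = land_idx[:, None, :] - seeds[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    assigned = np.argmin(d2, axis=1) + 1         # argmin ties -> lowest id
    realm_ids = np.zeros(config.grid_shape, dtype=np.int32)
    realm_ids[land_idx[:, 0], land_idx[:, 1]] = assigned
    names = {i: f"realm_{i}" for i in range(1, config.n_realms + 1)}
    return RealmMap(realm_ids, realm_names=names, seed_cells=seeds)


def generate_validation_plots(
    grid: PressureGrid, config: SimConfig, n_plots: int
) -> list[ValidationPlot]:
    """Sample visual-validation plots over the grid.

    ``n_plots`` distinct land cells are drawn uniformly without replacement;
    each plot's visual score is the cell's true normalised score plus
    Gaussian noise (sd = ``plot_noise_sd``), clamped to [0, 1], and the
    certain flag is Bernoulli(``certain_fraction``).
    """
    land_idx = np.argwhere(grid.land_mask)
    if n_plots > len(land_idx):
        raise GridError(f"n_plots={n_plots} exceeds the {len(land_idx)} land cells")
    rng = _rng(config, "plots")
    pick = rng.choice(len(land_idx), size=n_plots, replace=False)
    cells = land_idx[pick]
    true_norm = grid.scores[cells[:, 0], cells[:, 1]] / SCORE_MAX
    noise = rng.normal(0.0, config.plot_noise_sd, size=n_plots)
    visual = np.clip(true_norm + noise, 0.0, 1.0)
    certain = rng.random(n_plots) < config.certain_fraction
    return [
        ValidationPlot(
            plot_id=i + 1,
            row=int(cells[i, 0]),
            col=int(cells[i, 1]),
            visual_score_norm=float(visual[i]),
            certain=bool(certain[i]),
            hfp_score_norm=float(true_norm[i]),
        )
        for i in range(n_plots)
    ]
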