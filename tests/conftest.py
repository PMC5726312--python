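"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wildmaps import SimConfig, generate_grid_pair, generate_realm_partition


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force connected components by iterative flood fill.

    Independent of the package's labeling path (no scipy); returns the set
    of components, each a set of (row, col) tuples, in first-encounter
    row-major order.
    """
    mask = np.asarray(mask, dtype=bool)
    nrows, ncols = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        raise ValueError(connectivity)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def brute_force_thresholds(grid, realms, fraction):
    """Per-realm minimal threshold by explicit scan over scores 0..50."""
    areas = grid.cell_areas()
    out = {}
    for rid in realms.realms():
        sel = realms.realm_ids == rid
        realm_area = areas[sel].sum()
        for s in range(51):
            captured = areas[sel & (grid.scores <= s) & grid.land_mask].sum()
            if captured >= fraction * realm_area - 1e-9:
                out[rid] = s
                break
    return out


@pytest.fixture
def base_config() -> SimConfig:
    """Moderate-size synthetic study system used across modules."""
    return SimConfig(
        grid_shape=(64, 64),
        cell_area_km2=1.0,
        n_realms=4,
        zero_fraction=0.3,
        smoothness=3.0,
        increase_rate=0.1,
        decrease_rate=0.02,
        plot_noise_sd=0.05,
        certain_fraction=0.9,
        seed=7,
    )


@pytest.fixture
def grid_pair(base_config):
    return generate_grid_pair(base_config)


@pytest.fixture
def realm_map(base_config, grid_pair):
    return generate_realm_partition(base_config, grid=grid_pair[0])
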