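"""Shared fixtures and the naive dense-array oracle engine.

The oracle deliberately shares nothing with the sparse implementation:
it scans a boolean numpy grid and sums the 8 neighbor planes explicitly,
either wrapping (torus) or zero-padding (plane). It exists so the sparse
candidate-set engine can be checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest

from lifelab.engine import Universe


def dense_step(grid: np.ndarray, birth=frozenset({3}), survival=frozenset({2, 3}),
               torus: bool = True) -> np.ndarray:
    """One synchronous update of a dense boolean grid (rows = y, cols = x)."""
    g = grid.astype(np.int8)
    neigh = np.zeros_like(g)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            if torus:
                neigh += np.roll(np.roll(g, dy, axis=0), dx, axis=1)
            else:
                shifted = np.zeros_like(g)
                h, w = g.shape
                ys = slice(max(dy, 0), h + min(dy, 0))
                xs = slice(max(dx, 0), w + min(dx, 0))
                ys_src = slice(max(-dy, 0), h + min(-dy, 0))
                xs_src = slice(max(-dx, 0), w + min(-dx, 0))
                shifted[ys, xs] = g[ys_src, xs_src]
                neigh += shifted
    born = (g == 0) & np.isin(neigh, list(birth))
    stay = (g == 1) & np.isin(neigh, list(survival))
    return born | stay


def grid_to_universe(grid: np.ndarray, torus: bool) -> Universe:
    ys, xs = np.nonzero(grid)
    cells = frozenset((int(x), int(y)) for x, y in zip(xs, ys))
    h, w = grid.shape
    return Universe(cells, torus=(w, h) if torus else None)


def universe_to_grid(universe: Universe, width: int, height: int) -> np.ndarray:
    grid = np.zeros((height, width), dtype=bool)
    for x, y in universe.live:
        grid[y % height, x % width] = True
    return grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
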