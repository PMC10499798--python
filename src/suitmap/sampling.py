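"""Presence-cell aggregation and suitability-screened background sampling.

Occurrence points are aggregated to grid cells (duplicates collapse to one
presence cell). Background (pseudo-absence) cells are drawn from the cells a
reference suitability surface marks as unsuitable (value strictly below 0.5),
excluding presence cells; each of the B draws takes exactly as many background
cells as there are presence cells, without replacement within a draw, with
draw b seeded ``base_seed + b`` so the whole family is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .grid import cell_of
from .raster import CovariateStack, SuitabilityMap


@dataclass(frozen=True)
class PresenceCells:
    """Unique occurrence cells plus provenance counts."""

    cells: np.ndarray  # (m, 2) int array of (row, col), sorted row-major
    n_source_points: int
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.cells}


@dataclass(frozen=True)
class BackgroundDraw:
    """One seeded equal-count background draw."""

    index: int
    seed: int
    cells: np.ndarray  # (n, 2) int array of (row, col)

    def __len__(self) -> int:
        return len(self.cells)


def _sorted_unique_cells(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    cells = np.unique(np.column_stack([rows, cols]), axis=0)
    order = np.lexsort((cells[:, 1], cells[:, 0]))
    return cells[order]


def grid_presences(points: np.ndarray, stack: CovariateStack) -> PresenceCells:
    """Aggregate (lat, lon) points to unique valid presence cells.

    Points outside the grid or on nodata cells are dropped and counted.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValidationError("no occurrence points supplied")
    rows, cols, ok = cell_of(points[:, 0], points[:, 1], stack.grid)
    valid = stack.joint_valid()
    on_data = ok.copy()
    on_data[ok] = valid[rows[ok], cols[ok]]
    if not on_data.any():
        raise ValidationError("no occurrence points fall on valid grid cells")
    cells = _sorted_unique_cells(rows[on_data], cols[on_data])
    return PresenceCells(cells, n_source_points=len(points),
                         n_dropped=int((~on_data).sum()))


def screen_background_candidates(reference: SuitabilityMap,
                                 presences: PresenceCells,
                                 stack: CovariateStack | None = None,
                                 threshold: float = 0.5) -> np.ndarray:
    """Cells eligible as background: reference suitability strictly < threshold.

    Presence cells are excluded even when the reference calls them
    unsuitable. If a stack is given, candidates are restricted to its joint
    validity mask. Returns an (m, 2) array sorted row-major.
    """
    if stack is not None and reference.grid != stack.grid:
        raise GridMismatchError("reference map and stack are on different grids")
    eligible = reference.valid & (reference.mean.values < threshold)
    if stack is not None:
        eligible &= stack.joint_valid()
    eligible[presences.cells[:, 0], presences.cells[:, 1]] = False
    rows, cols = np.nonzero(eligible)
    return np.column_stack([rows, cols])


def draw_background(candidates: np.ndarray, n_per_draw: int, B: int,
                    base_seed: int) -> list[BackgroundDraw]:
    """B independent uniform without-replacement draws, draw b seeded base_seed+b."""
    candidates = np.asarray(candidates)
    if B < 1:
        raise ValidationError("need at least one background draw")
    if len(candidates) < n_per_draw:
        raise ValidationError(
            f"only {len(candidates)} background candidates for draws of "
            f"{n_per_draw} (short by {n_per_draw - len(candidates)})")
    draws = []
    for b in range(1, B + 1):
        seed = base_seed + b
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=n_per_draw, replace=False)
        idx.sort()
        draws.append(BackgroundDraw(b, seed, candidates[idx]))
    return draws


def bootstrap_reference(stack: CovariateStack, presences: PresenceCells,
                        config, seed: int = 0) -> SuitabilityMap:
    """Screening reference fitted from scratch when no external map exists.

    Fits a single boosted-tree sub-model against a uniformly random
    equal-count background drawn from all valid non-presence cells, and
    returns its prediction map. Used only to screen background candidates;
    an externally supplied reference surface takes priority in the pipeline.
    """
    from . import brt  # local import to avoid a cycle

    if len(presences) < 30:
        raise ValidationError(
            f"need at least 30 presence cells to bootstrap a reference, "
            f"got {len(presences)}")
    eligible = stack.joint_valid().copy()
    eligible[presences.cells[:, 0], presences.cells[:, 1]] = False
    rows, cols = np.nonzero(eligible)
    pool = np.column_stack([rows, cols])
    if len(pool) < len(presences):
        raise ValidationError("not enough non-presence cells for a bootstrap "
                              "background")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=len(presences), replace=False)
    idx.sort()
    draw = BackgroundDraw(0, seed, pool[idx])
    X, y, _ = brt.assemble_training(presences, draw, stack)
    n_trees, _ = brt.select_n_trees(X, y, config, seed=seed)
    sub = brt.fit_brt(X, y, config, n_trees=n_trees, seed=seed)
    return brt.predict_map(sub, stack)


def draws_to_frame(draws: list[BackgroundDraw], grid) -> pd.DataFrame:
    """Serialize draws for audit: one row per (draw, cell) with cell centres."""
    frames = []
    for d in draws:
        lat, lon = grid.cell_center(d.cells[:, 0], d.cells[:, 1])
        frames.append(pd.DataFrame({
            "draw_index": d.index, "row": d.cells[:, 0], "col": d.cells[:, 1],
            "lat_centre": lat, "lon_centre": lon}))
    return pd.concat(frames, ignore_index=True)
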