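"""Marginal-land accounting: thresholds, masks, areas, and scenario deltas.

Suitability maps are thresholded at tau (suitable iff >= tau, default 0.5),
restricted to marginal land-cover classes (shrublands, savannas, grassland by
default), and summed into per-region areas using exact spherical-band cell
areas. Areas are reported in Mha (1 Mha = 10^4 km^2), unrounded internally
and rounded only at report time. Changes between two masks decompose into
expansion (newly suitable), contraction (newly unsuitable) and their exact
difference, the net change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .grid import GridSpec, row_areas
from .raster import LandCoverMap, RegionMap, SuitabilityMap

KM2_PER_MHA = 1.0e4
GLOBAL_LABEL = "Total"


@dataclass
class SuitableMask:
    """Binary suitable/unsuitable raster plus the threshold that made it."""

    grid: GridSpec
    suitable: np.ndarray  # bool, True = suitable
    valid: np.ndarray     # bool, True = cell holds data
    threshold: float

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.suitable.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")
        if (self.suitable & ~self.valid).any():
            raise ValidationError("suitable cells outside the valid domain")

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


@dataclass
class AreaTable:
    """Per-region areas (Mha) and percent of the global total."""

    table: pd.DataFrame  # region, area_mha, percent — sorted descending
    total_mha: float
    empty: bool = False

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["area_mha"] = out["area_mha"].round(decimals)
        out["percent"] = out["percent"].round(decimals)
        return out

    @classmethod
    def from_areas(cls, areas: dict[str, float],
                   total: float | None = None) -> "AreaTable":
        """Build the percent-share table from already-computed region areas.

        ``total`` defaults to the sum of the areas; pass a printed grand total
        to reproduce published percentage columns exactly as printed.
        """
        if total is None:
            total = float(sum(areas.values()))
        empty = total <= 0
        rows = [{"region": k, "area_mha": float(v),
                 "percent": 0.0 if empty else 100.0 * v / total}
                for k, v in areas.items()]
        df = (pd.DataFrame(rows)
              .sort_values("area_mha", ascending=False, ignore_index=True))
        return cls(df, total, empty=empty)


@dataclass
class DeltaTable:
    """Expansion/contraction/net change (Mha) between two masks, per region."""

    table: pd.DataFrame  # region, expansion_mha, contraction_mha, net_mha
    global_row: pd.Series


def threshold_suitable(smap: SuitabilityMap, tau: float = 0.5) -> SuitableMask:
    """Suitable iff suitability >= tau (cells exactly at tau count suitable)."""
    if not 0 < tau < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {tau}")
    valid = smap.valid
    suitable = valid & (smap.mean.values >= tau)
    return SuitableMask(smap.grid, suitable, valid, tau)


def marginal_mask(suitable: SuitableMask, lc: LandCoverMap,
                  allowed: frozenset | set) -> SuitableMask:
    """Restrict a suitable mask to the allowed (marginal) land-cover classes."""
    if lc.raster.grid != suitable.grid:
        raise GridMismatchError("land cover is not on the mask grid")
    in_class = np.isin(lc.raster.values, list(allowed)) & lc.raster.valid
    return SuitableMask(suitable.grid, suitable.suitable & in_class,
                        suitable.valid, suitable.threshold)


def _region_areas_mha(mask: SuitableMask, regions: RegionMap) -> dict[str, float]:
    if regions.raster.grid != mask.grid:
        raise GridMismatchError("regions are not on the mask grid")
    areas = row_areas(mask.grid) / KM2_PER_MHA  # Mha per cell, by row
    out: dict[str, float] = {}
    for _, rec in regions.table.iterrows():
        sel = mask.suitable & (regions.raster.values == rec["region_id"]) \
            & regions.raster.valid
        rows = np.nonzero(sel)[0]
        out[str(rec["name"])] = float(areas[rows].sum())
    return out


def area_by_region(mask: SuitableMask, regions: RegionMap,
                   grid: GridSpec | None = None) -> AreaTable:
    """Sum suitable-cell areas per region, in Mha, sorted descending."""
    if grid is not None and grid != mask.grid:
        raise GridMismatchError("mask is not on the requested grid")
    return AreaTable.from_areas(_region_areas_mha(mask, regions))


def scenario_delta(current: SuitableMask, future: SuitableMask,
                   regions: RegionMap, grid: GridSpec | None = None
                   ) -> DeltaTable:
    """Decompose the change between two masks into expansion/contraction/net."""
    if future.grid != current.grid:
        raise GridMismatchError("masks are on different grids")
    if grid is not None and grid != current.grid:
        raise GridMismatchError("masks are not on the requested grid")
    exp_mask = SuitableMask(current.grid, future.suitable & ~current.suitable,
                            current.valid, future.threshold)
    con_mask = SuitableMask(current.grid, current.suitable & ~future.suitable,
                            current.valid, current.threshold)
    exp = _region_areas_mha(exp_mask, regions)
    con = _region_areas_mha(con_mask, regions)
    rows = [{"region": r, "expansion_mha": exp[r], "contraction_mha": con[r],
             "net_mha": exp[r] - con[r]} for r in exp]
    df = pd.DataFrame(rows).sort_values("net_mha", ascending=False,
                                        ignore_index=True)
    glob = pd.Series({"region": GLOBAL_LABEL,
                      "expansion_mha": df["expansion_mha"].sum(),
                      "contraction_mha": df["contraction_mha"].sum(),
                      "net_mha": (df["expansion_mha"].sum()
                                  - df["contraction_mha"].sum())})
    return DeltaTable(df, glob)


def net_change(current_total_mha: float, future_total_mha: float) -> float:
    """Net change in the global total between two time points (Mha)."""
    return float(future_total_mha) - float(current_total_mha)


@dataclass
class ScenarioReport:
    """Areas and deltas for every (scenario, horizon) versus the current map."""

    current_areas: AreaTable
    areas: dict[str, AreaTable] = field(default_factory=dict)
    deltas: dict[str, DeltaTable] = field(default_factory=dict)


def scenario_report(ens, scenario_stacks: dict, lc: LandCoverMap,
                    regions: RegionMap, current_stack, tau: float = 0.5,
                    allowed: frozenset | set | None = None) -> ScenarioReport:
    """Run predict -> threshold -> marginal mask -> areas/deltas per scenario.

    ``scenario_stacks`` maps a label (e.g. ``rcp45_2030``) to a covariate
    stack; each is compared against the current stack's marginal mask.
    """
    from .brt import ensemble_predict
    from .synthetic import MARGINAL_CLASSES

    if allowed is None:
        allowed = MARGINAL_CLASSES
    cur_mask = marginal_mask(
        threshold_suitable(ensemble_predict(ens, current_stack), tau),
        lc, allowed)
    report = ScenarioReport(area_by_region(cur_mask, regions))
    for label, stack in scenario_stacks.items():
        try:
            fut_mask = marginal_mask(
                threshold_suitable(ensemble_predict(ens, stack), tau),
                lc, allowed)
        except Exception as exc:
            raise type(exc)(f"scenario {label}: {exc}") from exc
        report.areas[label] = area_by_region(fut_mask, regions)
        report.deltas[label] = scenario_delta(cur_mask, fut_mask, regions)
    return report
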