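#!/usr/bin/env python
"""Simulate the virtual-species study world.

Builds the default 200x200 tropical landscape: eight autocorrelated climate
layers plus elevation, slope and soil class; a known suitability truth
dominated by a temperature-annual-range window; suitability-biased occurrence
points; contiguous land-cover and region partitions; and nine additive
climate scenarios (three pathways x three horizons). Writes everything as
GeoTIFF/CSV/YAML under the run directory so the later stages consume only
on-disk artifacts.
"""

import logging
import sys
from pathlib import Path

from suitmap import pipeline
from suitmap.sampling import grid_presences
from suitmap.raster import read_points

logging.basicConfig(stream=sys.stderr, level=logging.INFO)
CONFIG = Path(__file__).with_name("config.yaml")


def main() -> None:
    cfg = pipeline.validate_config(CONFIG)
    pipeline.run(cfg, ["simulate"])
    stack, lc, regions, shifts = pipeline._load_world(cfg)
    points, dropped = read_points(cfg.world_dir / "occurrences.csv")
    presences = grid_presences(points, stack)
    print(f"world: {stack.grid.n_rows}x{stack.grid.n_cols} cells at "
          f"{stack.grid.res} deg, {int(stack.joint_valid().sum())} on land")
    print(f"layers: {', '.join(stack.names)}")
    print(f"occurrences: {len(points)} points -> {len(presences)} presence "
          f"cells ({dropped} dropped)")
    print(f"scenarios: {len(shifts)} ({sorted({s.scenario for s in shifts})} "
          f"x {sorted({s.horizon for s in shifts})})")


if __name__ == "__main__":
    main()
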