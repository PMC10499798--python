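#!/usr/bin/env python
"""Account marginal-land areas under current and future climate.

Thresholds the suitability maps at 0.5, keeps only marginal land-cover
classes (shrublands, savannas, grassland), sums exact spherical cell areas
per region, and decomposes each scenario's change against the current map
into expansion, contraction, and net (their exact difference). Writes the
area and delta tables and prints the global summary.
"""

import logging
import sys
from pathlib import Path

import pandas as pd

from suitmap import pipeline

logging.basicConfig(stream=sys.stderr, level=logging.INFO)
CONFIG = Path(__file__).with_name("config.yaml")


def main() -> None:
    cfg = pipeline.validate_config(CONFIG)
    pipeline.run(cfg, ["account"])
    tables = cfg.outdir / "tables"
    current = pd.read_csv(tables / "area_current.csv")
    total = current["area_mha"].sum()
    print(f"current marginal land suitable for the crop: {total:.2f} Mha")
    print(current.to_string(index=False))
    print("\nscenario net changes vs current (Mha):")
    for path in sorted(tables.glob("delta_*.csv")):
        df = pd.read_csv(path)
        net = df.loc[df["region"] == "Total", "net_mha"].iloc[0]
        label = path.stem.removeprefix("delta_")
        print(f"  {label:12s} {net:+8.2f}")


if __name__ == "__main__":
    main()
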