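#!/usr/bin/env python
"""Project ensemble suitability under the climate scenarios.

Applies each scenario's additive climate shifts to the current covariate
stack (topography and soil unchanged) and writes one ensemble-mean
suitability GeoTIFF per scenario x horizon.
"""

import logging
import sys
from pathlib import Path

from suitmap import pipeline

logging.basicConfig(stream=sys.stderr, level=logging.INFO)
CONFIG = Path(__file__).with_name("config.yaml")


def main() -> None:
    cfg = pipeline.validate_config(CONFIG)
    pipeline.run(cfg, ["project"])
    maps = sorted((cfg.outdir / "projections").glob("*.tif"))
    print(f"wrote {len(maps)} projected suitability maps:")
    for m in maps:
        print(" ", m.name)


if __name__ == "__main__":
    main()
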