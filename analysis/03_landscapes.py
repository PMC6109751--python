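"""Interpolate the multi-species genetic landscapes.

Maps per-population diversity to collection locations and pairwise
divergence to pair midpoints, interpolates each species x statistic with
IDW (power 2, 12-point variable search radius) on a 60 x 60 grid, and
averages across species (one vote per species). Writes the three
landscape_*.asc rasters.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py")
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from genescape.io_formats import read_raster
from genescape.pipeline import stage_landscape


def main() -> None:
    cfg = config.pipeline_config()
    stage_landscape(cfg, config.OUTDIR)
    for stat in ("divergence", "gene_diversity", "sequence_diversity"):
        ls = read_raster(config.OUTDIR / f"landscape_{stat}.asc")
        vals = ls.valid_values()
        print(f"{stat}: grid {ls.grid.nrows}x{ls.grid.ncols}, "
              f"mean {vals.mean():.3f}, sd {vals.std():.3f}, "
              f"range [{vals.min():.3f}, {vals.max():.3f}]")


if __name__ == "__main__":
    sys.exit(main())
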