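"""Species-genetic diversity correlations and geographic trends.

Averages the normalized landscapes within region polygons, joins the
region-level species-diversity indices (ER, WE, PD, PE, BED), and reports
Pearson correlations plus ordinary least-squares regressions of each
diversity measure on longitude and latitude.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py")
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from genescape.pipeline import stage_sgdc


def main() -> None:
    cfg = config.pipeline_config()
    indir = config.OUTDIR / "input"
    cfg.regions_geojson = str(indir / "regions.geojson")
    cfg.species_diversity_csv = str(indir / "species_diversity.csv")
    stage_sgdc(cfg, config.OUTDIR)
    print("correlation table (r / p per genetic-diversity index):")
    print(pd.read_csv(config.OUTDIR / "sgdc_correlations.csv", index_col=0)
          .round(3))
    print("\ngeographic regressions:")
    print(pd.read_csv(config.OUTDIR / "geographic_regressions.csv").round(4))


if __name__ == "__main__":
    sys.exit(main())
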