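"""Compute and normalize the genetic statistics.

Reads the study generated by 01_simulate.py, applies the inclusion filters
(>= 10 populations per species, >= 3 individuals per population), computes
Hd/pi per population and the pairwise Phi_ST matrices, and max-normalizes
everything per species. Writes within_pop_diversity.csv and
pairwise_fst.csv.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py")
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from genescape.pipeline import stage_stats


def main() -> None:
    cfg = config.pipeline_config()
    indir = config.OUTDIR / "input"
    cfg.population_csv = str(indir / "populations.csv")
    cfg.manifest_csv = str(indir / "manifest.csv")
    stage_stats(cfg, config.OUTDIR)
    within = pd.read_csv(config.OUTDIR / "within_pop_diversity.csv")
    pairs = pd.read_csv(config.OUTDIR / "pairwise_fst.csv")
    print(f"{len(within)} population estimates, {len(pairs)} pairwise values")
    print(within.groupby("species_id")[["gene_diversity", "sequence_diversity"]]
          .mean().round(3))
    print("mean clamped Phi_ST per species:")
    print(pairs.groupby("species_id")["fst"].mean().round(3))


if __name__ == "__main__":
    sys.exit(main())
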