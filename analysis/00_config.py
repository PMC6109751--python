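"""Shared configuration for the numbered analysis scripts.

The reference study: five species sampled at 20 georeferenced populations
each (8 individuals per population) on the unit square, with two planted
within-population diversity bumps and one divergence barrier down the
middle. All scripts write into results/analysis/.
"""

from pathlib import Path

from genescape.pipeline import PipelineConfig

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 0


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, grid_cell_size=1.0 / 60.0,
                          grid_bounds=(0.0, 0.0, 1.0, 1.0))
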