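import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def small_study(tmp_path):
    """A tiny two-species study written to disk in the external formats."""
    from genescape.synthetic_data import (Barrier, Bump, SimulationConfig,
                                          generate_study, save_study)
    cfg = SimulationConfig(
        n_species=2, populations_per_species=12, individuals_per_population=4,
        sequence_length=60, n_haplotype_pool=8, seed=11,
        diversity_bumps=[Bump((0.3, 0.7), 0.2, 0.5)],
        barrier=Barrier((0.5, 0.0), (0.5, 1.0), 0.8))
    datasets, records, truth = generate_study(cfg)
    save_study(datasets, records, truth, tmp_path)
    return cfg, tmp_path
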