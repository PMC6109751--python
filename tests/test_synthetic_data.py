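"""The synthetic-study generator: determinism and planted structure."""

import json

import numpy as np
import pytest

from genescape.popgen_stats import compute_species_estimates, gene_diversity
from genescape.synthetic_data import (Barrier, Bump, SimulationConfig,
                                      generate_region_grid, generate_study,
                                      save_study)


def small_config(seed=0, **overrides):
    defaults = dict(n_species=2, populations_per_species=12,
                    individuals_per_population=6, sequence_length=80,
                    n_haplotype_pool=12, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_config_validation():
    with pytest.raises(ValueError, match="10 populations"):
        SimulationConfig(populations_per_species=5)
    with pytest.raises(ValueError, match="3 individuals"):
        SimulationConfig(individuals_per_population=2)
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        Barrier((0, 0), (0, 1), strength=1.2)
    with pytest.warns(UserWarning, match="outside the domain"):
        SimulationConfig(diversity_bumps=[Bump((3.0, 3.0), 0.1, 1.0)])


def test_bitwise_reproducibility(tmp_path):
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    for out in (out_a, out_b):
        save_study(*generate_study(small_config(seed=42)), out)
    for f in sorted(out_a.iterdir()):
        assert f.read_bytes() == (out_b / f.name).read_bytes(), f.name


def test_no_barrier_shared_pool_gives_near_zero_fst():
    """s=0, flat theta high enough for weak drift: mean |Phi_ST| small."""
    # panmixia needs weak drift (high theta) and enough gene copies for the
    # fixation-index estimator's null noise to sit well below the bound
    cfg = small_config(seed=7, populations_per_species=15,
                       individuals_per_population=16,
                       barrier=Barrier((0.5, 0), (0.5, 1), 0.0),
                       diversity_bumps=[], theta0=50.0)
    datasets, _, _ = generate_study(cfg)
    vals = []
    for ds in datasets:
        _, pairwise = compute_species_estimates(ds)
        iu = np.triu_indices(len(pairwise.population_ids), k=1)
        vals.extend(np.abs(pairwise.matrix_raw[iu]))
    assert len(vals) >= 100
    assert np.mean(vals) < 0.05


def test_full_barrier_gives_high_cross_fst():
    cfg = small_config(seed=8, individuals_per_population=8,
                       barrier=Barrier((0.5, 0), (0.5, 1), 1.0),
                       diversity_bumps=[], theta0=0.3)
    datasets, records, truth = generate_study(cfg)
    sides = truth.side_by_population
    cross = []
    for ds in datasets:
        _, pairwise = compute_species_estimates(ds)
        pops = pairwise.population_ids
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                if sides[pops[i]] != sides[pops[j]]:
                    cross.append(pairwise.matrix[i, j])
    assert np.mean(cross) > 0.8


def test_bump_elevates_within_population_diversity():
    cfg = small_config(seed=9, n_species=4, populations_per_species=25,
                       diversity_bumps=[Bump((0.5, 0.5), 0.35, 1.0)],
                       theta0=0.02,
                       barrier=Barrier((2.0, 0), (2.0, 1), 0.0))
    datasets, records, truth = generate_study(cfg)
    coords = {r.population_id: (r.lon, r.lat) for r in records}
    inside, outside = [], []
    for ds in datasets:
        for pop, seqs in ds.alignment.items():
            counts = list(np.unique(seqs, return_counts=True)[1])
            hd = gene_diversity(counts)
            x, y = coords[pop]
            d = np.hypot(x - 0.5, y - 0.5)
            (inside if d < 0.35 else outside).append(hd)
    assert np.mean(inside) > np.mean(outside)


def test_microsat_species_exercise_he_and_multilocus_fst():
    """Microsatellite datasets yield HE per population, no pi, full F_ST."""
    cfg = small_config(seed=3, n_microsat_species=1, n_loci=4,
                       n_allele_pool=8)
    datasets, records, _ = generate_study(cfg)
    micro = [ds for ds in datasets if ds.marker_type == "microsat"]
    assert len(micro) == 1
    within, pairwise = compute_species_estimates(micro[0])
    assert all(0.0 <= w.gene_diversity <= 1.0 for w in within)
    assert all(np.isnan(w.sequence_diversity) for w in within)
    n = len(pairwise.population_ids)
    iu = np.triu_indices(n, k=1)
    assert np.isfinite(pairwise.matrix[iu]).all()
    assert pairwise.mode == "allele_identity_multilocus"


def test_ground_truth_json_written(tmp_path):
    datasets, records, truth = generate_study(small_config(seed=1))
    save_study(datasets, records, truth, tmp_path)
    payload = json.loads((tmp_path / "ground_truth.json").read_text())
    assert set(payload["theta_by_population"]) == \
        {r.population_id for r in records}
    assert payload["barrier"]["strength"] == pytest.approx(0.8)


def test_region_grid_tessellation():
    region_set, sd = generate_region_grid(small_config(), 4, 0.5)
    assert len(region_set.regions) == 4
    areas = {geom.area for _, geom in region_set.regions}
    assert len(areas) == 1  # congruent rectangles
    assert len(sd) == 4 and {"ER", "WE", "PD", "PE", "BED"} <= set(sd.columns)


def test_region_grid_full_coupling_is_affine_in_base():
    base = np.linspace(0.1, 0.9, 25)
    _, sd = generate_region_grid(small_config(), 25, 1.0, agd_values=base)
    r = np.corrcoef(base, sd["ER"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_region_grid_rejects_bad_coupling():
    with pytest.raises(ValueError):
        generate_region_grid(small_config(), 25, 1.5)
    with pytest.raises(ValueError):
        generate_region_grid(small_config(), 3, 0.0)
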