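"""SD classification, hotspot extraction, and the unified report."""

import numpy as np
import pytest

from genescape.hotspots import (classify_sd, extract_hotspots, hotspot_report)
from genescape.landscape import GeneticLandscape, GridSpec


def make_landscape(values, cell=1.0):
    values = np.asarray(values, dtype=float)
    g = GridSpec(0, 0, cell, values.shape[1], values.shape[0])
    return GeneticLandscape(g, values)


def test_constant_raster_degenerates_to_middle_class():
    ls = make_landscape(np.full((5, 5), 0.3))
    with pytest.warns(UserWarning, match="zero variance"):
        cls = classify_sd(ls)
    assert cls.sd == 0.0
    assert np.all(cls.class_raster[ls.mask] == 0)
    hs = extract_hotspots(cls, ls)
    assert hs.patches == [] and hs.fraction_of_analyzed_area == 0.0


def test_two_value_raster_matches_arithmetic_oracle():
    vals = np.concatenate([np.zeros(900), np.ones(100)]).reshape(20, 50)
    ls = make_landscape(vals)
    cls = classify_sd(ls)
    mean, sd = 0.1, np.sqrt(0.1 * 0.9)  # population moments
    assert cls.mean == pytest.approx(mean)
    assert cls.sd == pytest.approx(sd)
    hs = extract_hotspots(cls, ls)
    threshold = mean + 1.5 * sd
    expected_flagged = int((vals > threshold).sum())
    assert hs.threshold == pytest.approx(threshold)
    assert hs.n_flagged_cells == expected_flagged == 100


def test_middle_class_spans_half_sd_each_side():
    rng = np.random.default_rng(3)
    ls = make_landscape(rng.normal(0, 1, (30, 30)))
    cls = classify_sd(ls)
    z = (ls.values - cls.mean) / cls.sd
    middle = cls.class_raster == 0
    assert np.all(z[middle] >= -0.5) and np.all(z[middle] < 0.5)


def test_single_block_is_one_patch():
    vals = np.zeros((10, 10))
    vals[3:6, 3:6] = 1.0
    ls = make_landscape(vals)
    hs = extract_hotspots(classify_sd(ls), ls)
    assert len(hs.patches) == 1 and len(hs.patches[0].cells) == 9
    assert hs.patches[0].centroid == (4.5, 5.5)  # cell centers


def test_diagonal_blocks_connectivity():
    vals = np.zeros((10, 10))
    vals[2:4, 2:4] = 1.0
    vals[4:6, 4:6] = 1.0  # touches the first block diagonally at (3,3)/(4,4)
    ls = make_landscape(vals)
    cls = classify_sd(ls)
    assert len(extract_hotspots(cls, ls, connectivity=8).patches) == 1
    assert len(extract_hotspots(cls, ls, connectivity=4).patches) == 2


def test_no_cell_above_threshold_yields_empty_set():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.49, 0.51, (10, 10))
    vals[0, 0] = 0.0  # heavy low outlier pushes threshold above the rest
    ls = make_landscape(vals)
    hs = extract_hotspots(classify_sd(ls), ls)
    expected = int((vals > hs.threshold).sum())
    assert hs.n_flagged_cells == expected


def test_flagged_fraction_identity(rng):
    ls = make_landscape(rng.normal(0, 1, (40, 40)))
    cls = classify_sd(ls)
    hs = extract_hotspots(cls, ls)
    assert hs.n_flagged_cells == int(
        (ls.values > cls.mean + 1.5 * cls.sd).sum())


def test_affine_invariance_of_hotspot_cells(rng):
    ls = make_landscape(rng.normal(0, 1, (25, 25)))
    base = extract_hotspots(classify_sd(ls), ls)
    for a, b in [(2.5, 0.0), (0.3, 10.0), (7.0, -3.0)]:
        t = make_landscape(a * ls.values + b)
        got = extract_hotspots(classify_sd(t), t)
        assert {frozenset(p.cells) for p in got.patches} == \
               {frozenset(p.cells) for p in base.patches}


def test_patch_numbering_deterministic_area_ordered():
    vals = np.zeros((12, 12))
    vals[1:4, 1:4] = 1.0    # 9 cells, northern
    vals[8:10, 8:10] = 1.0  # 4 cells
    ls = make_landscape(vals)
    hs = extract_hotspots(classify_sd(ls), ls)
    assert [len(p.cells) for p in hs.patches] == [9, 4]
    assert [p.patch_id for p in hs.patches] == [1, 2]


def test_merge_distance_unifies_nearby_patches():
    vals = np.zeros((10, 10))
    vals[1, 1] = 1.0
    vals[1, 4] = 1.0  # 3 cells apart (centers 3.0 units)
    ls = make_landscape(vals)
    cls = classify_sd(ls)
    assert len(extract_hotspots(cls, ls).patches) == 2
    assert len(extract_hotspots(cls, ls, merge_distance=3.5).patches) == 1


def test_unified_report_flags():
    vals_a = np.zeros((10, 10)); vals_a[2:4, 2:4] = 1.0
    vals_b = np.zeros((10, 10)); vals_b[3:5, 3:5] = 1.0   # overlaps a
    vals_c = np.zeros((10, 10)); vals_c[7:9, 7:9] = 1.0   # disjoint
    sets = {}
    for name, vals in [("divergence", vals_a), ("gene_diversity", vals_b),
                       ("sequence_diversity", vals_c)]:
        ls = make_landscape(vals)
        ls.statistic = name
        sets[name] = extract_hotspots(classify_sd(ls), ls)
    report = hotspot_report(sets)
    assert len(report) == 2
    both = report[report["flag_divergence"]]
    assert bool(both["flag_gene_diversity"].iloc[0])
    assert not bool(both["flag_sequence_diversity"].iloc[0])
    only_c = report[report["flag_sequence_diversity"]]
    assert not bool(only_c["flag_divergence"].iloc[0])
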