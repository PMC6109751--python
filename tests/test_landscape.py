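"""Midpoints, IDW interpolation, averaging and clipping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from genescape.landscape import (GeneticLandscape, GridSpec,
                                 average_landscapes, clip_to_boundary,
                                 divergence_midpoints, geodesic_midpoint,
                                 idw_interpolate, multi_species_average)


class Rec:
    def __init__(self, pid, lon, lat):
        self.population_id, self.lon, self.lat = pid, lon, lat


def _pairs_frame(rows):
    import pandas as pd
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst_norm"])


def test_planar_midpoint():
    pts = divergence_midpoints(_pairs_frame([("a", "b", 0.4)]),
                               [Rec("a", 0, 0), Rec("b", 2, 2)])
    assert np.allclose(pts, [[1.0, 1.0, 0.4]])


def test_haversine_equatorial_midpoint():
    lon, lat = geodesic_midpoint(0.0, 0.0, 90.0, 0.0)
    assert lon == pytest.approx(45.0) and lat == pytest.approx(0.0, abs=1e-9)


def test_midpoint_count_is_choose_two():
    recs = [Rec(f"p{i}", i * 0.1, 0.0) for i in range(10)]
    rows = [(f"p{i}", f"p{j}", 0.5) for i in range(10) for j in range(i + 1, 10)]
    assert len(divergence_midpoints(_pairs_frame(rows), recs)) == 45


GRID = GridSpec(0.0, 0.0, 0.25, 8, 8)


def test_idw_constant_field_reproduced():
    pts = np.array([[0.1, 0.1, 0.7], [1.5, 1.2, 0.7], [1.9, 0.3, 0.7]])
    ls = idw_interpolate(pts, GRID, k_neighbors=2)
    assert np.allclose(ls.values, 0.7)


def test_idw_exact_at_data_point():
    # (0.625, 0.625) is a cell center of GRID
    pts = np.array([[0.625, 0.625, 0.3], [1.3, 1.4, 0.9]])
    ls = idw_interpolate(pts, GRID, k_neighbors=2)
    row, col = 5, 2  # y index from north: nrows - 1 - 2
    assert ls.values[GRID.nrows - 1 - 2, 2] == pytest.approx(0.3)


def test_idw_equidistant_symmetry():
    pts = np.array([[0.0, 1.0, 0.0], [2.0, 1.0, 1.0]])
    ls = idw_interpolate(pts, GRID, k_neighbors=2)
    mid_col = np.isclose(GRID.cell_centers()[0][0], 1.0)
    assert np.allclose(ls.values[:, mid_col], 0.5)


def test_idw_convexity_and_order_invariance(rng):
    for _ in range(20):
        pts = np.column_stack([rng.uniform(0, 2, 15), rng.uniform(0, 2, 15),
                               rng.uniform(0, 1, 15)])
        ls = idw_interpolate(pts, GRID, k_neighbors=5)
        assert ls.values.min() >= pts[:, 2].min() - 1e-12
        assert ls.values.max() <= pts[:, 2].max() + 1e-12
        shuffled = pts[rng.permutation(len(pts))]
        assert np.allclose(idw_interpolate(shuffled, GRID, k_neighbors=5).values,
                           ls.values)


def test_idw_duplicate_point_set_invariance(rng):
    pts = np.column_stack([rng.uniform(0, 2, 10), rng.uniform(0, 2, 10),
                           rng.uniform(0, 1, 10)])
    once = idw_interpolate(pts, GRID, k_neighbors=4).values
    twice = idw_interpolate(np.vstack([pts, pts]), GRID, k_neighbors=4).values
    assert np.allclose(once, twice)


def test_idw_k_reduced_with_warning():
    pts = np.array([[0.5, 0.5, 0.2], [1.5, 1.5, 0.8]])
    with pytest.warns(UserWarning, match="exceeds point count"):
        idw_interpolate(pts, GRID, k_neighbors=12)


def test_idw_empty_points_fatal():
    with pytest.raises(ValueError):
        idw_interpolate(np.empty((0, 3)), GRID)


def test_planar_haversine_agree_on_small_equatorial_region():
    grid = GridSpec(0.0, 0.0, 0.01, 10, 10, crs="lonlat")
    rng = np.random.default_rng(5)
    pts = np.column_stack([rng.uniform(0, 0.1, 12), rng.uniform(0, 0.1, 12),
                           rng.uniform(0, 1, 12)])
    a = idw_interpolate(pts, grid, metric="planar").values
    b = idw_interpolate(pts, grid, metric="haversine").values
    assert np.max(np.abs(a - b)) < 1e-3


def test_average_landscapes_examples():
    g = GridSpec(0, 0, 1.0, 3, 3)
    a = GeneticLandscape(g, np.full((3, 3), 0.2))
    b = GeneticLandscape(g, np.full((3, 3), 0.6))
    assert np.allclose(average_landscapes([a, b]).values, 0.4)
    assert np.allclose(average_landscapes([a]).values, a.values)


def test_two_stage_species_average():
    """Two markers of one species average before the cross-species mean."""
    g = GridSpec(0, 0, 1.0, 2, 2)
    sp1_m1 = GeneticLandscape(g, np.zeros((2, 2)))
    sp1_m2 = GeneticLandscape(g, np.ones((2, 2)))
    sp2 = GeneticLandscape(g, np.full((2, 2), 0.5))
    multi = multi_species_average({"sp1": [sp1_m1, sp1_m2], "sp2": [sp2]})
    assert np.allclose(multi.values, 0.5)  # mean(mean(0,1), 0.5)


def test_average_commutative_and_idempotent(rng):
    g = GridSpec(0, 0, 1.0, 4, 4)
    a = GeneticLandscape(g, rng.uniform(0, 1, (4, 4)))
    b = GeneticLandscape(g, rng.uniform(0, 1, (4, 4)))
    assert np.allclose(average_landscapes([a, b]).values,
                       average_landscapes([b, a]).values)
    assert np.allclose(average_landscapes([a, a]).values, a.values)


def test_average_min_coverage_masks_cells():
    g = GridSpec(0, 0, 1.0, 2, 2)
    a_vals = np.array([[0.2, np.nan], [0.2, 0.2]])
    b_vals = np.full((2, 2), 0.6)
    avg = average_landscapes([GeneticLandscape(g, a_vals),
                              GeneticLandscape(g, b_vals)], min_coverage=2)
    assert np.isnan(avg.values[0, 1]) and avg.values[0, 0] == pytest.approx(0.4)


def test_average_mismatched_grids_fatal():
    a = GeneticLandscape(GridSpec(0, 0, 1.0, 2, 2), np.zeros((2, 2)))
    b = GeneticLandscape(GridSpec(0, 0, 0.5, 2, 2), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        average_landscapes([a, b])


def test_clip_identity_halfplane_and_disjoint():
    g = GridSpec(0, 0, 0.25, 8, 8)
    ls = GeneticLandscape(g, np.full((8, 8), 0.5))
    whole = clip_to_boundary(ls, box(-1, -1, 3, 3))
    assert whole.n_valid == 64

    half = clip_to_boundary(ls, box(-1, -1, 1.0, 3))  # x < 1.0 half
    gx, _ = g.cell_centers()
    expected = (gx < 1.0).sum()
    assert half.n_valid == expected == 32

    with pytest.warns(UserWarning, match="disjoint"):
        none = clip_to_boundary(ls, box(10, 10, 11, 11))
    assert none.n_valid == 0


def test_clip_matches_point_in_polygon_oracle(rng):
    g = GridSpec(0, 0, 0.2, 10, 10)
    ls = GeneticLandscape(g, rng.uniform(0, 1, (10, 10)))
    poly = Polygon([(0.1, 0.1), (1.9, 0.3), (1.2, 1.9), (0.2, 1.4)])
    clipped = clip_to_boundary(ls, poly)
    gx, gy = g.cell_centers()
    from shapely.geometry import Point
    for i in range(10):
        for j in range(10):
            inside = poly.contains(Point(gx[i, j], gy[i, j]))
            assert np.isfinite(clipped.values[i, j]) == inside


def test_lonlat_cell_area_uses_cos_latitude():
    g = GridSpec(0, 59.0, 1.0, 1, 2, crs="lonlat")
    areas = g.cell_areas()
    # northern row (row 0) is at lat 60.5, southern at 59.5
    assert areas[0, 0] < areas[1, 0]
    assert areas[1, 0] == pytest.approx(111.195 ** 2 * np.cos(np.radians(59.5)))
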