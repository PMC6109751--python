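"""Interpolated genetic-landscape rasters.

Per-population diversity values (or per-population-pair divergence values
placed at pair midpoints) are interpolated onto a regular grid with
inverse-distance weighting, then averaged cellwise across species into a
multi-species genetic landscape.

Grids may live in planar coordinates (synthetic unit-square studies) or in
geographic lon/lat degrees; the ``crs`` attribute selects the distance and
cell-area conventions. Nodata cells are represented by NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

#: kilometres per degree of great-circle arc (mean Earth radius sphere).
KM_PER_DEGREE = 111.195
EARTH_RADIUS_KM = KM_PER_DEGREE * 180.0 / math.pi

_COINCIDENT_EPS = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Regular grid addressed from its lower-left corner.

    ``origin`` is the lower-left corner of the lower-left cell (ESRI
    ``xllcorner``/``yllcorner``). In-memory arrays follow the ESRI raster
    convention: row 0 is the northernmost row.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    ncols: int
    nrows: int
    crs: str = "planar"  # "planar" | "lonlat"

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs not in ("planar", "lonlat"):
            raise ValueError(f"unknown crs {self.crs!r}")

    @classmethod
    def from_bounds(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                    cell_size: float, crs: str = "planar") -> "GridSpec":
        ncols = max(1, int(math.ceil((xmax - xmin) / cell_size - 1e-9)))
        nrows = max(1, int(math.ceil((ymax - ymin) / cell_size - 1e-9)))
        return cls(xmin, ymin, cell_size, ncols, nrows, crs)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped (nrows, ncols), row 0 north."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.origin_y + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_areas(self) -> np.ndarray:
        """Cell areas, shaped (nrows, ncols).

        Planar grids report cell_size**2 in squared grid units; lon/lat grids
        report km**2 with the cos-latitude correction.
        """
        if self.crs == "planar":
            return np.full((self.nrows, self.ncols), self.cell_size ** 2)
        _, ys = self.cell_centers()
        side_km = self.cell_size * KM_PER_DEGREE
        return side_km ** 2 * np.cos(np.radians(ys))


@dataclass
class GeneticLandscape:
    """A raster of one (normalized) genetic statistic.

    ``values`` is (nrows, ncols) with NaN marking nodata; ``statistic`` is one
    of ``divergence`` / ``gene_diversity`` / ``sequence_diversity``;
    ``species_id`` is a species name or ``"multi-species"``.
    """

    grid: GridSpec
    values: np.ndarray
    statistic: str = "divergence"
    species_id: str = "multi-species"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"grid is {self.grid.nrows}x{self.grid.ncols} but values are "
                f"{self.values.shape}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def area_km2(self) -> float:
        """Total area of unmasked cells (km^2 for lon/lat, grid units planar)."""
        return float(self.grid.cell_areas()[self.mask].sum())

    def copy(self) -> "GeneticLandscape":
        return replace(self, values=self.values.copy())


# ---------------------------------------------------------------------------
# distances and midpoints


def _lonlat_to_unit_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.stack([np.cos(phi) * np.cos(lam),
                     np.cos(phi) * np.sin(lam),
                     np.sin(phi)], axis=-1)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between lon/lat points (degrees)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((phi2 - phi1) / 2) ** 2
         + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2)
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_midpoint(lon1, lat1, lon2, lat2) -> tuple[float, float]:
    """Great-circle midpoint of two lon/lat points (degrees).

    Antipodal pairs have no unique midpoint; the normalized chord midpoint is
    returned for near-antipodal input, which is deterministic but arbitrary.
    """
    v = _lonlat_to_unit_xyz(np.asarray([lon1, lon2]), np.asarray([lat1, lat2]))
    m = v.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < 1e-12:  # antipodal: fall back to planar midpoint
        return (lon1 + lon2) / 2.0, (lat1 + lat2) / 2.0
    m /= norm
    return (math.degrees(math.atan2(m[1], m[0])),
            math.degrees(math.asin(np.clip(m[2], -1.0, 1.0))))


def divergence_midpoints(pairwise, population_records,
                         metric: str = "planar",
                         value_column: str = "fst_norm") -> np.ndarray:
    """Place each population pair's divergence at the pair midpoint.

    Parameters
    ----------
    pairwise
        A :class:`~genescape.popgen_stats.PairwiseDivergence` or a long-format
        DataFrame with columns ``pop_a``, ``pop_b`` and *value_column*.
    population_records
        Iterable of records with ``population_id``, ``lon``, ``lat``.
    metric
        ``planar`` for arithmetic midpoints, ``haversine`` for great-circle
        geodesic midpoints.

    Returns
    -------
    ndarray of shape (n_pairs, 3): columns x, y, value. Pairs whose value is
    missing (NaN) are dropped.
    """
    coords = {r.population_id: (r.lon, r.lat) for r in population_records}
    frame = pairwise.to_frame() if hasattr(pairwise, "to_frame") else pairwise
    out = []
    for row in frame.itertuples(index=False):
        v = getattr(row, value_column)
        if not np.isfinite(v):
            continue
        x1, y1 = coords[row.pop_a]
        x2, y2 = coords[row.pop_b]
        if metric == "haversine":
            mx, my = geodesic_midpoint(x1, y1, x2, y2)
        else:
            mx, my = (x1 + x2) / 2.0, (y1 + y2) / 2.0
        out.append((mx, my, float(v)))
    return np.asarray(out, dtype=float).reshape(-1, 3)


def diversity_points(within_pop, population_records,
                     value_column: str) -> np.ndarray:
    """Place per-population diversity values at the collection locations."""
    coords = {r.population_id: (r.lon, r.lat) for r in population_records}
    frame = within_pop.to_frame() if hasattr(within_pop, "to_frame") else within_pop
    out = []
    for row in frame.itertuples(index=False):
        v = getattr(row, value_column)
        if not np.isfinite(v):
            continue
        x, y = coords[row.population_id]
        out.append((x, y, float(v)))
    return np.asarray(out, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# IDW interpolation


def _preaverage_coincident(points: np.ndarray) -> np.ndarray:
    """Average values of points at identical coordinates into one point.

    IDW weights diverge at zero distance, so coincident samples are collapsed
    to their mean first; this also makes the surface invariant to duplicating
    the full point set.
    """
    if len(points) == 0:
        return points
    order = np.lexsort((points[:, 1], points[:, 0]))
    pts = points[order]
    keys = pts[:, :2]
    new_group = np.any(keys[1:] != keys[:-1], axis=1)
    group_ids = np.concatenate([[0], np.cumsum(new_group)])
    n_groups = group_ids[-1] + 1
    out = np.empty((n_groups, 3))
    np.add.at(counts := np.zeros(n_groups), group_ids, 1)
    np.add.at(sums := np.zeros(n_groups), group_ids, pts[:, 2])
    first = np.searchsorted(group_ids, np.arange(n_groups))
    out[:, :2] = keys[first]
    out[:, 2] = sums / counts
    return out


def idw_interpolate(points: np.ndarray, grid_spec: GridSpec,
                    power: float = 2.0, k_neighbors: int = 12,
                    metric: str | None = None,
                    statistic: str = "divergence",
                    species_id: str = "multi-species") -> GeneticLandscape:
    """Inverse-distance-weighted interpolation onto a grid.

    Each cell center takes the weighted mean of its *k_neighbors* nearest
    sample points with weights d**(-power) ("variable search radius": the
    k-th neighbor sets the radius, however far). A cell coinciding with a
    sample point takes that point's value exactly. *metric* defaults to the
    grid's natural metric: planar distance for planar grids, great-circle km
    for lon/lat grids.

    Parameters
    ----------
    points
        (n, 3) array of x, y, value rows.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("idw_interpolate requires at least one point")
    if metric is None:
        metric = "haversine" if grid_spec.crs == "lonlat" else "planar"
    points = _preaverage_coincident(points)
    k = min(int(k_neighbors), len(points))
    if k < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k < k_neighbors:
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds point count; using k={k}",
            stacklevel=2)

    gx, gy = grid_spec.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    if metric == "haversine":
        # kNN on 3-D chord distance preserves great-circle ordering; weights
        # use the true arc length in km.
        src = _lonlat_to_unit_xyz(points[:, 0], points[:, 1])
        tgt = _lonlat_to_unit_xyz(targets[:, 0], targets[:, 1])
        dist_chord, idx = cKDTree(src).query(tgt, k=k)
        half = np.clip(dist_chord / 2.0, 0.0, 1.0)
        dist = EARTH_RADIUS_KM * 2.0 * np.arcsin(half)
        eps = _COINCIDENT_EPS
    elif metric == "planar":
        dist, idx = cKDTree(points[:, :2]).query(targets, k=k)
        eps = _COINCIDENT_EPS
    else:
        raise ValueError(f"unknown metric {metric!r}")

    dist = np.atleast_2d(dist.reshape(len(targets), k))
    idx = np.atleast_2d(idx.reshape(len(targets), k))
    vals = points[idx, 2]

    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    exact = dist[:, 0] < eps  # coincident points were pre-averaged: k=1 hit
    w[~np.isfinite(w)] = 0.0
    cell = np.einsum("ij,ij->i", w, vals)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        cell = cell / wsum
    cell[exact] = vals[exact, 0]
    return GeneticLandscape(grid_spec, cell.reshape(gx.shape),
                            statistic=statistic, species_id=species_id)


# ---------------------------------------------------------------------------
# averaging and clipping


def average_landscapes(landscapes: list[GeneticLandscape],
                       min_coverage: int = 1,
                       species_id: str = "multi-species") -> GeneticLandscape:
    """Cellwise arithmetic mean over landscapes on a shared grid.

    Cells unmasked in fewer than *min_coverage* inputs are masked in the
    result. Inputs must share an identical :class:`GridSpec`.
    """
    if not landscapes:
        raise ValueError("average_landscapes requires at least one landscape")
    grid = landscapes[0].grid
    for ls in landscapes[1:]:
        if ls.grid != grid:
            raise ValueError("landscapes are not on a shared grid")
    stack = np.stack([ls.values for ls in landscapes])
    coverage = np.isfinite(stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(stack, axis=0)
    mean[coverage < max(1, min_coverage)] = np.nan
    return GeneticLandscape(grid, mean, statistic=landscapes[0].statistic,
                            species_id=species_id)


def multi_species_average(per_species: dict[str, list[GeneticLandscape]],
                          min_coverage: int = 1) -> GeneticLandscape:
    """Two-stage average: markers within species first, then across species.

    A species with several marker landscapes contributes one vote — its
    within-species mean — so marker-rich species do not dominate.
    """
    species_means = [
        average_landscapes(markers, species_id=sp)
        for sp, markers in sorted(per_species.items()) if markers
    ]
    return average_landscapes(species_means, min_coverage=min_coverage)


def clip_to_boundary(landscape: GeneticLandscape,
                     polygon: BaseGeometry) -> GeneticLandscape:
    """Mask cells whose centers fall outside *polygon*."""
    if not polygon.is_valid:
        polygon = polygon.buffer(0)
    gx, gy = landscape.grid.cell_centers()
    inside = contains_xy(polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    values = landscape.values.copy()
    values[~inside] = np.nan
    clipped = replace(landscape, values=values)
    if clipped.n_valid == 0:
        warnings.warn("boundary polygon is disjoint from the grid: "
                      "all cells masked", stacklevel=2)
    return clipped
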