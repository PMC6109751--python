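"""Hotspot delineation by standard-deviation classification.

A multi-species landscape is divided into classes one standard deviation
wide, with the middle class centered on the mean (mean - 0.5 sd to
mean + 0.5 sd). Cells more than 1.5 sd above the mean are "evolutionary
hotspots"; maximal connected components of such cells form numbered hotspot
patches, and patches from the divergence / gene-diversity /
sequence-diversity layers that overlap spatially are unified into one
reporting row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import GeneticLandscape

STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class SdClassification:
    """Standard-deviation classes of a landscape.

    ``class_raster`` holds the integer class per cell (0 = the middle class,
    +k/-k the k-th class above/below; class k spans
    [mean + (k-0.5) sd, mean + (k+0.5) sd)); nodata cells hold the minimum
    int32. ``class_edges`` lists the interior cut values in ascending order.
    """

    mean: float
    sd: float
    class_raster: np.ndarray
    class_edges: list[float]

    NODATA_CLASS = np.iinfo(np.int32).min


def classify_sd(landscape: GeneticLandscape) -> SdClassification:
    """Classify a landscape into 1-sd-wide classes around its mean.

    Mean and sd are taken over unmasked cells with the population (N)
    denominator: the classification describes the realized raster, not a
    sample from it. A constant raster (sd = 0) degenerates to a single
    middle class.
    """
    vals = landscape.valid_values()
    if len(vals) < 2:
        raise ValueError("classification needs at least two unmasked cells")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    classes = np.full(landscape.values.shape, SdClassification.NODATA_CLASS,
                      dtype=np.int32)
    if sd == 0.0:
        warnings.warn("landscape has zero variance: single middle class, "
                      "no hotspots", stacklevel=2)
        classes[landscape.mask] = 0
        return SdClassification(mean, 0.0, classes, [])
    z = (landscape.values - mean) / sd
    with np.errstate(invalid="ignore"):
        k = np.floor(z + 0.5).astype(np.int32)
    classes[landscape.mask] = k[landscape.mask]
    lo, hi = int(classes[landscape.mask].min()), int(classes[landscape.mask].max())
    edges = [mean + (c - 0.5) * sd for c in range(lo + 1, hi + 1)]
    return SdClassification(mean, sd, classes, edges)


@dataclass
class HotspotPatch:
    patch_id: int
    statistic: str
    cells: list[tuple[int, int]]        # (row, col)
    area: float                          # km^2 (lonlat) or grid units (planar)
    centroid: tuple[float, float]        # lon/lat (or planar x/y)
    mean_value: float


@dataclass
class HotspotSet:
    statistic: str
    threshold: float
    patches: list[HotspotPatch]
    total_hotspot_area: float
    fraction_of_analyzed_area: float
    n_flagged_cells: int
    n_valid_cells: int

    def flagged_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for p in self.patches:
            rows, cols = zip(*p.cells)
            mask[list(rows), list(cols)] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "patch_id": p.patch_id, "statistic": p.statistic,
            "n_cells": len(p.cells), "area": p.area,
            "centroid_lon": p.centroid[0], "centroid_lat": p.centroid[1],
            "mean_value": p.mean_value,
        } for p in self.patches])


def _merge_close_patches(labels: np.ndarray, n_patches: int,
                         landscape: GeneticLandscape,
                         merge_distance: float) -> np.ndarray:
    """Union patches whose minimum inter-cell center distance <= merge_distance."""
    gx, gy = landscape.grid.cell_centers()
    coords = [np.column_stack([gx[labels == i + 1], gy[labels == i + 1]])
              for i in range(n_patches)]
    parent = list(range(n_patches))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_patches):
        for j in range(i + 1, n_patches):
            dmin = np.sqrt(((coords[i][:, None, :] - coords[j][None, :, :]) ** 2
                            ).sum(-1)).min()
            if dmin <= merge_distance:
                parent[find(i)] = find(j)
    remap = {}
    out = labels.copy()
    for i in range(n_patches):
        root = find(i)
        remap.setdefault(root, len(remap) + 1)
        out[labels == i + 1] = remap[root]
    return out


def extract_hotspots(classification: SdClassification,
                     landscape: GeneticLandscape,
                     connectivity: int = 8,
                     min_cells: int = 1,
                     merge_distance: float = 0.0,
                     threshold_multiplier: float = 1.5) -> HotspotSet:
    """Extract hotspot patches: connected cells above mean + 1.5 sd.

    Patches are numbered in decreasing area order (ties broken by the
    northernmost, then westernmost member cell, i.e. smallest row then
    column index), so labeling is deterministic. ``merge_distance > 0``
    optionally unifies patches closer than that distance before numbering.
    """
    if connectivity not in STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    threshold = classification.mean + threshold_multiplier * classification.sd
    if classification.sd == 0.0:
        hot = np.zeros_like(landscape.values, dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            hot = landscape.mask & (landscape.values > threshold)
    labels, n = ndimage.label(hot, structure=STRUCTURES[connectivity])
    if n and merge_distance > 0:
        labels = _merge_close_patches(labels, n, landscape, merge_distance)
        n = labels.max()

    areas = landscape.grid.cell_areas()
    gx, gy = landscape.grid.cell_centers()
    patches = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if len(rows) < min_cells:
            continue
        patch_area = float(areas[rows, cols].sum())
        patches.append(HotspotPatch(
            patch_id=-1, statistic=landscape.statistic,
            cells=list(zip(rows.tolist(), cols.tolist())),
            area=patch_area,
            centroid=(float(gx[rows, cols].mean()), float(gy[rows, cols].mean())),
            mean_value=float(landscape.values[rows, cols].mean())))
    patches.sort(key=lambda p: (-p.area, min(p.cells)))
    for i, p in enumerate(patches, start=1):
        p.patch_id = i

    n_flagged = sum(len(p.cells) for p in patches)
    total_area = sum(p.area for p in patches)
    analyzed = float(areas[landscape.mask].sum())
    return HotspotSet(
        statistic=landscape.statistic, threshold=float(threshold),
        patches=patches, total_hotspot_area=total_area,
        fraction_of_analyzed_area=total_area / analyzed if analyzed else 0.0,
        n_flagged_cells=n_flagged, n_valid_cells=landscape.n_valid)


def hotspot_report(hotspot_sets: dict[str, HotspotSet]) -> pd.DataFrame:
    """Unify hotspot layers into one table of spatially overlapping groups.

    Patches from different statistics that share at least one cell join the
    same group; each row carries a boolean flag per statistic plus the
    member patch ids, so one table shows which diversity components mark
    each geographic hotspot.
    """
    entries = []  # (statistic, patch)
    for stat, hs in sorted(hotspot_sets.items()):
        for p in hs.patches:
            entries.append((stat, p))
    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cell_sets = [set(p.cells) for _, p in entries]
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if cell_sets[i] & cell_sets[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(find(i), []).append(i)

    rows = []
    stats = sorted(hotspot_sets)
    for members in groups.values():
        cells = set().union(*(cell_sets[i] for i in members))
        flagged = {entries[i][0] for i in members}
        row = {"n_cells": len(cells),
               "members": ";".join(f"{entries[i][0]}:{entries[i][1].patch_id}"
                                   for i in sorted(members))}
        for s in stats:
            row[f"flag_{s}"] = s in flagged
        rows.append((min(cells), row))
    rows.sort(key=lambda t: t[0])  # north-west first, deterministic
    out = pd.DataFrame([r for _, r in rows])
    if not out.empty:
        out.insert(0, "hotspot_id", range(1, len(out) + 1))
    return out
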