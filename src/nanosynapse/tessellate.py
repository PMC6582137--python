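"""Voronoi-tessellation density segmentation (SR-Tesseler-style).

Every localization gets a Voronoi cell; the inverse cell area is a local
density estimate. Segmentation is two-level: *objects* (neurites) are
connected components of localizations denser than ``object_factor`` (default
2) times the image-average density, and *clusters* (protein clusters) are
connected components within an object denser than ``cluster_factor``
(default 3) times the object-local average density, subject to a minimum
polygonal area (default 0.0005 um^2). Cells are clipped to the analysis
region so that their areas partition it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Voronoi
from scipy.spatial._qhull import QhullError
from shapely.geometry import Polygon, box
from shapely.prepared import prep

from .errors import DegenerateGeometryError, InvalidArgumentError, ROIRejectedError

NM2_PER_UM2 = 1e6


@dataclass
class DensityField:
    """Per-localization Voronoi cells, areas and local densities."""

    points_nm: np.ndarray          # (N, 2)
    cell_areas_nm2: np.ndarray     # (N,) clipped to the region
    density_per_nm2: np.ndarray    # (N,) local density estimate
    avg_density_per_nm2: float     # N / region area
    region: Polygon
    neighbor_pairs: np.ndarray     # (M, 2) indices of Voronoi-adjacent cells
    cell_polygons: Optional[list] = None

    @property
    def n(self) -> int:
        return len(self.points_nm)


def _as_region(region, points: np.ndarray) -> Polygon:
    if region is None:
        # pad the bounding box by the median nearest-neighbor distance so
        # border cells stay finite without inflating the analyzed area
        from scipy.spatial import cKDTree

        d, _ = cKDTree(points).query(points, k=2)
        pad = float(np.median(d[:, 1]))
        x0, y0 = points.min(axis=0) - pad
        x1, y1 = points.max(axis=0) + pad
        return box(x0, y0, x1, y1)
    if isinstance(region, Polygon):
        return region
    arr = np.asarray(region, dtype=float)
    if arr.shape == (4,):
        return box(*arr)
    return Polygon(arr)


def voronoi_density(
    points_nm,
    region=None,
    density_mode: str = "cell",
    keep_polygons: bool = False,
) -> DensityField:
    """Tessellate a point set and estimate per-localization densities.

    ``density_mode='cell'`` uses 1/(own cell area); ``'rank1'`` averages over
    the cell and its first-rank Voronoi neighbors. Cells are clipped to
    ``region`` (shapely polygon, (xmin, ymin, xmax, ymax), or a vertex
    array; default: data bounding box padded by the median nearest-neighbor
    distance).
    """
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points must be (N, 2)")
    n = len(pts)
    if n < 4:
        raise DegenerateGeometryError("need >= 4 localizations")
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("all localizations are collinear")
    poly = _as_region(region, pts)
    if poly.area <= 0:
        raise InvalidArgumentError("region has zero area")
    if density_mode not in ("cell", "rank1"):
        raise InvalidArgumentError(f"unknown density_mode '{density_mode}'")

    # ghost points on a distant circle bound every real cell, so that all
    # real cells are finite polygons before clipping
    cx, cy = pts.mean(axis=0)
    diam = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), np.sqrt(poly.area))
    minx, miny, maxx, maxy = poly.bounds
    diam = max(diam, maxx - minx, maxy - miny)
    ang = np.linspace(0.0, 2.0 * np.pi, 33)[:-1]
    ghosts = np.column_stack([cx + 4.0 * diam * np.cos(ang), cy + 4.0 * diam * np.sin(ang)])
    try:
        vor = Voronoi(np.vstack([pts, ghosts]))
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point configuration: {exc}") from exc

    prepared = prep(poly)
    areas = np.zeros(n)
    polys = [None] * n if keep_polygons else None
    for i in range(n):
        reg = vor.regions[vor.point_region[i]]
        if -1 in reg or len(reg) < 3:
            raise DegenerateGeometryError("unbounded cell despite ghost points (collinear input?)")
        verts = vor.vertices[reg]
        cell = Polygon(verts)
        if prepared.contains_properly(cell):
            clipped = cell
        else:
            clipped = cell.intersection(poly)
        areas[i] = clipped.area
        if keep_polygons:
            polys[i] = clipped

    ridge = vor.ridge_points
    real = (ridge[:, 0] < n) & (ridge[:, 1] < n)
    pairs = ridge[real]

    if density_mode == "cell":
        density = np.where(areas > 0, 1.0 / np.where(areas > 0, areas, 1.0), np.inf)
    else:
        deg = np.zeros(n)
        asum = areas.copy()
        np.add.at(deg, pairs[:, 0], 1)
        np.add.at(deg, pairs[:, 1], 1)
        np.add.at(asum, pairs[:, 0], areas[pairs[:, 1]])
        np.add.at(asum, pairs[:, 1], areas[pairs[:, 0]])
        density = np.where(asum > 0, (deg + 1.0) / np.where(asum > 0, asum, 1.0), np.inf)

    return DensityField(
        points_nm=pts,
        cell_areas_nm2=areas,
        density_per_nm2=density,
        avg_density_per_nm2=n / poly.area,
        region=poly,
        neighbor_pairs=pairs,
        cell_polygons=polys,
    )


@dataclass
class VoronoiObject:
    indices: np.ndarray
    n_locs: int
    area_nm2: float

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2


@dataclass
class VoronoiCluster:
    indices: np.ndarray
    n_locs: int
    area_um2: float
    centroid_nm: np.ndarray
    object_id: int


@dataclass
class VoronoiClusterSet:
    clusters: list

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.clusters])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.clusters)),
                "object_id": [c.object_id for c in self.clusters],
                "n_locs": [c.n_locs for c in self.clusters],
                "area_um2": [c.area_um2 for c in self.clusters],
                "centroid_x_nm": [c.centroid_nm[0] for c in self.clusters],
                "centroid_y_nm": [c.centroid_nm[1] for c in self.clusters],
            }
        )


def _components(subset: np.ndarray, pairs: np.ndarray, n_total: int):
    """Connected components of ``subset`` under Voronoi-neighbor adjacency."""
    keep = np.zeros(n_total, dtype=bool)
    keep[subset] = True
    sel = keep[pairs[:, 0]] & keep[pairs[:, 1]]
    sub = pairs[sel]
    remap = -np.ones(n_total, dtype=int)
    remap[subset] = np.arange(len(subset))
    m = len(subset)
    if m == 0:
        return []
    graph = sparse.coo_matrix(
        (np.ones(len(sub)), (remap[sub[:, 0]], remap[sub[:, 1]])), shape=(m, m)
    )
    ncomp, labels = connected_components(graph, directed=False)
    return [subset[labels == k] for k in range(ncomp)]


def segment_objects(field: DensityField, object_factor: float = 2.0):
    """Objects: connected localization groups at >= object_factor x average density."""
    kept = np.flatnonzero(field.density_per_nm2 >= object_factor * field.avg_density_per_nm2)
    comps = _components(kept, field.neighbor_pairs, field.n)
    return [
        VoronoiObject(indices=c, n_locs=len(c), area_nm2=float(field.cell_areas_nm2[c].sum()))
        for c in comps
    ]


def _cluster_area_um2(field: DensityField, comp: np.ndarray, area_mode: str) -> float:
    if area_mode == "cells":
        return float(field.cell_areas_nm2[comp].sum()) / NM2_PER_UM2
    if len(comp) < 3:
        return 0.0
    pts = field.points_nm[comp]
    try:
        return float(ConvexHull(pts).volume) / NM2_PER_UM2  # 2D: volume == area
    except QhullError:
        return 0.0


def segment_clusters(
    field: DensityField,
    objects: Sequence[VoronoiObject],
    cluster_factor: float = 3.0,
    min_area_um2: float = 0.0005,
    min_locs: int = 5,
    reference: str = "object",
    area_mode: str = "hull",
) -> VoronoiClusterSet:
    """Clusters within objects at >= cluster_factor x the reference density.

    ``reference='object'`` (default) thresholds against the object-local
    average density n_object / area_object; ``'global'`` against the image
    average. Components below ``min_area_um2`` or with fewer than
    ``min_locs`` localizations are discarded.

    ``area_mode='hull'`` (default) reports the convex-hull area of the
    member localizations, which is an unbiased estimate of a compact
    cluster's footprint; ``'cells'`` sums the member Voronoi cell areas,
    which inflates the footprint by the half-gap to the surrounding sparse
    background (border cells bulge outward).
    """
    if reference not in ("object", "global"):
        raise InvalidArgumentError(f"unknown reference '{reference}'")
    if area_mode not in ("hull", "cells"):
        raise InvalidArgumentError(f"unknown area_mode '{area_mode}'")
    clusters = []
    for oid, obj in enumerate(objects):
        if obj.area_nm2 <= 0:
            continue
        ref_density = (
            obj.n_locs / obj.area_nm2 if reference == "object" else field.avg_density_per_nm2
        )
        dense = obj.indices[
            field.density_per_nm2[obj.indices] >= cluster_factor * ref_density
        ]
        for comp in _components(dense, field.neighbor_pairs, field.n):
            area_um2 = _cluster_area_um2(field, comp, area_mode)
            if area_um2 < min_area_um2 or len(comp) < min_locs:
                continue
            clusters.append(
                VoronoiCluster(
                    indices=comp,
                    n_locs=len(comp),
                    area_um2=area_um2,
                    centroid_nm=field.points_nm[comp].mean(axis=0),
                    object_id=oid,
                )
            )
    return VoronoiClusterSet(clusters=clusters)


def punctae_per_micron(clusters, neurite_length_um: float) -> float:
    """Linear density of detected clusters along a neurite."""
    if neurite_length_um <= 0:
        raise InvalidArgumentError("neurite_length_um must be > 0")
    count = len(clusters) if not isinstance(clusters, (int, np.integer)) else int(clusters)
    return count / neurite_length_um


def synapse_cluster_area(
    table: pd.DataFrame,
    roi,
    channel: str,
    cluster_factor: float = 3.0,
    min_area_um2: float = 0.0005,
    min_locs: int = 5,
    min_roi_locs: int = 10,
    area_mode: str = "hull",
    reference_density_per_nm2: Optional[float] = None,
) -> float:
    """Area (um^2) of the largest protein cluster of one channel in a synapse ROI.

    Cluster identification runs within the ROI only: localizations denser
    than ``cluster_factor`` times the reference density form clusters. The
    reference is the channel's image-average density (its localization count
    over its bounding-box area), not the ROI average — a synapse ROI is drawn
    tightly around the cluster, so its own average density approaches the
    cluster density and a threshold relative to it would be
    self-referential. The object-segmentation level is likewise skipped:
    inside the ROI the object would be the cluster itself.
    """
    ch = table.loc[table["channel"] == channel]
    inside = ch.loc[roi.contains(ch["x_nm"], ch["y_nm"])]
    if len(inside) < max(min_roi_locs, 4):
        raise ROIRejectedError(
            f"channel '{channel}': {len(inside)} localizations in ROI"
        )
    if reference_density_per_nm2 is None:
        allpts = ch[["x_nm", "y_nm"]].to_numpy(dtype=float)
        extent = max(np.ptp(allpts[:, 0]) * np.ptp(allpts[:, 1]), roi.long_nm * roi.short_nm)
        reference_density_per_nm2 = len(allpts) / extent
    pts = inside[["x_nm", "y_nm"]].to_numpy(dtype=float)
    field_ = voronoi_density(pts, region=Polygon(roi.polygon_nm()))
    dense = np.flatnonzero(
        field_.density_per_nm2 >= cluster_factor * reference_density_per_nm2
    )
    best = 0.0
    for comp in _components(dense, field_.neighbor_pairs, field_.n):
        area_um2 = _cluster_area_um2(field_, comp, area_mode)
        if area_um2 >= min_area_um2 and len(comp) >= min_locs:
            best = max(best, area_um2)
    return best
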