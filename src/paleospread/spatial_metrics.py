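"""Great-circle geometry, 1-degree grid binning and palaeogeographic-spread metrics.

Geographic spread of a set of fossil localities is summarized by the summed
length of the minimum spanning tree (MST) over occupied grid cells, together
with convex-hull area, maximum great-circle distance, standard distance and
the count of occupied cells.  All distances are great-circle kilometres on a
sphere of mean radius 6371 km (so 1 degree of arc is ~111.19 km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridCell",
    "SpatialPool",
    "great_circle_km",
    "normalize_lon",
    "bin_to_grid",
    "build_mst",
    "spread_metrics",
    "metric_correlations",
]


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into (-180, 180]."""
    lon = math.fmod(lon, 360.0)
    if lon <= -180.0:
        lon += 360.0
    elif lon > 180.0:
        lon -= 360.0
    return lon


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not -90.0 <= lat <= 90.0 or not -180.0 < normalize_lon(lon) <= 180.0:
            raise ValueError(f"coordinate out of bounds: ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass(frozen=True)
class GridCell:
    """One occupied equal-angle grid cell.

    ``cell_id`` is the (lat_index, lon_index) pair from flooring the raw
    coordinates; the centroid sits at the cell centre and stands in for all
    member collections in distance computations.
    """

    cell_id: tuple[int, int]
    centroid: tuple[float, float]
    member_collections: frozenset = frozenset()


def bin_to_grid(
    collections: dict[str, tuple[float, float]], cell_deg: float = 1.0
) -> list[GridCell]:
    """Bin collection palaeocoordinates into cell_deg-degree grid cells.

    ``collections`` maps collection id -> (palaeolat, palaeolon).  The grid
    is anchored at (0, 0) and indexed by floor division; longitudes are
    normalized into (-180, 180] first.  Returns cells sorted by cell_id.
    """
    members: dict[tuple[int, int], set[str]] = {}
    for cid, (lat, lon) in collections.items():
        lon = normalize_lon(lon)
        key = (math.floor(lat / cell_deg), math.floor(lon / cell_deg))
        members.setdefault(key, set()).add(cid)
    cells = []
    for (i, j), mem in sorted(members.items()):
        centroid = ((i + 0.5) * cell_deg, normalize_lon((j + 0.5) * cell_deg))
        cells.append(GridCell((i, j), centroid, frozenset(mem)))
    return cells


def build_mst(
    cells: list[GridCell],
) -> tuple[list[tuple[tuple[int, int], tuple[int, int], float]], float]:
    """Exact MST over the complete great-circle graph of cell centroids.

    Returns (edges, summed_length_km) with each edge as (cell_id_a,
    cell_id_b, km), a < b and edges sorted.  Equal-weight ties break toward
    the lexicographically smaller cell-id pair (Kruskal with stable sort over
    lexicographically inserted edges).
    """
    if not cells:
        raise ValueError("build_mst requires at least one cell")
    by_id = {c.cell_id: c for c in sorted(cells, key=lambda c: c.cell_id)}
    ids = list(by_id)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            g.add_edge(u, v, weight=great_circle_km(by_id[u].centroid, by_id[v].centroid))
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in tree.edges(data=True)
    )
    return edges, float(sum(e[2] for e in edges))


def _unit_vectors(latlon: np.ndarray) -> np.ndarray:
    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def _mean_point(latlon: np.ndarray) -> tuple[float, float]:
    """Geographic mean: mean of unit vectors renormalized to the sphere."""
    v = _unit_vectors(latlon).mean(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-12:  # degenerate (e.g. antipodal pair): fall back to first point
        return float(latlon[0, 0]), float(latlon[0, 1])
    v = v / n
    return float(np.degrees(np.arcsin(np.clip(v[2], -1, 1)))), float(
        np.degrees(np.arctan2(v[1], v[0]))
    )


def _laea_project(latlon: np.ndarray, centre: tuple[float, float]) -> np.ndarray:
    """Lambert azimuthal equal-area projection (km) about ``centre``."""
    lat0, lon0 = math.radians(centre[0]), math.radians(centre[1])
    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    # k = sqrt(2 / (1 + cos c)); antipode of the centre is a singularity
    k = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0)
    )
    return np.column_stack([x, y])


@dataclass
class SpreadMetrics:
    summed_mst_km: float
    convex_hull_km2: float
    max_gcd_km: float
    standard_distance_km: float
    n_grid_cells: int
    hull_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "summed_mst_km": self.summed_mst_km,
            "convex_hull_km2": self.convex_hull_km2,
            "max_gcd_km": self.max_gcd_km,
            "standard_distance_km": self.standard_distance_km,
            "n_grid_cells": self.n_grid_cells,
        }


def spread_metrics(cells: list[GridCell]) -> SpreadMetrics:
    """All five spread metrics for a set of occupied grid cells.

    Standard distance is the RMS great-circle distance of cell centroids from
    their geographic mean point; the hull area is computed on a local
    equal-area projection about that point and is 0 (flagged degenerate) for
    fewer than 3 non-collinear cells.
    """
    if not cells:
        raise ValueError("spread_metrics requires at least one cell")
    _, mst_len = build_mst(cells)
    pts = np.array([c.centroid for c in cells], dtype=float)
    n = len(cells)
    max_gcd = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            max_gcd = max(max_gcd, great_circle_km(tuple(pts[i]), tuple(pts[j])))
    centre = _mean_point(pts)
    sd = math.sqrt(
        float(
            np.mean([great_circle_km(tuple(p), centre) ** 2 for p in pts])
        )
    )
    hull_area = 0.0
    degenerate = True
    if n >= 3:
        try:
            hull = ConvexHull(_laea_project(pts, centre))
            hull_area = float(hull.volume)  # 2-D: volume is the area
            degenerate = False
        except QhullError:
            pass  # collinear cells: keep area 0, degenerate
    return SpreadMetrics(mst_len, hull_area, max_gcd, sd, n, degenerate)


@dataclass(frozen=True)
class SpatialPool:
    """The occupied grid of one region x time bin, with its MST and metrics."""

    region_label: str
    bin: str
    cells: tuple
    mst_edges: tuple = field(default=())
    summed_mst_km: float = 0.0
    metrics: SpreadMetrics | None = None

    @classmethod
    def from_cells(cls, region_label: str, bin_name: str, cells: list[GridCell]):
        edges, total = build_mst(cells)
        return cls(
            region_label,
            bin_name,
            tuple(sorted(cells, key=lambda c: c.cell_id)),
            tuple(edges),
            total,
            spread_metrics(cells),
        )


def metric_correlations(pools: list[SpatialPool]):
    """Pearson correlation matrix of the spread metrics across pools.

    Returns a pandas DataFrame; entries involving a constant metric are NaN
    (correlation undefined).  Requires >= 3 pools with >= 2 cells each.
    """
    import pandas as pd

    usable = [p for p in pools if p.metrics is not None and len(p.cells) >= 2]
    if len(usable) < 3:
        raise ValueError("metric_correlations needs >= 3 pools with >= 2 cells")
    df = pd.DataFrame([p.metrics.as_dict() for p in usable])
    return df.corr(method="pearson")
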