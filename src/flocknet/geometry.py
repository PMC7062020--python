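"""Thiessen (Voronoi) breeding territories and neighbourhood order.

Each breeding pair's territory is the Voronoi cell of its nest, clipped to
the study-site boundary.  Two territories are neighbours (order 1) when
their polygons share a border of positive length — cells meeting only at a
point are a tessellation artefact, not neighbours.  The neighbourhood
order of any dyad is the shortest-path distance in the resulting adjacency
graph: order 2 means one territory in between, and so on.

Coordinates are planar metres; no geographic projection handling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: tolerance (m) below which a shared border counts as point contact
EDGE_TOLERANCE = 1e-9


@dataclass
class TerritoryMap:
    """Clipped Voronoi polygons plus the territory adjacency graph."""

    nest_ids: list
    polygons: dict
    adjacency: nx.Graph
    boundary: Polygon

    def area_check(self, tol: float = 1e-6) -> bool:
        """Territories partition the boundary (within relative tolerance)."""
        total = sum(p.area for p in self.polygons.values())
        return abs(total - self.boundary.area) <= tol * self.boundary.area


def resolve_breeding_records(broods: pd.DataFrame) -> pd.DataFrame:
    """Reduce raw brood records to one record per social pair.

    Replacement clutches are removed.  A polygynous male keeps only the
    nest of the female he settled with first (ties broken toward the lower
    nest_id, with a warning).
    """
    df = broods.copy()
    if "replacement" in df.columns:
        df = df[~df["replacement"].astype(bool)]
    df = df.assign(settle_date=pd.to_datetime(df["settle_date"]))
    df = df.sort_values(["male_tag", "settle_date", "nest_id"], kind="mergesort")
    ties = df[df.duplicated(subset=["male_tag"], keep=False)]
    for male, grp in ties.groupby("male_tag"):
        if grp["settle_date"].iloc[0] == grp["settle_date"].iloc[1]:
            logger.warning(
                "polygynous male %s with tied settle dates; keeping nest %s",
                male,
                grp["nest_id"].iloc[0],
            )
    df = df.drop_duplicates(subset=["male_tag"], keep="first")
    return df.sort_values("nest_id", kind="mergesort").reset_index(drop=True)


def _bounded_voronoi(points: np.ndarray, boundary: Polygon) -> list[Polygon]:
    """Voronoi cells clipped to the boundary.

    Qhull's diagram is unbounded; mirroring every point across the four
    sides of the boundary's bounding box closes all cells of the original
    points, which are then intersected with the boundary polygon.
    """
    minx, miny, maxx, maxy = boundary.bounds
    pad = 0.0
    mirrored = [points]
    for axis, bound in ((0, minx - pad), (0, maxx + pad), (1, miny - pad), (1, maxy + pad)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # cannot happen after mirroring
            raise RuntimeError("unbounded Voronoi cell despite mirroring")
        poly = Polygon(vor.vertices[region])
        poly = make_valid(poly).intersection(boundary)
        cells.append(poly)
    return cells


def assign_territories(nests: pd.DataFrame, boundary: Polygon) -> TerritoryMap:
    """Build the territory map from nest coordinates.

    ``nests`` needs columns nest_id, x, y.  Raises on coincident nests or
    nests outside the boundary.  Adjacency requires a shared border longer
    than :data:`EDGE_TOLERANCE`.
    """
    if len(nests) < 2:
        raise ValueError("need at least two nests for a tessellation")
    pts = nests[["x", "y"]].to_numpy(dtype=float)
    ids = list(nests["nest_id"])

    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(f"coincident nest coordinates: {ids[i]} and {ids[j]}")
    from shapely.geometry import Point

    outside = [ids[i] for i, p in enumerate(pts) if not boundary.covers(Point(p))]
    if outside:
        raise ValueError(f"nests outside the site boundary: {outside}")

    cells = _bounded_voronoi(pts, boundary)
    polygons = dict(zip(ids, cells))

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for (ia, a), (ib, b) in itertools.combinations(enumerate(ids), 2):
        inter = cells[ia].intersection(cells[ib])
        if inter.length > EDGE_TOLERANCE:
            graph.add_edge(a, b, border=inter.length)
    return TerritoryMap(nest_ids=ids, polygons=polygons, adjacency=graph, boundary=boundary)


def neighbourhood_order(tmap: TerritoryMap, max_order: int = 5) -> pd.DataFrame:
    """Dyadic neighbourhood orders (graph distance between territories).

    Dyads in disconnected components get a missing order; dyads beyond
    ``max_order`` are flagged out of range but their order is reported.
    """
    lengths = dict(nx.all_pairs_shortest_path_length(tmap.adjacency))
    rows = []
    for a, b in itertools.combinations(tmap.nest_ids, 2):
        order = lengths.get(a, {}).get(b)
        rows.append(
            (a, b, float(order) if order is not None else np.nan,
             order is not None and order <= max_order)
        )
    df = pd.DataFrame(rows, columns=["nest_a", "nest_b", "order", "in_range"])
    n_missing = int(df["order"].isna().sum())
    if n_missing:
        logger.warning("%d dyads have no neighbourhood order (disconnected map)", n_missing)
    return df


def order_matrix(tmap: TerritoryMap) -> tuple[list, np.ndarray]:
    """Square neighbourhood-order matrix (NaN where disconnected)."""
    ids = tmap.nest_ids
    pos = {nid: i for i, nid in enumerate(ids)}
    mat = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(mat, 0.0)
    for a, lens in nx.all_pairs_shortest_path_length(tmap.adjacency):
        for b, k in lens.items():
            mat[pos[a], pos[b]] = k
    return ids, mat
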