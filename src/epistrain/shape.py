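"""Cell-shape and division metrics.

Shape is characterised by the second-moment tensor of a cell's junction
positions about their arithmetic-mean centroid:

    C = (1/n) sum_i R_i,      S = (1/n) sum_i (R_i - C) (R_i - C)^T

with the cell long axis the principal eigenvector of S and circularity the
eigenvalue ratio lambda_min / lambda_max (1 for a perfect circle).

Orientations relative to a hyper-contractile cluster are acute angles in
[0, 90] degrees between an axis (shape long axis, or anaphase daughter-nuclei
separation axis) and the line from the cell centroid to the nearest point on
the cluster's outer boundary.  Host cells are grouped by graph (ring)
distance to the cluster into the categories 1-3, 4-6 and 7+.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import shapely.ops as sops

from .errors import GeometryError, ValidationError
from .params import MechanicalParams
from .tissue import Tissue

CATEGORIES = ("1-3", "4-6", "7+")

EIGEN_GAP_TOL = 1e-6  # relative eigen-gap below which the long axis is undefined


# ------------------------------------------------------------------- polygons
@dataclass
class CellPolygon:
    """A traced apical cell polygon (anticlockwise, simple)."""

    vertices: np.ndarray
    cell_id: object = None
    sample_id: object = None
    is_cluster: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if len(v) < 3:
            raise GeometryError(f"cell {self.cell_id}: fewer than 3 vertices")
        shp = sgeom.Polygon(v)
        if not (shp.is_valid and shp.is_simple):
            raise GeometryError(
                f"cell {self.cell_id} (sample {self.sample_id}): "
                "polygon is not simple"
            )
        # normalise to anticlockwise (positive signed area)
        x, y = v[:, 0], v[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        self.vertices = v if signed > 0 else v[::-1]


@dataclass
class DivisionEvent:
    """An in-plane anaphase division: centroid, axis, timestamp."""

    time_min: float
    cell_centroid: np.ndarray
    daughter_axis: np.ndarray
    in_plane: bool = True

    def __post_init__(self):
        self.cell_centroid = np.asarray(self.cell_centroid, dtype=float)
        a = np.asarray(self.daughter_axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("daughter_axis must be non-zero")
        self.daughter_axis = a / n


# ------------------------------------------------------------- shape measures
def centroid(vertices: np.ndarray) -> np.ndarray:
    """Arithmetic mean of junction positions."""
    return np.asarray(vertices, dtype=float).mean(axis=0)


def shape_tensor(vertices: np.ndarray) -> np.ndarray:
    """Second-moment shape tensor S about the vertex-mean centroid."""
    v = np.asarray(vertices, dtype=float)
    d = v - v.mean(axis=0)
    return d.T @ d / len(v)


def principal_axis(S: np.ndarray, tol: float = EIGEN_GAP_TOL):
    """(angle in degrees in [0, 180), defined flag) of the long axis of S.

    The flag is False when the eigenvalue gap is below ``tol`` relative to
    the largest eigenvalue (near-isotropic cell, axis meaningless).
    """
    w, v = np.linalg.eigh(S)
    lmin, lmax = float(w[0]), float(w[1])
    if lmax <= 0 or (lmax - lmin) <= tol * lmax:
        return float("nan"), False
    vec = v[:, 1]
    angle = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
    return float(angle), True


def circularity(S: np.ndarray) -> float:
    """Eigenvalue ratio lambda_min / lambda_max of S, in (0, 1]."""
    w = np.linalg.eigvalsh(S)
    if w[1] <= 0:
        raise ValueError("circularity undefined for a zero shape tensor")
    return float(w[0] / w[1])


def acute_angle_between(axis_deg: float, reference_deg: float) -> float:
    """Acute angle in [0, 90] between two undirected axes given in degrees."""
    d = abs(axis_deg - reference_deg) % 180.0
    return min(d, 180.0 - d)


# ------------------------------------------------------- rings and orientation
def ring_distance(adjacency: nx.Graph, cluster_flags) -> np.ndarray:
    """Per-cell graph (BFS) distance to the nearest cluster cell.

    Cluster cells get ring 0.  Raises ``ValueError`` if no cell is flagged.
    """
    flags = np.asarray(cluster_flags, dtype=bool)
    sources = np.nonzero(flags)[0]
    if sources.size == 0:
        raise ValueError("ring_distance: no cluster cells flagged")
    g = adjacency.copy()
    virtual = "__cluster__"
    g.add_node(virtual)
    for s in sources:
        g.add_edge(virtual, int(s))
    lengths = nx.single_source_shortest_path_length(g, virtual)
    rings = np.full(adjacency.number_of_nodes(), -1, dtype=int)
    for node, dist in lengths.items():
        if node != virtual:
            rings[node] = dist - 1
    if np.any(rings < 0):
        raise ValueError("ring_distance: some cells unreachable from cluster")
    return rings


def ring_category(ring: int):
    """Distance category '1-3', '4-6' or '7+'; None for cluster cells."""
    if ring == 0:
        return None
    if ring <= 3:
        return CATEGORIES[0]
    if ring <= 6:
        return CATEGORIES[1]
    return CATEGORIES[2]


def cluster_boundary(cluster_polygons) -> sgeom.base.BaseGeometry:
    """Outer boundary of the union of the cluster cells' polygons."""
    union = sops.unary_union([sgeom.Polygon(p) for p in cluster_polygons])
    if union.is_empty:
        raise ValueError("cluster_boundary: empty cluster")
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    return sgeom.LineString(union.exterior.coords)


def reference_angle(
    point: np.ndarray,
    boundary: sgeom.base.BaseGeometry,
    fallback_point: np.ndarray = None,
) -> float:
    """Angle (degrees mod 180) of the line from ``point`` to the nearest
    cluster-boundary point; falls back to the direction toward
    ``fallback_point`` (e.g. the cluster centroid) when the nearest point is
    ambiguous (zero-length reference vector)."""
    p = sgeom.Point(point)
    nearest = sops.nearest_points(boundary, p)[0]
    ref = np.array([nearest.x, nearest.y]) - np.asarray(point, dtype=float)
    if np.linalg.norm(ref) < 1e-12:
        if fallback_point is None:
            raise GeometryError("degenerate reference direction to cluster")
        ref = np.asarray(fallback_point, dtype=float) - np.asarray(point, dtype=float)
        if np.linalg.norm(ref) < 1e-12:
            raise GeometryError("degenerate reference direction to cluster")
    return float(np.degrees(np.arctan2(ref[1], ref[0])) % 180.0)


def orientation_to_cluster(
    cell_centroid: np.ndarray,
    axis_angle_deg: float,
    boundary: sgeom.base.BaseGeometry,
    fallback_point: np.ndarray = None,
) -> float:
    """Acute angle in [0, 90] between a cell's long axis and the direction
    from its centroid to the nearest point on the cluster boundary
    (0 = pointing at the cluster)."""
    ref = reference_angle(cell_centroid, boundary, fallback_point)
    return acute_angle_between(axis_angle_deg, ref)


def division_orientation(
    event: DivisionEvent,
    boundary: sgeom.base.BaseGeometry,
    fallback_point: np.ndarray = None,
) -> float:
    """Acute angle in [0, 90] between the daughter-separation axis and the
    line from the dividing cell's centroid to the closest cluster edge."""
    if not event.in_plane:
        raise ValueError("division_orientation is defined for in-plane events only")
    axis_deg = float(
        np.degrees(np.arctan2(event.daughter_axis[1], event.daughter_axis[0])) % 180.0
    )
    ref = reference_angle(event.cell_centroid, boundary, fallback_point)
    return acute_angle_between(axis_deg, ref)


# ------------------------------------------------------------ division counts
def division_rate(n_divisions: int, n_cells: int, duration_min: float) -> float:
    """Cell division rate: percentage of cells dividing per minute."""
    if n_cells <= 0:
        raise ValueError("division_rate requires n_cells > 0")
    if duration_min <= 0:
        raise ValueError("division_rate requires duration_min > 0")
    return 100.0 * n_divisions / (n_cells * duration_min)


def rose_histogram(angles) -> np.ndarray:
    """Counts of angles in the nine 10-degree bins [0,10), ..., [80,90].

    90 degrees falls in the last bin.  Raises ``ValidationError`` naming any
    out-of-range value.
    """
    a = np.asarray(angles, dtype=float)
    if a.size:
        bad = a[(a < 0) | (a > 90)]
        if bad.size:
            raise ValidationError(f"angle {bad[0]} outside [0, 90]")
    counts, _ = np.histogram(a, bins=np.linspace(0.0, 90.0, 10))
    return counts


# -------------------------------------------------------- tissue measurements
def measure_tissue(
    tissue: Tissue,
    params: MechanicalParams = None,
    eigen_tol: float = EIGEN_GAP_TOL,
) -> pd.DataFrame:
    """Per-cell shape/stress summary table of a simulated tissue.

    Columns: cell_id, is_cluster, ring, ring_category, area, perimeter,
    circularity, principal_angle, orientation_defined, orientation_to_cluster
    and (when ``params`` given) peff.  Orientation is measured in a seam-free
    frame centred on the box center (where the cluster sits), using the
    nearest point on the cluster's outer boundary as the reference, with the
    cluster centroid as fallback.
    """
    if not tissue.cluster.any():
        raise ValueError("measure_tissue requires a flagged cluster")
    areas, perims = tissue.areas_perimeters()
    rings = ring_distance(tissue.adjacency_graph(), tissue.cluster)
    polys = [tissue.cell_polygon(i, anchor="center") for i in range(tissue.n_cells)]
    boundary = cluster_boundary([polys[i] for i in np.nonzero(tissue.cluster)[0]])
    cluster_centroid = np.vstack(
        [polys[i] for i in np.nonzero(tissue.cluster)[0]]
    ).mean(axis=0)

    rows = []
    for i in range(tissue.n_cells):
        S = shape_tensor(polys[i])
        ang, defined = principal_axis(S, tol=eigen_tol)
        orient = np.nan
        if defined and not tissue.cluster[i]:
            orient = orientation_to_cluster(
                centroid(polys[i]), ang, boundary, fallback_point=cluster_centroid
            )
        rows.append(
            {
                "cell_id": i,
                "is_cluster": bool(tissue.cluster[i]),
                "ring": int(rings[i]),
                "ring_category": ring_category(int(rings[i])),
                "area": float(areas[i]),
                "perimeter": float(perims[i]),
                "circularity": circularity(S),
                "principal_angle": ang,
                "orientation_defined": defined,
                "orientation_to_cluster": orient,
            }
        )
    df = pd.DataFrame(rows)
    if params is not None:
        from .mechanics import tissue_peff

        df["peff"] = tissue_peff(tissue, params)
    return df
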