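"""Traced-polygon tables: export from simulations, loading, and measurement.

The tracing dialect is one row per junction:

    embryo_id, cell_id, vertex_order, x, y, is_cluster

Junctions shared by neighbouring cells carry identical coordinates, which
is how cell adjacency is reconstructed on load.  Simulated tissues are
exported in a seam-free frame centred on the cluster; cells crossing the
periodic seam are dropped, emulating a bounded field of view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .shape import (
    CATEGORIES,
    EIGEN_GAP_TOL,
    CellPolygon,
    centroid,
    cluster_boundary,
    orientation_to_cluster,
    principal_axis,
    ring_category,
    shape_tensor,
)
from .tissue import Tissue, wrap_displacement

TRACING_COLUMNS = ["embryo_id", "cell_id", "vertex_order", "x", "y", "is_cluster"]


def tissue_to_tracing(
    tissue: Tissue,
    embryo_id,
    jitter_sigma: float = 0.0,
    rng: np.random.Generator = None,
) -> pd.DataFrame:
    """Export a simulated tissue as a tracing table.

    ``jitter_sigma`` adds isotropic Gaussian noise (as a fraction of the
    mean edge length) to each junction once, so neighbouring cells stay
    consistent — emulating manual tracing error.  Cells whose polygon would
    wrap around the periodic seam are excluded (bounded field of view).
    """
    center = tissue.box / 2.0
    g = center + wrap_displacement(tissue.vertices - center, tissue.box)
    if jitter_sigma > 0:
        if rng is None:
            raise ValueError("jitter requires an explicit rng")
        g = g + rng.normal(0.0, jitter_sigma * tissue.mean_edge_length(), g.shape)
    half = tissue.box / 2.0
    rows = []
    for ci, cyc in enumerate(tissue.cells):
        pts = g[cyc]
        d = np.diff(pts, axis=0, append=pts[:1])
        if np.any(np.abs(d) > half):  # crosses the seam; outside field of view
            continue
        for order, (v, (x, y)) in enumerate(zip(cyc, pts)):
            rows.append(
                {
                    "embryo_id": embryo_id,
                    "cell_id": int(ci),
                    "vertex_order": order,
                    "x": float(x),
                    "y": float(y),
                    "is_cluster": bool(tissue.cluster[ci]),
                }
            )
    return pd.DataFrame(rows, columns=TRACING_COLUMNS)


def polygons_from_tracing(df: pd.DataFrame, flip_y: bool = False):
    """Parse one embryo's tracing rows into validated CellPolygon objects."""
    polys = []
    for (embryo, cell), grp in df.groupby(["embryo_id", "cell_id"], sort=True):
        grp = grp.sort_values("vertex_order")
        v = grp[["x", "y"]].to_numpy(dtype=float)
        if flip_y:
            v = v * np.array([1.0, -1.0])
        flags = grp["is_cluster"].unique()
        if len(flags) != 1:
            raise ValidationError(
                f"embryo {embryo} cell {cell}: inconsistent is_cluster flag"
            )
        polys.append(
            CellPolygon(
                vertices=v,
                cell_id=cell,
                sample_id=embryo,
                is_cluster=bool(flags[0]),
            )
        )
    return polys


def _junction_key(xy: np.ndarray, decimals: int = 6):
    return (round(float(xy[0]), decimals), round(float(xy[1]), decimals))


def _adjacency_from_polygons(polys):
    """Cell-neighbour graph from shared junction coordinates (>= 2 shared)."""
    import networkx as nx

    junction_cells: dict = {}
    for idx, p in enumerate(polys):
        for v in p.vertices:
            junction_cells.setdefault(_junction_key(v), set()).add(idx)
    g = nx.Graph()
    g.add_nodes_from(range(len(polys)))
    shared: dict = {}
    for cells in junction_cells.values():
        cells = sorted(cells)
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                key = (cells[i], cells[j])
                shared[key] = shared.get(key, 0) + 1
    for (i, j), n in shared.items():
        if n >= 2:  # a shared wall, not just a touching corner
            g.add_edge(i, j)
    return g


def measure_tracing(
    df: pd.DataFrame,
    eigen_tol: float = EIGEN_GAP_TOL,
    flip_y: bool = False,
) -> pd.DataFrame:
    """Per-cell orientation table from a tracing dataset (all embryos).

    Columns: embryo_id, cell_id, is_cluster, ring, ring_category,
    circularity, principal_angle, orientation_defined,
    orientation_to_cluster.
    """
    from .shape import ring_distance

    out = []
    for embryo, grp in df.groupby("embryo_id", sort=True):
        polys = polygons_from_tracing(grp, flip_y=flip_y)
        flags = np.array([p.is_cluster for p in polys])
        if not flags.any():
            raise ValidationError(f"embryo {embryo}: no cluster cells flagged")
        graph = _adjacency_from_polygons(polys)
        rings = ring_distance(graph, flags)
        boundary = cluster_boundary(
            [p.vertices for p, f in zip(polys, flags) if f]
        )
        fallback = np.vstack(
            [p.vertices for p, f in zip(polys, flags) if f]
        ).mean(axis=0)
        for idx, p in enumerate(polys):
            S = shape_tensor(p.vertices)
            ang, defined = principal_axis(S, tol=eigen_tol)
            orient = np.nan
            if defined and not p.is_cluster:
                orient = orientation_to_cluster(
                    centroid(p.vertices), ang, boundary, fallback_point=fallback
                )
            w = np.linalg.eigvalsh(S)
            out.append(
                {
                    "embryo_id": embryo,
                    "cell_id": p.cell_id,
                    "is_cluster": p.is_cluster,
                    "ring": int(rings[idx]),
                    "ring_category": ring_category(int(rings[idx])),
                    "circularity": float(w[0] / w[1]),
                    "principal_angle": ang,
                    "orientation_defined": defined,
                    "orientation_to_cluster": orient,
                }
            )
    return pd.DataFrame(out)


def angles_by_category(measured: pd.DataFrame) -> dict:
    """Pool defined, non-cluster orientations into the three ring categories."""
    ok = measured[
        measured["orientation_defined"]
        & ~measured["is_cluster"]
        & measured["orientation_to_cluster"].notna()
    ]
    return {
        cat: ok.loc[ok["ring_category"] == cat, "orientation_to_cluster"]
        .to_numpy(dtype=float)
        for cat in CATEGORIES
    }
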