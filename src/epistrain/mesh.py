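"""Random periodic tissue generation.

A tissue is seeded as the Voronoi tessellation of uniform random points in
a periodic square box, smoothed with a fixed number of Lloyd relaxation
steps.  The box area equals the cell count so the mean cell area is 1,
matching the model's preferred area.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .errors import GeometryError
from .tissue import Tissue, wrap_displacement

_OFFSETS = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)


def _tiled_voronoi_regions(points: np.ndarray, box: np.ndarray):
    """Voronoi polygons of the central copy of 3x3-tiled periodic points."""
    n = len(points)
    tiles = np.vstack([points + off * box for off in _OFFSETS])
    # the (0, 0) tile is offset index 4 -> central points occupy [4n, 5n)
    vor = Voronoi(tiles)
    polys = []
    for i in range(4 * n, 5 * n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise GeometryError("unbounded Voronoi region in periodic tiling")
        poly = vor.vertices[region]
        # Voronoi cells are convex: sort vertices anticlockwise around the mean
        c = poly.mean(axis=0)
        order = np.argsort(np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0]))
        polys.append(poly[order])
    return polys


def _polygon_area_centroid(poly: np.ndarray):
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, np.array([cx, cy])


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mesh_from_polygons(polys, box: np.ndarray) -> Tissue:
    """Merge duplicated junction coordinates across tile copies into a mesh."""
    coords = np.vstack(polys)
    wrapped = np.mod(coords, box)
    # junction images across copies agree to ~1e-12 * box; merge within 1e-7
    merge_r = 1e-7 * float(box.min())
    tree = cKDTree(wrapped, boxsize=box)
    uf = _UnionFind(len(wrapped))
    for i, j in tree.query_pairs(merge_r):
        uf.union(i, j)
    root = np.array([uf.find(i) for i in range(len(wrapped))])
    uniq, inverse = np.unique(root, return_inverse=True)
    vertices = wrapped[uniq]
    cells = []
    pos = 0
    for poly in polys:
        k = len(poly)
        cyc = inverse[pos:pos + k].astype(np.int64)
        pos += k
        keep = np.concatenate([[True], cyc[1:] != cyc[:-1]])
        cyc = cyc[keep]
        if cyc[0] == cyc[-1]:
            cyc = cyc[:-1]
        cells.append(cyc)
    t = Tissue(vertices=vertices, cells=cells, box=box.copy())
    # ensure anticlockwise cycles
    areas, _ = t.areas_perimeters()
    flipped = False
    for i in np.nonzero(areas < 0)[0]:
        t.cells[i] = t.cells[i][::-1]
        flipped = True
    if flipped:
        t.invalidate_topology()
    return t


def generate_tissue(
    n_cells: int,
    seed: int,
    lloyd_steps: int = 4,
    box: np.ndarray = None,
) -> Tissue:
    """Generate a random periodic tissue mesh.

    Uniform random seed points in a square box of area ``n_cells`` are
    tessellated (periodic Voronoi) and smoothed with ``lloyd_steps`` Lloyd
    iterations.  Deterministic: the same ``(n_cells, seed)`` reproduces the
    identical mesh.

    Raises
    ------
    ValueError
        If ``n_cells < 16`` (a central cluster plus three surrounding rings
        cannot fit).
    """
    if n_cells < 16:
        raise ValueError(f"n_cells must be >= 16, got {n_cells}")
    if box is None:
        side = float(np.sqrt(n_cells))
        box = np.array([side, side])
    else:
        box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    points = rng.uniform(0.0, 1.0, size=(n_cells, 2)) * box
    for _ in range(lloyd_steps):
        polys = _tiled_voronoi_regions(points, box)
        cents = np.array([_polygon_area_centroid(p)[1] for p in polys])
        points = np.mod(cents, box)
    tissue = _mesh_from_polygons(_tiled_voronoi_regions(points, box), box)
    tissue.validate(strict_trivalent=False)
    return tissue


def nearest_cell_to_center(tissue: Tissue) -> int:
    """Index of the cell whose vertex-mean centroid is nearest the box center."""
    center = tissue.box / 2.0
    best, best_d = 0, np.inf
    for i in range(tissue.n_cells):
        poly = tissue.cell_polygon(i)
        d = np.linalg.norm(wrap_displacement(poly.mean(axis=0) - center, tissue.box))
        if d < best_d:
            best, best_d = i, d
    return best
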