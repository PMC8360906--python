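"""Periodic vertex-mesh container and geometry.

A :class:`Tissue` is a planar polygonal tiling of a periodic rectangle:
vertex positions, cells as anticlockwise vertex-index cycles, per-cell
contractility multipliers and cluster flags.  All geometry (areas,
perimeters, polygon coordinates) uses minimum-image unwrapping so cells
straddling the box boundary behave exactly like interior cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import GeometryError, TopologyError


def wrap_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) ``d`` in a periodic ``box``."""
    return d - box * np.round(d / box)


@dataclass
class Tissue:
    """Vertex mesh of an epithelium in a periodic box.

    Attributes
    ----------
    vertices:
        ``(n_vertices, 2)`` array of positions, stored wrapped into
        ``[0, Lx) x [0, Ly)``.
    cells:
        List of integer arrays; each is an anticlockwise cycle of vertex
        indices (>= 3 per cell).
    box:
        ``(Lx, Ly)`` of the periodic rectangle.
    gamma_multiplier:
        Per-cell factor on the contractility Gamma (1.0 = wild type).
    cluster:
        Per-cell boolean cluster flag.
    """

    vertices: np.ndarray
    cells: list
    box: np.ndarray
    gamma_multiplier: np.ndarray = None
    cluster: np.ndarray = None
    _he: dict = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.cells = [np.asarray(c, dtype=np.int64) for c in self.cells]
        n = len(self.cells)
        if self.gamma_multiplier is None:
            self.gamma_multiplier = np.ones(n)
        else:
            self.gamma_multiplier = np.asarray(self.gamma_multiplier, dtype=float)
        if self.cluster is None:
            self.cluster = np.zeros(n, dtype=bool)
        else:
            self.cluster = np.asarray(self.cluster, dtype=bool)

    # ------------------------------------------------------------------ basic
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "Tissue":
        return Tissue(
            vertices=self.vertices.copy(),
            cells=[c.copy() for c in self.cells],
            box=self.box.copy(),
            gamma_multiplier=self.gamma_multiplier.copy(),
            cluster=self.cluster.copy(),
        )

    def invalidate_topology(self) -> None:
        """Drop cached half-edge arrays after a topological edit."""
        self._he = None

    # -------------------------------------------------------------- half-edges
    def half_edges(self) -> dict:
        """Flattened half-edge arrays for vectorised geometry.

        Returns a dict with ``v_from``, ``v_to``, ``cell_of`` (one entry per
        directed cell edge), ``offsets`` (per-cell slice starts, length
        n_cells+1) and ``prev`` (index of the previous half-edge within the
        same cell cycle).
        """
        if self._he is None:
            counts = np.array([len(c) for c in self.cells])
            offsets = np.concatenate([[0], np.cumsum(counts)])
            v_from = np.concatenate(self.cells) if self.cells else np.empty(0, int)
            v_to = np.concatenate([np.roll(c, -1) for c in self.cells])
            cell_of = np.repeat(np.arange(len(self.cells)), counts)
            idx = np.arange(offsets[-1])
            prev = idx - 1
            prev[offsets[:-1]] = offsets[1:] - 1
            self._he = {
                "counts": counts,
                "offsets": offsets,
                "v_from": v_from,
                "v_to": v_to,
                "cell_of": cell_of,
                "prev": prev,
            }
        return self._he

    # ---------------------------------------------------------------- geometry
    def edge_vectors(self, positions: np.ndarray = None) -> np.ndarray:
        """Minimum-image vector of every half-edge."""
        he = self.half_edges()
        r = self.vertices if positions is None else positions
        return wrap_displacement(r[he["v_to"]] - r[he["v_from"]], self.box)

    def relative_coords(self, positions: np.ndarray = None) -> np.ndarray:
        """Unwrapped vertex coordinates relative to each cell's first vertex."""
        he = self.half_edges()
        e = self.edge_vectors(positions)
        cs = np.vstack([[0.0, 0.0], np.cumsum(e, axis=0)])[:-1]
        base = np.repeat(cs[he["offsets"][:-1]], he["counts"], axis=0)
        return cs - base

    def areas_perimeters(self, positions: np.ndarray = None):
        """Signed areas and perimeters of all cells (periodic unwrapping)."""
        he = self.half_edges()
        e = self.edge_vectors(positions)
        p = self.relative_coords(positions)
        starts = he["offsets"][:-1]
        cross = p[:, 0] * e[:, 1] - p[:, 1] * e[:, 0]
        areas = 0.5 * np.add.reduceat(cross, starts)
        lengths = np.linalg.norm(e, axis=1)
        perims = np.add.reduceat(lengths, starts)
        return areas, perims

    def cell_polygon(self, cell_index: int, anchor: str = "first") -> np.ndarray:
        """Unwrapped absolute coordinates of one cell's polygon.

        ``anchor='first'`` places the polygon at the stored position of its
        first vertex; ``anchor='center'`` translates it so its vertex-mean
        centroid sits at the minimum-image position relative to the box
        center (useful when assembling a seam-free global picture).
        """
        cyc = self.cells[cell_index]
        r0 = self.vertices[cyc[0]]
        edges = wrap_displacement(
            np.diff(self.vertices[cyc], axis=0, append=self.vertices[cyc][:1]),
            self.box,
        )
        steps = np.vstack([[0.0, 0.0], np.cumsum(edges, axis=0)])[:-1]
        poly = r0 + steps
        if anchor == "center":
            c = self.box / 2.0
            mean = poly.mean(axis=0)
            poly = poly + (c + wrap_displacement(mean - c, self.box)) - mean
        return poly

    def mean_edge_length(self) -> float:
        e = self.edge_vectors()
        return float(np.linalg.norm(e, axis=1).mean())

    # ---------------------------------------------------------------- topology
    def edge_cells(self) -> dict:
        """Map undirected vertex pair -> list of (cell, position of v_from)."""
        he = self.half_edges()
        table: dict = {}
        for k in range(len(he["v_from"])):
            a, b = int(he["v_from"][k]), int(he["v_to"][k])
            table.setdefault((min(a, b), max(a, b)), []).append((int(he["cell_of"][k]), a))
        return table

    def vertex_cells(self) -> dict:
        """Map vertex index -> sorted list of incident cells."""
        he = self.half_edges()
        out: dict = {}
        for v, c in zip(he["v_from"], he["cell_of"]):
            out.setdefault(int(v), set()).add(int(c))
        return {v: sorted(cs) for v, cs in out.items()}

    def adjacency_graph(self) -> nx.Graph:
        """Cell-neighbour graph; nodes are cell indices, edges shared walls."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        for pair, incident in self.edge_cells().items():
            cells = {c for c, _ in incident}
            if len(cells) == 2:
                g.add_edge(*sorted(cells))
        return g

    # -------------------------------------------------------------- validation
    def validate(self, strict_trivalent: bool = True) -> None:
        """Raise if a structural or geometric invariant is violated."""
        for i, c in enumerate(self.cells):
            if len(c) < 3:
                raise TopologyError(f"cell {i} has fewer than 3 vertices")
            if len(set(c.tolist())) != len(c):
                raise TopologyError(f"cell {i} repeats a vertex")
        areas, _ = self.areas_perimeters()
        bad = np.nonzero(areas <= 0)[0]
        if bad.size:
            raise GeometryError(f"non-positive area in cells {bad.tolist()}")
        for pair, incident in self.edge_cells().items():
            if len(incident) != 2:
                raise TopologyError(f"edge {pair} belongs to {len(incident)} cells")
            (c1, a1), (c2, a2) = incident
            if a1 == a2:
                raise TopologyError(f"edge {pair} traversed twice in same direction")
        if strict_trivalent:
            for v, cs in self.vertex_cells().items():
                if len(cs) != 3:
                    raise TopologyError(
                        f"vertex {v} belongs to {len(cs)} cells (expected 3)"
                    )

    # --------------------------------------------------------------------- I/O
    def to_json(self, path) -> None:
        """Write the mesh as JSON (round-trips bit-exactly)."""
        payload = {
            "box": self.box.tolist(),
            "vertices": self.vertices.tolist(),
            "cells": [c.tolist() for c in self.cells],
            "gamma_multiplier": self.gamma_multiplier.tolist(),
            "cluster": self.cluster.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Tissue":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            vertices=np.array(payload["vertices"], dtype=float),
            cells=[np.array(c, dtype=np.int64) for c in payload["cells"]],
            box=np.array(payload["box"], dtype=float),
            gamma_multiplier=np.array(payload["gamma_multiplier"], dtype=float),
            cluster=np.array(payload["cluster"], dtype=bool),
        )


def cell_geometry(tissue: Tissue, cell_index: int):
    """(area, perimeter) of one cell with periodic unwrapping.

    Independent of which vertex starts the cycle.  Raises
    :class:`GeometryError` naming the cell if its polygon self-intersects.
    """
    poly = tissue.cell_polygon(cell_index)
    import shapely.geometry as sgeom

    shp = sgeom.Polygon(poly)
    if not shp.is_simple or not shp.is_valid:
        raise GeometryError(f"cell {cell_index} polygon is self-intersecting")
    areas, perims = tissue.areas_perimeters()
    a, p = float(areas[cell_index]), float(perims[cell_index])
    if a <= 0:
        raise GeometryError(f"cell {cell_index} has non-positive area {a}")
    return a, p
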