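"""Vertex-model mechanics: energy, forces, relaxation and perturbation.

Each cell carries the dimensionless energy

    U = (A - 1)^2 + (G/2) * (L + Lambda / (2 G))^2,   G = m * Gamma,

where ``m`` is the cell's contractility multiplier (1 for wild type,
``1 + cluster_increment`` inside the cluster).  Mechanical equilibrium is
found by minimising the total energy summed over cells with respect to the
vertex positions, using the analytic gradient.  Edges that collapse below a
threshold length undergo T1 neighbour exchanges, after which relaxation
continues.

The cell-level isotropic stress is

    Peff = A - 1 + G L^2 / (2 A) - Lambda L / (4 A),

positive under net tension and negative under net compression.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, TopologyError
from .mesh import generate_tissue, nearest_cell_to_center
from .params import MechanicalParams
from .tissue import Tissue, wrap_displacement

__all__ = [
    "cell_energy",
    "peff",
    "tissue_peff",
    "total_energy",
    "energy_and_forces",
    "relax",
    "t1_swap",
    "zero_net_stress",
    "apply_cluster",
    "mean_peff",
    "simulate_cluster_tissue",
]


# --------------------------------------------------------------- scalar forms
def cell_energy(area, perimeter, params: MechanicalParams, gamma_multiplier=1.0):
    """Single-cell energy U(A, L); Gamma is scaled by ``gamma_multiplier``."""
    g = gamma_multiplier * params.gamma_ref
    return (area - 1.0) ** 2 + 0.5 * g * (
        perimeter + params.lambda_coeff / (2.0 * g)
    ) ** 2


def peff(area, perimeter, params: MechanicalParams, gamma_multiplier=1.0):
    """Isotropic cell stress Peff(A, L); positive = net tension."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("peff requires area > 0")
    g = gamma_multiplier * params.gamma_ref
    val = (
        area
        - 1.0
        + g * perimeter**2 / (2.0 * area)
        - params.lambda_coeff * perimeter / (4.0 * area)
    )
    return float(val) if val.ndim == 0 else val


# ------------------------------------------------------------ vectorised core
def _cell_gammas(tissue: Tissue, params: MechanicalParams) -> np.ndarray:
    return params.gamma_ref * tissue.gamma_multiplier


def energy_and_forces(
    tissue: Tissue, params: MechanicalParams, positions: np.ndarray = None
):
    """Total energy and its gradient with respect to vertex positions.

    Returns ``(E, grad)`` with ``grad`` of shape ``(n_vertices, 2)``.  The
    force on vertex i is ``-grad[i]``.
    """
    he = tissue.half_edges()
    e = tissue.edge_vectors(positions)
    areas, perims = tissue.areas_perimeters(positions)
    g = _cell_gammas(tissue, params)
    lam = params.lambda_coeff
    energy = float(
        np.sum((areas - 1.0) ** 2 + 0.5 * g * (perims + lam / (2.0 * g)) ** 2)
    )

    coef_a = 2.0 * (areas - 1.0)
    coef_l = g * perims + 0.5 * lam
    ca = coef_a[he["cell_of"]]
    cl = coef_l[he["cell_of"]]

    norms = np.linalg.norm(e, axis=1)
    unit = e / np.maximum(norms, 1e-300)[:, None]
    e_prev = e[he["prev"]]
    unit_prev = unit[he["prev"]]

    # dA/dr_v = 0.5 * (e_prev + e) rotated by -90 deg; dL/dr_v = u_prev - u
    s = e_prev + e
    grad_he = np.empty_like(e)
    grad_he[:, 0] = ca * (0.5 * s[:, 1]) + cl * (unit_prev[:, 0] - unit[:, 0])
    grad_he[:, 1] = ca * (-0.5 * s[:, 0]) + cl * (unit_prev[:, 1] - unit[:, 1])

    r = tissue.vertices if positions is None else positions
    grad = np.zeros_like(r)
    np.add.at(grad, he["v_from"], grad_he)
    return energy, grad


def total_energy(
    tissue: Tissue, params: MechanicalParams, positions: np.ndarray = None
) -> float:
    """Total mechanical energy summed over all cells."""
    areas, perims = tissue.areas_perimeters(positions)
    g = _cell_gammas(tissue, params)
    lam = params.lambda_coeff
    return float(
        np.sum((areas - 1.0) ** 2 + 0.5 * g * (perims + lam / (2.0 * g)) ** 2)
    )


def tissue_peff(tissue: Tissue, params: MechanicalParams) -> np.ndarray:
    """Per-cell isotropic stress Peff."""
    areas, perims = tissue.areas_perimeters()
    g = _cell_gammas(tissue, params)
    return (
        areas
        - 1.0
        + g * perims**2 / (2.0 * areas)
        - params.lambda_coeff * perims / (4.0 * areas)
    )


def mean_peff(tissue: Tissue, params: MechanicalParams) -> float:
    """Cell-area-weighted mean Peff of the tissue."""
    areas, _ = tissue.areas_perimeters()
    p = tissue_peff(tissue, params)
    return float(np.sum(areas * p) / np.sum(areas))


# ------------------------------------------------------------------- T1 moves
def t1_swap(tissue: Tissue, v_a: int, v_b: int, new_length: float) -> None:
    """Neighbour exchange on edge (v_a, v_b), modifying the tissue in place.

    The edge collapses to its midpoint and reopens perpendicular with length
    ``new_length``; the two cells sharing the edge separate and the two cells
    meeting it only at an endpoint become neighbours.

    Raises :class:`TopologyError` when the move is not applicable (boundary
    configuration, triangle cell, or shared third cell).
    """
    cells = tissue.cells
    p_idx = q_idx = None
    for ci, cyc in enumerate(cells):
        lst = cyc.tolist()
        if v_a in lst and v_b in lst:
            ia = lst.index(v_a)
            if lst[(ia + 1) % len(lst)] == v_b:
                p_idx = ci
            elif lst[ia - 1] == v_b:
                q_idx = ci
    if p_idx is None or q_idx is None:
        raise TopologyError(f"edge ({v_a},{v_b}) is not interior")
    r_idx = s_idx = None
    for ci, cyc in enumerate(cells):
        if ci in (p_idx, q_idx):
            continue
        has_a = v_a in cyc
        has_b = v_b in cyc
        if has_a and has_b:
            raise TopologyError("third cell contains both edge endpoints")
        if has_a:
            r_idx = ci
        if has_b:
            s_idx = ci
    if r_idx is None or s_idx is None or r_idx == s_idx:
        raise TopologyError(f"edge ({v_a},{v_b}) has no valid T1 configuration")
    if len(cells[p_idx]) <= 3 or len(cells[q_idx]) <= 3:
        raise TopologyError("T1 would reduce a triangle below 3 vertices")

    def _remove(cyc, v):
        return cyc[cyc != v]

    def _insert_before(cyc, anchor, v):
        i = int(np.nonzero(cyc == anchor)[0][0])
        return np.insert(cyc, i, v)

    # reposition: midpoint +- half the new edge, perpendicular to the old edge
    ra, rb = tissue.vertices[v_a], tissue.vertices[v_b]
    u = wrap_displacement(rb - ra, tissue.box)
    u = u / np.linalg.norm(u)
    m = ra + 0.5 * wrap_displacement(rb - ra, tissue.box)
    n = np.array([-u[1], u[0]])  # points into cell P (left of a->b)
    tissue.vertices[v_a] = np.mod(m + 0.5 * new_length * n, tissue.box)
    tissue.vertices[v_b] = np.mod(m - 0.5 * new_length * n, tissue.box)

    cells[p_idx] = _remove(cells[p_idx], v_b)
    cells[q_idx] = _remove(cells[q_idx], v_a)
    cells[r_idx] = _insert_before(cells[r_idx], v_a, v_b)
    cells[s_idx] = _insert_before(cells[s_idx], v_b, v_a)
    tissue.invalidate_topology()


def t2_collapse(tissue: Tissue, cell_index: int) -> None:
    """Collapse a degenerate triangle cell to a single vertex, in place.

    At these parameters a triangle's energy decreases monotonically as it
    shrinks, so triangles produced by T1 cascades can collapse to a point
    where no further T1 applies; the T2 move removes the cell and merges
    its three vertices, restoring a well-posed (trivalent) mesh.  This is
    numerical mesh maintenance, not a model of extrusion.
    """
    cyc = tissue.cells[cell_index]
    if len(cyc) != 3:
        raise TopologyError("t2_collapse applies to triangle cells only")
    poly = tissue.cell_polygon(cell_index)
    keep = int(cyc[0])
    drop = set(int(v) for v in cyc[1:])
    tissue.vertices[keep] = np.mod(poly.mean(axis=0), tissue.box)
    new_cells = []
    for ci, c in enumerate(tissue.cells):
        if ci == cell_index:
            continue
        c = np.array([keep if int(v) in drop else int(v) for v in c], dtype=np.int64)
        dedup = [c[0]]
        for v in c[1:]:
            if v != dedup[-1]:
                dedup.append(v)
        while len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            raise TopologyError("T2 collapse would degenerate a neighbour cell")
        new_cells.append(np.array(dedup, dtype=np.int64))
    # compact vertex indices (drop orphans)
    used = np.unique(np.concatenate(new_cells))
    remap = -np.ones(tissue.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    tissue.vertices = tissue.vertices[used]
    tissue.cells = [remap[c] for c in new_cells]
    mask = np.ones(len(tissue.gamma_multiplier), dtype=bool)
    mask[cell_index] = False
    tissue.gamma_multiplier = tissue.gamma_multiplier[mask]
    tissue.cluster = tissue.cluster[mask]
    tissue.invalidate_topology()


def _collapsed_triangles(tissue: Tissue, threshold: float):
    """Triangle cells whose perimeter has fallen below ``3 * threshold``."""
    _, perims = tissue.areas_perimeters()
    return [
        i
        for i, c in enumerate(tissue.cells)
        if len(c) == 3 and perims[i] < 3.0 * threshold
    ]


def _short_edges(tissue: Tissue, threshold: float):
    """Undirected edges shorter than ``threshold``, shortest first."""
    he = tissue.half_edges()
    e = tissue.edge_vectors()
    norms = np.linalg.norm(e, axis=1)
    seen = {}
    for k in np.argsort(norms):
        if norms[k] >= threshold:
            break
        a, b = int(he["v_from"][k]), int(he["v_to"][k])
        key = (min(a, b), max(a, b))
        if key not in seen:
            seen[key] = (a, b, float(norms[k]))
    return list(seen.values())


# ----------------------------------------------------------------- relaxation
def relax(
    tissue: Tissue,
    params: MechanicalParams,
    tol: float = 1e-6,
    max_evals: int = 100_000,
    t1_enabled: bool = True,
    t1_threshold: float = 0.05,
    max_t1_rounds: int = 50,
    energy_trace: list = None,
) -> Tissue:
    """Minimise the total energy to mechanical equilibrium.

    Quasi-Newton (L-BFGS-B) descent with the analytic gradient until the
    largest per-vertex gradient norm is <= ``tol``.  When ``t1_enabled``,
    edges shorter than ``t1_threshold`` times the mean edge length are
    swapped (T1) and relaxation continues.  ``energy_trace``, if given, is
    filled with the accepted energies of each descent segment (a list per
    segment; monotone non-increasing within a segment).

    Raises :class:`ConvergenceError` (carrying the best-so-far tissue) if
    the tolerance is not met within ``max_evals`` evaluations.
    """
    t = tissue.copy()

    def objective(x):
        pos = x.reshape(-1, 2)
        e, g = energy_and_forces(t, params, pos)
        return e, g.ravel()

    for _ in range(max_t1_rounds + 1):
        trace: list = []

        def cb(x, _trace=trace):
            _trace.append(total_energy(t, params, x.reshape(-1, 2)))

        # restart L-BFGS (resetting its memory) if it stalls short of tol
        gnorm = np.inf
        for _restart in range(5):
            x0 = t.vertices.ravel()
            res = minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                callback=cb if energy_trace is not None else None,
                options={
                    "maxfun": max_evals,
                    "maxiter": max_evals,
                    "ftol": 1e-16,
                    "gtol": 0.05 * tol,
                },
            )
            t.vertices = np.mod(res.x.reshape(-1, 2), t.box)
            _, grad = energy_and_forces(t, params)
            gnorm = float(np.linalg.norm(grad, axis=1).max())
            if gnorm <= tol:
                break
        if energy_trace is not None:
            energy_trace.append(trace)
        converged = gnorm <= tol
        if converged and not t1_enabled:
            return t
        swapped = False
        if t1_enabled:
            thr = t1_threshold * t.mean_edge_length()
            # a stalled descent usually means an edge is collapsing (the
            # perimeter gradient is non-smooth at zero edge length): allow a
            # T1 on the shortest edge even if it is above the usual threshold
            limit = thr if converged else 3.0 * thr
            for tri in _collapsed_triangles(t, limit):
                try:
                    t2_collapse(t, tri)
                    swapped = True
                    break
                except TopologyError:
                    continue
            for a, b, _ in [] if swapped else _short_edges(t, limit):
                try:
                    t1_swap(t, a, b, 1.5 * thr)
                    swapped = True
                    break  # re-relax after each topological change
                except TopologyError:
                    continue
        if not swapped:
            if converged:
                return t
            raise ConvergenceError(
                f"relaxation stalled at per-vertex gradient norm {gnorm:.3e} "
                f"(tol {tol:.1e})",
                state=t,
            )
    raise ConvergenceError("T1 cascade did not settle", state=t)


# ----------------------------------------------------- zero-net-stress tissue
def _rescaled(tissue: Tissue, factor: float) -> Tissue:
    t = tissue.copy()
    t.vertices = t.vertices * factor
    t.box = t.box * factor
    return t


def hexagonal_zero_stress_area(params: MechanicalParams) -> float:
    """Cell area at which a regular hexagon has zero isotropic stress.

    A regular hexagon of area A has perimeter L = 6 sqrt(2A / (3 sqrt(3)));
    solving Peff(A, L(A)) = 0 gives a sharp analytic estimate of the
    zero-net-stress mean cell area of a disordered tissue, used to centre
    the box-scale bisection bracket.
    """
    from scipy.optimize import brentq

    def perim(a):
        return 6.0 * np.sqrt(2.0 * a / (3.0 * np.sqrt(3.0)))

    def f(a):
        return peff(a, perim(a), params)

    return float(brentq(f, 1e-4, 25.0))


def zero_net_stress(
    tissue: Tissue,
    params: MechanicalParams,
    tol: float = 1e-4,
    bracket=(0.8, 1.2),
    relax_tol: float = 1e-6,
    max_bisect: int = 60,
) -> Tissue:
    """Rescale the periodic box until the area-weighted mean Peff is ~zero.

    Bisection on an isotropic box scale factor, re-relaxing at every
    evaluation and warm-starting from the nearest previously relaxed state.
    The ``bracket`` of scale factors is taken relative to the analytic
    hexagonal zero-stress estimate (see
    :func:`hexagonal_zero_stress_area`), so the search succeeds regardless
    of the mean cell area the mesh was generated at.

    Raises ``ValueError`` with the end-point stresses if the bracket does
    not straddle zero.
    """
    base = relax(tissue, params, tol=relax_tol)
    mean_area = float(np.prod(base.box)) / base.n_cells
    s0 = np.sqrt(hexagonal_zero_stress_area(params) / mean_area)
    bracket = (bracket[0] * s0, bracket[1] * s0)
    evaluated = [(1.0, base)]

    def f(scale):
        s0, t0 = min(evaluated, key=lambda st: abs(st[0] - scale))
        guess = _rescaled(t0, scale / s0)
        relaxed = relax(guess, params, tol=relax_tol)
        evaluated.append((scale, relaxed))
        return mean_peff(relaxed, params), relaxed

    lo, hi = bracket
    f_lo, t_lo = f(lo)
    if abs(f_lo) <= tol:
        return t_lo
    f_hi, t_hi = f(hi)
    if abs(f_hi) <= tol:
        return t_hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"no zero crossing of mean Peff in scale bracket {bracket}: "
            f"Peff({lo})={f_lo:.4g}, Peff({hi})={f_hi:.4g}"
        )
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        f_mid, t_mid = f(mid)
        if abs(f_mid) <= tol:
            return t_mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    raise ConvergenceError(
        f"zero-net-stress bisection did not reach |mean Peff| <= {tol}",
        state=t_mid,
    )


# ------------------------------------------------------------------- clusters
def apply_cluster(
    tissue: Tissue,
    params: MechanicalParams,
    target_size: int = 19,
    relax_tol: float = 1e-6,
) -> Tissue:
    """Flag a central cluster and raise its contractility, then re-relax.

    The cluster is the cell nearest the box center plus successive
    adjacency rings until at least ``target_size`` cells are flagged.
    Flagged cells receive ``gamma_multiplier = 1 + params.cluster_increment``.
    """
    if target_size >= tissue.n_cells / 4:
        raise ValueError(
            f"cluster of {target_size} cells too large for {tissue.n_cells}-cell tissue"
        )
    t = tissue.copy()
    seed_cell = nearest_cell_to_center(t)
    graph = t.adjacency_graph()
    flagged = {seed_cell}
    frontier = {seed_cell}
    while len(flagged) < target_size:
        frontier = {
            nb for c in frontier for nb in graph.neighbors(c)
        } - flagged
        if not frontier:
            raise TopologyError("cluster growth exhausted the tissue")
        flagged |= frontier
    t.cluster = np.zeros(t.n_cells, dtype=bool)
    t.cluster[sorted(flagged)] = True
    t.gamma_multiplier = np.ones(t.n_cells)
    t.gamma_multiplier[t.cluster] = 1.0 + params.cluster_increment
    return relax(t, params, tol=relax_tol)


def simulate_cluster_tissue(
    n_cells: int,
    seed: int,
    params: MechanicalParams,
    cluster_size: int = 19,
    relax_tol: float = 1e-6,
    zero_stress_tol: float = 1e-4,
    base_tissue: Tissue = None,
) -> Tissue:
    """Full quasi-static pipeline: generate, relax, zero net stress, cluster.

    ``base_tissue`` may supply a pre-computed zero-net-stress tissue (e.g.
    when sweeping the cluster increment over the same mesh), skipping the
    generation and initialisation stages.
    """
    if base_tissue is None:
        base_tissue = zero_stress_base(n_cells, seed, params, relax_tol, zero_stress_tol)
    return apply_cluster(base_tissue, params, target_size=cluster_size, relax_tol=relax_tol)


def zero_stress_base(
    n_cells: int,
    seed: int,
    params: MechanicalParams,
    relax_tol: float = 1e-6,
    zero_stress_tol: float = 1e-4,
) -> Tissue:
    """Generate and relax a tissue, then bring it to zero net stress."""
    t = generate_tissue(n_cells, seed)
    return zero_net_stress(
        t, params, tol=zero_stress_tol, relax_tol=relax_tol
    )
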