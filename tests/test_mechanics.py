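"""Vertex-model energy, forces, relaxation and perturbations."""

import numpy as np
import pytest

from epistrain import (
    MechanicalParams,
    apply_cluster,
    cell_energy,
    energy_and_forces,
    generate_tissue,
    mean_peff,
    peff,
    relax,
    total_energy,
    zero_net_stress,
)
from epistrain.mechanics import _rescaled, t2_collapse
from epistrain.tissue import Tissue

LAMBDA, GAMMA = 0.259, 0.172


def test_single_cell_energy_closed_forms(params):
    # U(A=1, L=0) = Lambda^2 / (8 Gamma)
    assert cell_energy(1.0, 0.0, params) == pytest.approx(
        LAMBDA**2 / (8 * GAMMA), rel=1e-12
    )
    # U = 0 iff A = 1 and L = L0
    assert cell_energy(1.0, params.preferred_perimeter, params) == pytest.approx(0.0)
    assert cell_energy(2.0, 0.0, params) == pytest.approx(
        1.0 + LAMBDA**2 / (8 * GAMMA), rel=1e-12
    )


def test_energy_nonnegative_random_inputs(params, rng):
    a = rng.uniform(0.1, 3.0, 100)
    length = rng.uniform(0.0, 6.0, 100)
    assert np.all(cell_energy(a, length, params) >= 0)


def test_peff_closed_forms(params):
    # Gamma L^2 / 2 = Lambda L / 4 exactly at L = Lambda / (2 Gamma)
    assert peff(1.0, LAMBDA / (2 * GAMMA), params) == pytest.approx(0.0, abs=1e-15)
    assert peff(1.0, 0.0, params) == 0.0
    assert peff(2.0, 0.0, params) == 1.0  # net tension
    with pytest.raises(ValueError):
        peff(-1.0, 1.0, params)


def test_total_energy_additive_and_translation_invariant(relaxed_tissue, params):
    t = relaxed_tissue
    areas, perims = t.areas_perimeters()
    per_cell = sum(
        cell_energy(a, p_, params, m)
        for a, p_, m in zip(areas, perims, t.gamma_multiplier)
    )
    assert total_energy(t, params) == pytest.approx(per_cell, rel=1e-12)
    shifted = np.mod(t.vertices + np.array([0.3, 0.7]), t.box)
    assert total_energy(t, params, shifted) == pytest.approx(
        total_energy(t, params), rel=1e-9
    )


@pytest.mark.parametrize("relaxed", [False, True])
def test_forces_match_finite_differences(small_tissue, params, rng, relaxed):
    t = relax(small_tissue, params) if relaxed else small_tissue
    _, grad = energy_and_forces(t, params)
    h = 1e-6
    for _ in range(10):
        vi = rng.integers(t.n_vertices)
        d = rng.integers(2)
        pos = t.vertices.copy()
        pos[vi, d] += h
        e_plus = total_energy(t, params, pos)
        pos[vi, d] -= 2 * h
        e_minus = total_energy(t, params, pos)
        fd = (e_plus - e_minus) / (2 * h)
        assert abs(fd - grad[vi, d]) < 1e-6


def test_relax_is_fixed_point_and_descends(relaxed_tissue, params, rng):
    again = relax(relaxed_tissue, params)
    assert total_energy(again, params) == pytest.approx(
        total_energy(relaxed_tissue, params), abs=1e-10
    )
    # perturb, re-relax: returns to the minimum, energies monotone per segment
    e_min = total_energy(relaxed_tissue, params)
    noisy = relaxed_tissue.copy()
    noisy.vertices = np.mod(
        noisy.vertices + rng.normal(0, 0.005, noisy.vertices.shape), noisy.box
    )
    trace = []
    back = relax(noisy, params, energy_trace=trace)
    assert total_energy(back, params) <= e_min + 1e-6
    for segment in trace:
        diffs = np.diff(segment)
        assert np.all(diffs <= 1e-10)


def test_zero_net_stress_residual_and_sign(zero_stress_tissue, params):
    assert abs(mean_peff(zero_stress_tissue, params)) <= 1e-4
    shrunk = relax(_rescaled(zero_stress_tissue, 0.97), params)
    grown = relax(_rescaled(zero_stress_tissue, 1.03), params)
    assert mean_peff(shrunk, params) < 0  # compression
    assert mean_peff(grown, params) > 0  # tension


def test_apply_cluster_flags_connected_patch(zero_stress_tissue, params):
    c = apply_cluster(zero_stress_tissue, params.with_increment(0.3), target_size=7)
    assert c.cluster.sum() >= 7
    assert np.all(c.gamma_multiplier[c.cluster] == pytest.approx(1.3))
    assert np.all(c.gamma_multiplier[~c.cluster] == 1.0)
    sub = c.adjacency_graph().subgraph(np.nonzero(c.cluster)[0].tolist())
    import networkx as nx

    assert nx.is_connected(sub)


def test_apply_cluster_zero_increment_is_noop(zero_stress_tissue, params):
    c = apply_cluster(zero_stress_tissue, params.with_increment(0.0), target_size=7)
    assert abs(mean_peff(c, params)) <= 1e-3
    assert total_energy(c, params) == pytest.approx(
        total_energy(zero_stress_tissue, params), rel=1e-8
    )


def test_cluster_too_large_rejected(zero_stress_tissue, params):
    with pytest.raises(ValueError):
        apply_cluster(zero_stress_tissue, params, target_size=40)


def test_t1_then_t2_keep_mesh_valid():
    """A T1 on a quad's edge makes it a triangle; T2 then removes it."""
    from epistrain.errors import TopologyError
    from epistrain.mechanics import t1_swap

    t = generate_tissue(64, seed=0)  # this mesh contains quad cells
    t.validate()
    tri = None
    for ci, cyc in enumerate(t.cells):
        if len(cyc) != 4:
            continue
        for k in range(4):
            a, b = int(cyc[k]), int(cyc[(k + 1) % 4])
            try:
                t1_swap(t, a, b, 0.5 * 0.05 * t.mean_edge_length())
            except TopologyError:
                continue
            tri = ci
            break
        if tri is not None:
            break
    assert tri is not None and len(t.cells[tri]) == 3
    t.validate()  # still trivalent with paired edges
    n0 = t.n_cells
    t2_collapse(t, tri)
    assert t.n_cells == n0 - 1
    t.validate(strict_trivalent=False)
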