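"""Cell-shape tensor, orientation, ring-distance and division metrics."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistrain import (
    DivisionEvent,
    centroid,
    circularity,
    division_orientation,
    division_rate,
    principal_axis,
    ring_distance,
    rose_histogram,
    shape_tensor,
)
from epistrain.errors import ValidationError
from epistrain.shape import acute_angle_between, cluster_boundary, ring_category

SQUARE = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
RECT = np.array([[-1.0, -0.5], [1.0, -0.5], [1.0, 0.5], [-1.0, 0.5]])


def _rot(deg):
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def test_centroid_examples_and_translation_equivariance(rng):
    assert centroid(SQUARE) == pytest.approx([0.0, 0.0])
    tri = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    assert centroid(tri) == pytest.approx([1.0, 1.0])
    shift = rng.normal(size=2)
    assert centroid(RECT + shift) == pytest.approx(centroid(RECT) + shift)
    # cyclic relabeling
    assert centroid(np.roll(RECT, 2, axis=0)) == pytest.approx(centroid(RECT))


def test_shape_tensor_hand_values():
    assert shape_tensor(SQUARE) == pytest.approx(0.25 * np.eye(2))
    assert shape_tensor(RECT) == pytest.approx(np.array([[1.0, 0.0], [0.0, 0.25]]))
    hexagon = np.stack(
        [np.cos(np.radians(np.arange(0, 360, 60))),
         np.sin(np.radians(np.arange(0, 360, 60)))], axis=1
    )
    assert shape_tensor(hexagon) == pytest.approx(0.5 * np.eye(2))


@given(st.floats(-180, 180), st.floats(0.1, 10.0))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_shape_tensor_rotation_equivariant_and_scale_quadratic(angle, scale):
    R = _rot(angle)
    S0 = shape_tensor(RECT)
    assert shape_tensor(RECT @ R.T) == pytest.approx(R @ S0 @ R.T, abs=1e-9)
    assert shape_tensor(RECT * scale) == pytest.approx(S0 * scale**2, rel=1e-9)
    assert circularity(shape_tensor(RECT * scale)) == pytest.approx(
        circularity(S0), rel=1e-9
    )


def test_principal_axis_and_circularity():
    ang, defined = principal_axis(shape_tensor(RECT))
    assert defined and ang == pytest.approx(0.0, abs=1e-9)
    _, defined_sq = principal_axis(shape_tensor(SQUARE))
    assert not defined_sq  # isotropic
    ang30, defined30 = principal_axis(shape_tensor(RECT @ _rot(30).T))
    assert defined30 and ang30 == pytest.approx(30.0, abs=1e-6)
    assert circularity(shape_tensor(SQUARE)) == pytest.approx(1.0)
    assert circularity(shape_tensor(RECT)) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        circularity(np.zeros((2, 2)))


def test_angle_folding():
    assert acute_angle_between(30.0, 0.0) == pytest.approx(30.0)
    assert acute_angle_between(150.0, 0.0) == pytest.approx(30.0)
    assert acute_angle_between(0.0, 0.0) == 0.0
    assert acute_angle_between(90.0, 0.0) == 90.0


def test_ring_distance_matches_shortest_path_oracle(rng):
    g = nx.random_geometric_graph(30, 0.35, seed=4)
    while not nx.is_connected(g):  # pragma: no cover
        g = nx.random_geometric_graph(30, 0.35, seed=rng.integers(1000))
    flags = np.zeros(30, dtype=bool)
    flags[[2, 5]] = True
    rings = ring_distance(g, flags)
    for node in g.nodes:
        expected = min(
            nx.shortest_path_length(g, node, s) for s in (2, 5)
        )
        assert rings[node] == expected
    assert all(rings[f] == 0 for f in (2, 5))


def test_ring_distance_requires_cluster():
    g = nx.path_graph(5)
    with pytest.raises(ValueError):
        ring_distance(g, np.zeros(5, dtype=bool))


def test_ring_categories():
    assert ring_category(0) is None
    assert [ring_category(r) for r in (1, 3, 4, 6, 7, 12)] == [
        "1-3", "1-3", "4-6", "4-6", "7+", "7+",
    ]


@pytest.mark.parametrize(
    "axis_deg,expected",
    [(0.0, 0.0), (90.0, 90.0), (60.0, 60.0), (240.0, 60.0)],
)
def test_division_orientation_relative_to_circular_cluster(axis_deg, expected):
    boundary = cluster_boundary(
        [np.stack([np.cos(t), np.sin(t)], axis=1)
         for t in [np.linspace(0, 2 * np.pi, 60, endpoint=False)]]
    )
    # dividing cell sits on the +x axis: reference direction is 180 deg
    theta = np.radians(180.0 + axis_deg)
    ev = DivisionEvent(
        time_min=1.0,
        cell_centroid=[3.0, 0.0],
        daughter_axis=[np.cos(theta), np.sin(theta)],
    )
    assert division_orientation(ev, boundary) == pytest.approx(expected, abs=1e-6)


def test_out_of_plane_division_rejected():
    ev = DivisionEvent(1.0, [3.0, 0.0], [1.0, 0.0], in_plane=False)
    boundary = cluster_boundary([SQUARE])
    with pytest.raises(ValueError):
        division_orientation(ev, boundary)


def test_division_rate_examples():
    assert division_rate(6, 100, 30.0) == pytest.approx(0.2)
    assert division_rate(0, 100, 30.0) == 0.0
    assert division_rate(6, 100, 60.0) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        division_rate(1, 100, 0.0)


def test_rose_histogram_binning(rng):
    counts = rose_histogram([5.0, 15.0, 85.0, 90.0])
    assert counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 2]
    assert rose_histogram([]).tolist() == [0] * 9
    with pytest.raises(ValidationError, match="95"):
        rose_histogram([5.0, 95.0])
    # uniform samples spread evenly (multinomial)
    big = rng.uniform(0, 90, 9000)
    counts = rose_histogram(big)
    assert counts.sum() == 9000
    assert np.all(np.abs(counts - 1000) < 5 * np.sqrt(1000))
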