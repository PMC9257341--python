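"""Neighbor graphs, observed/expected/corrected percentages, permutation z."""

import numpy as np
import pandas as pd
import pytest

from imcmicro.microenv import (
    build_neighbor_graph,
    microenvironment_matrix,
    permutation_z,
)

from .oracles import brute_edges, brute_observed, enumerate_permutation_z


def _cells(points, rois=None):
    pts = np.asarray(points, dtype=float)
    df = pd.DataFrame(
        {"cell_id": np.arange(len(pts)) + 1, "x": pts[:, 0], "y": pts[:, 1]}
    )
    if rois is not None:
        df["roi_id"] = rois
    return df


def test_radius_is_inclusive():
    g = build_neighbor_graph(_cells([[0, 0], [10, 0]]), radius=10, mode="centroid")
    assert len(g.edges) == 1
    g2 = build_neighbor_graph(_cells([[0, 0], [10.01, 0]]), radius=10, mode="centroid")
    assert len(g2.edges) == 0


def test_single_cell_has_no_self_edge():
    g = build_neighbor_graph(_cells([[5, 5]]), radius=10, mode="centroid")
    assert len(g.edges) == 0


def test_graph_matches_bruteforce_all_pairs(random_cells):
    g = build_neighbor_graph(random_cells, radius=10, mode="centroid")
    got = {tuple(sorted(e)) for e in g.edges.tolist()}
    expected = brute_edges(random_cells[["x", "y"]].to_numpy(), 10)
    assert got == expected


def test_edges_never_cross_rois():
    cells = _cells([[0, 0], [5, 0], [0, 0], [5, 0]], rois=["r1", "r1", "r2", "r2"])
    g = build_neighbor_graph(cells, radius=10, mode="centroid")
    roi = cells["roi_id"].to_numpy()
    assert len(g.edges) == 2
    assert all(roi[i] == roi[j] for i, j in g.edges)


def test_boundary_mode_uses_minimum_mask_distance():
    # two 2×2 cells: nearest pixels at x=2 and x=5, so pixel distance 3
    # while centroid distance is 4
    mask = np.zeros((8, 12), dtype=int)
    mask[3:5, 1:3] = 1
    mask[3:5, 5:7] = 2
    cells = pd.DataFrame({"cell_id": [1, 2], "x": [1.5, 5.5], "y": [3.5, 3.5]})
    g3 = build_neighbor_graph(cells, radius=3, mode="boundary", masks=mask)
    assert len(g3.edges) == 1
    g2 = build_neighbor_graph(cells, radius=2, mode="boundary", masks=mask)
    assert len(g2.edges) == 0
    with pytest.raises(ValueError, match="masks"):
        build_neighbor_graph(cells, radius=3, mode="boundary")


def test_hand_worked_observed_expected_corrected():
    """A₁(0,0) B₁(5,0) A₂(100,0) B₂(200,0), r=10: one qualifying A-B pair."""
    cells = _cells([[0, 0], [5, 0], [100, 0], [200, 0]])
    labels = pd.Series(["A", "B", "A", "B"])
    g = build_neighbor_graph(cells, radius=10, mode="centroid")
    m = microenvironment_matrix(g, labels).set_index(["cluster_a", "cluster_b"])
    row = m.loc[("A", "B")]
    assert row["observed"] == 0.5
    assert row["expected"] == 0.25
    assert row["corrected"] == 0.25


def test_saturated_single_type_field():
    cells = _cells([[0, 0], [5, 0], [10, 0]])
    labels = pd.Series(["A", "A", "A"])
    g = build_neighbor_graph(cells, radius=10, mode="centroid")
    m = microenvironment_matrix(g, labels).iloc[0]
    assert m["observed"] == 1.0 and m["expected"] == 1.0 and m["corrected"] == 0.0


def test_empty_graph_observed_zero_corrected_negative_expected():
    cells = _cells([[0, 0], [100, 100], [200, 0]])
    labels = pd.Series(["A", "B", "A"])
    g = build_neighbor_graph(cells, radius=5, mode="centroid")
    m = microenvironment_matrix(g, labels)
    assert (m["observed"] == 0).all()
    assert np.allclose(m["corrected"], -m["expected"])
    zs = permutation_z(g, labels, n_perm=50, seed=0)
    assert (zs["z"] == 0).all()


def test_observed_matches_bruteforce(random_cells):
    rng = np.random.default_rng(11)
    labels = pd.Series(rng.choice(["A", "B", "C"], size=len(random_cells)))
    g = build_neighbor_graph(random_cells, radius=10, mode="centroid")
    m = microenvironment_matrix(g, labels).set_index(["cluster_a", "cluster_b"])
    pts = random_cells[["x", "y"]].to_numpy()
    for a in "ABC":
        for b in "ABC":
            expected = brute_observed(pts, labels, 10, a, b)
            assert m.loc[(a, b), "observed"] == expected, (a, b)


def test_rigid_motion_invariance(random_cells):
    rng = np.random.default_rng(12)
    labels = pd.Series(rng.choice(["A", "B"], size=len(random_cells)))
    g1 = build_neighbor_graph(random_cells, radius=10, mode="centroid")
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = random_cells.copy()
    xy = random_cells[["x", "y"]].to_numpy() @ rot.T + np.array([50.0, -20.0])
    moved["x"], moved["y"] = xy[:, 0], xy[:, 1]
    g2 = build_neighbor_graph(moved, radius=10, mode="centroid")
    m1 = microenvironment_matrix(g1, labels)
    m2 = microenvironment_matrix(g2, labels)
    pd.testing.assert_frame_equal(m1, m2)
    z1 = permutation_z(g1, labels, n_perm=100, seed=5)
    z2 = permutation_z(g2, labels, n_perm=100, seed=5)
    pd.testing.assert_frame_equal(z1, z2)


def test_bounds_invariants(random_cells):
    rng = np.random.default_rng(13)
    labels = pd.Series(rng.choice(["A", "B", "C"], size=len(random_cells)))
    g = build_neighbor_graph(random_cells, radius=10, mode="centroid")
    m = microenvironment_matrix(g, labels)
    assert m["observed"].between(0, 1).all()
    assert m["expected"].between(0, 1).all()
    assert m["corrected"].between(-1, 1).all()


def test_permutation_deterministic_under_seed(random_cells):
    rng = np.random.default_rng(14)
    labels = pd.Series(rng.choice(["A", "B"], size=len(random_cells)))
    g = build_neighbor_graph(random_cells, radius=10, mode="centroid")
    z1 = permutation_z(g, labels, n_perm=100, seed=3)
    z2 = permutation_z(g, labels, n_perm=100, seed=3)
    pd.testing.assert_frame_equal(z1, z2)


def test_nperm_too_small():
    g = build_neighbor_graph(_cells([[0, 0], [1, 0]]), radius=10, mode="centroid")
    with pytest.raises(ValueError, match="n_perm"):
        permutation_z(g, pd.Series(["A", "B"]), n_perm=1, seed=0)


def test_sampled_z_matches_exhaustive_enumeration():
    """6 cells (3 A, 3 B) on a line: sampled z within 0.1 of the exact z
    from enumerating all 20 distinct label arrangements."""
    pts = np.array([[i * 8.0, 0.0] for i in range(6)])  # chain, r=10 links neighbors
    labels = ["A", "A", "A", "B", "B", "B"]
    z_exact = enumerate_permutation_z(pts, labels, 10.0, "A", "B")
    g = build_neighbor_graph(_cells(pts), radius=10, mode="centroid")
    zs = permutation_z(g, pd.Series(labels), n_perm=10_000, seed=17)
    z_sampled = zs.set_index(["cluster_a", "cluster_b"]).loc[("A", "B"), "z"]
    assert abs(z_sampled - z_exact) <= 0.1


def test_permutation_shuffles_within_roi_only():
    """Labels stay within their ROI: a pair split across ROIs stays null."""
    # ROI r1 holds only A cells, r2 only B cells; any permutation keeps that,
    # so observed(A,B) is identically 0 and z must be exactly 0.
    cells = _cells(
        [[0, 0], [5, 0], [0, 0], [5, 0]], rois=["r1", "r1", "r2", "r2"]
    )
    labels = pd.Series(["A", "A", "B", "B"])
    g = build_neighbor_graph(cells, radius=10, mode="centroid")
    zs = permutation_z(g, labels, n_perm=200, seed=1)
    z_ab = zs.set_index(["cluster_a", "cluster_b"]).loc[("A", "B"), "z"]
    assert z_ab == 0.0
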