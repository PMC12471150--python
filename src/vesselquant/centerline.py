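"""Centerline extraction and refinement for single-vessel binary masks.

The principal centerline is the longest shortest path (in physical mm)
between any two endpoints of the skeleton graph of the mask:

1. topology-preserving 3D thinning of the mask to a 1-voxel-wide skeleton;
2. pruning to the largest connected component (26-connectivity);
3. conversion to a weighted graph (nodes = skeleton voxels, edge weight =
   Euclidean distance in mm between neighbouring voxel centres);
4. Dijkstra shortest paths between all endpoint pairs, keeping the pair with
   maximal path length;
5. refinement: uniform-filter smoothing of the Y/X coordinate sequences with
   jump correction, then snapping the first and last fraction of points to
   the slice-wise centre of mass of the mask.

Paths are always ordered so the first point has the smaller (or equal)
z-coordinate, giving a reproducible inferior-to-superior traversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .volumes import Volume

__all__ = [
    "Skeleton",
    "SkeletonGraph",
    "Centerline",
    "skeletonize",
    "largest_connected_component",
    "to_graph",
    "principal_path",
    "smooth_centerline",
    "correct_endpoints",
    "extract_centerline",
    "centerline_to_csv",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Skeleton:
    """1-voxel-wide medial axis: integer (z, y, x) voxels plus grid context."""

    voxels: np.ndarray  # (N, 3) int
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.voxels)

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out


@dataclass
class SkeletonGraph:
    """Weighted adjacency graph of a connected skeleton."""

    graph: nx.Graph
    spacing: tuple[float, float, float]

    @property
    def endpoints(self) -> list[tuple[int, int, int]]:
        return sorted(n for n, d in self.graph.degree() if d == 1)


@dataclass
class Centerline:
    """Ordered (z, y, x) points through a vessel, with refinement stage."""

    points: np.ndarray  # (N, 3) float
    spacing: tuple[float, float, float]
    stage: str = "raw"  # raw | smoothed | endpoint_corrected

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        if self.points[0, 0] > self.points[-1, 0]:
            raise ValueError("centerline must be ordered with z_first <= z_last")
        if (np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive centerline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative physical arc length (mm) at each point; starts at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0) * np.asarray(self.spacing), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length_mm(self) -> float:
        return float(self.arc_lengths()[-1])


def _rethin_symmetric(comp: np.ndarray) -> np.ndarray:
    """Thin a component that the standard pass deleted entirely.

    Perfectly symmetric objects of even width can be annihilated by
    simultaneous removal of opposite border voxels. Breaking the symmetry
    with a one-voxel one-sided dilation makes the thinning well-behaved;
    the resulting skeleton voxels are then mapped to their nearest voxel
    inside the original component.
    """
    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, 1] = struct[2, 1, 1] = struct[1, 2, 1] = struct[1, 1, 2] = True
    grown = ndimage.binary_dilation(comp, structure=struct)
    skel_g = _sk_skeletonize(grown)
    if not skel_g.any():
        raise RuntimeError("thinning produced an empty skeleton for a nonempty component")
    _, nearest = ndimage.distance_transform_edt(~comp, return_indices=True)
    out = np.zeros_like(comp)
    vox = np.argwhere(skel_g)
    mapped = nearest[:, vox[:, 0], vox[:, 1], vox[:, 2]].T
    out[tuple(mapped.T)] = True
    return out


def skeletonize(mask: Volume) -> Skeleton:
    """Thin a binary mask to its 1-voxel-wide medial axis.

    Uses topology-preserving iterative thinning, so the number of connected
    components and loops of the mask is preserved. Components that vanish
    under the standard pass (exactly symmetric tubes of even voxel width)
    are re-thinned after a symmetry-breaking one-sided dilation.
    """
    if not mask.is_binary():
        raise ValueError("skeletonize expects a binary mask")
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("skeletonize expects a nonempty mask")
    skel = _sk_skeletonize(data).astype(bool)
    labels, n = ndimage.label(data, structure=_STRUCT26)
    for lab in range(1, n + 1):
        comp = labels == lab
        if not (skel & comp).any():
            skel |= _rethin_symmetric(comp)
    voxels = np.argwhere(skel)
    return Skeleton(voxels=voxels, shape=mask.shape, spacing=mask.spacing)


def largest_connected_component(s: Skeleton) -> Skeleton:
    """Retain only the largest 26-connected component of the skeleton.

    Ties in voxel count are broken deterministically: the component whose
    lexicographically smallest voxel is smallest wins.
    """
    if len(s) == 0:
        raise ValueError("empty skeleton")
    labels, n = ndimage.label(s.to_dense(), structure=_STRUCT26)
    if n <= 1:
        return Skeleton(voxels=s.voxels, shape=s.shape, spacing=s.spacing)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = None
    for lab in np.flatnonzero(sizes == sizes.max()) + 1:
        vox = np.argwhere(labels == lab)
        vox = vox[np.lexsort(vox.T[::-1])]
        key = tuple(vox[0])
        if best is None or key < best[0]:
            best = (key, vox)
    assert best is not None
    return Skeleton(voxels=best[1], shape=s.shape, spacing=s.spacing)


def to_graph(s: Skeleton) -> SkeletonGraph:
    """Convert a connected skeleton to a weighted graph.

    One node per voxel; edges join 26-neighbours and are weighted by the
    Euclidean distance in mm between the voxel centres.
    """
    if len(s) == 0:
        raise ValueError("empty skeleton")
    g = nx.Graph()
    voxset = {tuple(v) for v in s.voxels}
    sp = np.asarray(s.spacing)
    for v in sorted(voxset):
        g.add_node(v)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # half the 26-neighbourhood avoids duplicates
    ]
    for v in sorted(voxset):
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxset:
                weight = float(np.linalg.norm(np.asarray(off) * sp))
                g.add_edge(v, w, weight=weight)
    return SkeletonGraph(graph=g, spacing=s.spacing)


def principal_path(g: SkeletonGraph) -> Centerline:
    """Longest shortest path between any two skeleton endpoints.

    Dijkstra from every endpoint; the endpoint pair with maximal shortest-path
    length wins, ties broken by lexicographic order of the (sorted) endpoint
    coordinate pair. The path is returned with z_first <= z_last.
    """
    endpoints = g.endpoints
    if len(endpoints) < 2:
        raise ValueError(
            f"principal path needs at least 2 endpoints, found {len(endpoints)} "
            "(loop-only skeleton?)"
        )
    best_key: tuple | None = None
    best_path: list | None = None
    for i, e in enumerate(endpoints):
        dist, paths = nx.single_source_dijkstra(g.graph, e, weight="weight")
        for f in endpoints[i + 1 :]:
            if f not in dist:
                continue
            # maximise length; among ties prefer the smallest endpoint pair
            key = (-dist[f], (e, f))
            if best_key is None or key < best_key:
                best_key = key
                best_path = paths[f]
    if best_path is None:
        raise ValueError("no endpoint pair is connected")
    pts = np.asarray(best_path, dtype=np.float64)
    if pts[0, 0] > pts[-1, 0]:
        pts = pts[::-1]
    return Centerline(points=pts, spacing=g.spacing, stage="raw")


def _correct_jumps(seq: np.ndarray, thresh: float) -> np.ndarray:
    """Replace points after a consecutive jump > thresh by their neighbour mean."""
    out = seq.astype(np.float64).copy()
    n = len(out)
    for k in range(1, n):
        if abs(out[k] - out[k - 1]) > thresh:
            if k + 1 < n:
                out[k] = 0.5 * (out[k - 1] + out[k + 1])
            else:
                out[k] = out[k - 1]
    return out


def smooth_centerline(c: Centerline, win: int = 5, jump_thresh: float = 3.0) -> Centerline:
    """Smooth the Y and X coordinate sequences of a raw centerline.

    Sudden jumps larger than ``jump_thresh`` voxels between consecutive
    points are first corrected by local neighbour averaging; the sequences
    are then passed through a length-``win`` moving-average (uniform) filter.
    Z coordinates are untouched and the number of points is preserved.
    """
    if c.stage != "raw":
        raise ValueError(f"smooth_centerline expects a raw centerline, got stage {c.stage!r}")
    if win < 1 or win % 2 == 0:
        raise ValueError(f"win must be a positive odd integer, got {win}")
    if jump_thresh <= 0:
        raise ValueError(f"jump_thresh must be positive, got {jump_thresh}")
    pts = c.points.copy()
    for axis in (1, 2):
        seq = _correct_jumps(pts[:, axis], jump_thresh)
        if win > 1:
            seq = ndimage.uniform_filter1d(seq, size=win, mode="nearest")
        pts[:, axis] = seq
    return Centerline(points=pts, spacing=c.spacing, stage="smoothed")


def _slice_com(mask_slice: np.ndarray, near_yx: np.ndarray, z: int) -> np.ndarray:
    """Foreground centre of mass of one z-slice, restricted to the connected
    component nearest ``near_yx``; snapped inside the component if needed."""
    fg = np.argwhere(mask_slice)
    if len(fg) == 0:
        raise ValueError(f"z-slice {z} has no mask foreground; cannot correct endpoint")
    labels, n = ndimage.label(mask_slice, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        dists = np.linalg.norm(fg - near_yx, axis=1)
        lab = labels[tuple(fg[int(np.argmin(dists))])]
        fg = np.argwhere(labels == lab)
    com = fg.mean(axis=0)
    # non-convex slices can place the CoM outside the component: snap inside
    ci = np.rint(com).astype(int)
    if not mask_slice[ci[0], ci[1]]:
        com = fg[int(np.argmin(np.linalg.norm(fg - com, axis=1)))].astype(float)
    return com


def correct_endpoints(c: Centerline, mask: Volume, fraction: float = 0.05) -> Centerline:
    """Snap both ends of a smoothed centerline to slice-wise mask centres of mass.

    The first and last ``ceil(fraction * N)`` points have their Y/X set to
    the foreground centre of mass of the mask's z-slice at that point, so the
    centerline reliably starts inside the lumen at both ends.
    """
    if c.stage != "smoothed":
        raise ValueError(f"correct_endpoints expects a smoothed centerline, got {c.stage!r}")
    if not (0 < fraction < 0.5):
        raise ValueError(f"fraction must lie in (0, 0.5), got {fraction}")
    n = len(c)
    n_corr = math.ceil(fraction * n)
    pts = c.points.copy()
    for k in list(range(n_corr)) + list(range(n - n_corr, n)):
        z = int(round(pts[k, 0]))
        com = _slice_com(mask.data[z].astype(bool), pts[k, 1:], z)
        pts[k, 1:] = com
    # steep segments can place several consecutive points in one z-slice;
    # their corrected coordinates coincide, so drop the duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.diff(pts, axis=0) != 0).any(axis=1)
    return Centerline(points=pts[keep], spacing=c.spacing, stage="endpoint_corrected")


def extract_centerline(
    mask: Volume,
    win: int = 5,
    jump_thresh: float = 3.0,
    fraction: float = 0.05,
) -> Centerline:
    """Full pipeline: skeletonize -> LCC -> graph -> longest shortest path ->
    smoothing -> endpoint correction. Returns the refined centerline."""
    skel = largest_connected_component(skeletonize(mask))
    c = principal_path(to_graph(skel))
    c = smooth_centerline(c, win=win, jump_thresh=jump_thresh)
    return correct_endpoints(c, mask, fraction=fraction)


def centerline_to_csv(c: Centerline, path: str) -> None:
    """Export as CSV (k, z, y, x) in voxel coordinates; spacing in the header."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "k": np.arange(len(c)),
            "z": c.points[:, 0],
            "y": c.points[:, 1],
            "x": c.points[:, 2],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# spacing_zyx_mm={c.spacing[0]},{c.spacing[1]},{c.spacing[2]} stage={c.stage}\n")
        df.to_csv(fh, index=False)
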