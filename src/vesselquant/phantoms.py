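"""Synthetic vascular phantoms with analytic ground truth.

Tubular binary masks (straight/tilted cylinders, linearly tapered tubes,
torus segments and an aorto-iliac-style bifurcation) are voxelised by
centre-point membership: a voxel belongs to the phantom iff its centre lies
inside the analytic tube. Each generator returns the mask together with a
:class:`TubeTruth` giving the exact centerline and the exact diameter at any
position, so centerline extraction and diameter profiling can be validated
without any imaging data. Probability-map phantoms with controllable
confidence exercise the uncertainty scoring.

All geometry is in physical mm; points are (z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .volumes import Volume

__all__ = [
    "PhantomSpec",
    "TubeTruth",
    "make_tube_mask",
    "cylinder_phantom",
    "tapered_phantom",
    "torus_phantom",
    "bifurcation_phantom",
    "make_probability_map",
]


@dataclass
class TubeTruth:
    """Analytic ground truth for a tube phantom.

    ``centerline_vox`` samples the exact axis in voxel coordinates;
    ``diameter_at(p_vox)`` returns the exact local diameter (mm) for any
    point near the tube; ``length_mm`` is the axis arc length.
    """

    centerline_vox: np.ndarray  # (N, 3) float, ZYX
    diameter_at: Callable[[np.ndarray], float]
    length_mm: float


@dataclass
class PhantomSpec:
    """Declarative description of a tube phantom.

    shape
        One of ``cylinder``, ``tapered``, ``torus_segment``, ``bifurcation``.
    radius / radius2
        Tube radius in mm; ``radius2`` is the far-end radius of a taper or
        the branch radius of a bifurcation.
    length
        Axis length in mm (trunk length for a bifurcation).
    bend_radius
        Ring radius of the torus segment, mm.
    branch_angle_deg
        Angle of each bifurcation branch from the trunk axis.
    tilt_deg
        Rotation of the cylinder/taper axis away from z, in the z-x plane.
    spacing
        Isotropic-by-default voxel spacing (z, y, x), mm.
    margin_mm
        Background padding around the phantom (>= 2 voxels enforced).
    """

    shape: str = "cylinder"
    radius: float = 6.0
    radius2: float | None = None
    length: float = 60.0
    bend_radius: float = 30.0
    branch_angle_deg: float = 30.0
    tilt_deg: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0 or self.bend_radius <= 0:
            raise ValueError("phantom geometric lengths must be positive")
        if self.radius2 is not None and self.radius2 <= 0:
            raise ValueError("radius2 must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.margin_mm < 2 * max(self.spacing):
            raise ValueError("phantom must fit inside the grid with a >= 2-voxel margin")


def _voxel_centers(shape: tuple[int, int, int], spacing) -> list[np.ndarray]:
    """Physical coordinates of voxel centres per axis (broadcastable)."""
    sp = np.asarray(spacing)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij", sparse=True
    )
    return grids


def _check_margin(data: np.ndarray) -> None:
    border = np.zeros_like(data, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    if (data & border).any():
        raise ValueError("phantom touches the grid border; enlarge the grid or margin")


def _segment_phantom(spec: PhantomSpec, tapered: bool) -> tuple[Volume, TubeTruth]:
    """Straight (optionally tapered) tube, axis tilted in the z-x plane."""
    sp = np.asarray(spec.spacing)
    r0 = spec.radius
    r1 = spec.radius2 if (tapered and spec.radius2 is not None) else spec.radius
    rmax = max(r0, r1)
    t = np.deg2rad(spec.tilt_deg)
    axis = np.array([np.cos(t), 0.0, np.sin(t)])  # ZYX

    half = spec.length / 2.0
    extent = np.abs(axis) * half + rmax + spec.margin_mm
    shape = tuple(int(np.ceil(2 * e / s)) + 1 for e, s in zip(extent, sp))
    center = (np.asarray(shape) - 1) * sp / 2.0

    zz, yy, xx = _voxel_centers(shape, sp)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    a = dz * axis[0] + dy * axis[1] + dx * axis[2]  # axial coordinate in [-L/2, L/2]
    rad2 = (dz - a * axis[0]) ** 2 + (dy - a * axis[1]) ** 2 + (dx - a * axis[2]) ** 2
    r_here = r0 + (r1 - r0) * (a + half) / spec.length
    data = (np.abs(a) <= half) & (rad2 <= r_here**2)
    data = np.ascontiguousarray(data.astype(np.uint8))
    _check_margin(data.astype(bool))
    mask = Volume(data=data, spacing=tuple(sp))

    n_samples = max(int(np.ceil(spec.length)), 2)
    s_vals = np.linspace(-half, half, n_samples)
    cl_phys = center[None, :] + s_vals[:, None] * axis[None, :]
    cl_vox = cl_phys / sp

    def diameter_at(p_vox: np.ndarray) -> float:
        p_phys = np.asarray(p_vox, dtype=float) * sp
        s = float(np.clip(np.dot(p_phys - center, axis), -half, half))
        return 2.0 * (r0 + (r1 - r0) * (s + half) / spec.length)

    return mask, TubeTruth(centerline_vox=cl_vox, diameter_at=diameter_at, length_mm=spec.length)


def cylinder_phantom(
    radius: float = 6.0,
    length: float = 60.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tilt_deg: float = 0.0,
    margin_mm: float = 4.0,
) -> tuple[Volume, TubeTruth]:
    spec = PhantomSpec(
        shape="cylinder", radius=radius, length=length, spacing=spacing,
        tilt_deg=tilt_deg, margin_mm=margin_mm,
    )
    return _segment_phantom(spec, tapered=False)


def tapered_phantom(
    radius_start: float = 10.0,
    radius_end: float = 5.0,
    length: float = 100.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tilt_deg: float = 0.0,
    margin_mm: float = 4.0,
) -> tuple[Volume, TubeTruth]:
    """Linearly tapered tube; diameter varies linearly along the axis."""
    spec = PhantomSpec(
        shape="tapered", radius=radius_start, radius2=radius_end, length=length,
        spacing=spacing, tilt_deg=tilt_deg, margin_mm=margin_mm,
    )
    return _segment_phantom(spec, tapered=True)


def torus_phantom(
    tube_radius: float = 5.0,
    bend_radius: float = 30.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin_mm: float = 4.0,
) -> tuple[Volume, TubeTruth]:
    """Quarter-torus tube (constant diameter, strong curvature) in the z-y plane."""
    spec = PhantomSpec(
        shape="torus_segment", radius=tube_radius, bend_radius=bend_radius,
        spacing=spacing, margin_mm=margin_mm,
    )
    sp = np.asarray(spec.spacing)
    r, R = spec.radius, spec.bend_radius
    # ring centre placed so the arc phi in [0, pi/2] fits with margin
    c = np.array([r + spec.margin_mm, r + spec.margin_mm, r + spec.margin_mm])
    extent = c + np.array([R + r, R + r, r]) + spec.margin_mm
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, sp))

    zz, yy, xx = _voxel_centers(shape, sp)
    dz, dy, dx = zz - c[0], yy - c[1], xx - c[2]
    rho = np.hypot(dz, dy)
    phi = np.arctan2(dy, dz)
    dist2 = (rho - R) ** 2 + dx**2
    data = (dist2 <= r**2) & (phi >= 0.0) & (phi <= np.pi / 2)
    data = np.ascontiguousarray(data.astype(np.uint8))
    _check_margin(data.astype(bool))
    mask = Volume(data=data, spacing=tuple(sp))

    length = R * np.pi / 2
    phis = np.linspace(0.0, np.pi / 2, max(int(np.ceil(length)), 2))
    cl_phys = np.stack(
        [c[0] + R * np.cos(phis), c[1] + R * np.sin(phis), np.full_like(phis, c[2])], axis=1
    )
    cl_vox = cl_phys / sp

    def diameter_at(p_vox: np.ndarray) -> float:
        return 2.0 * r

    return mask, TubeTruth(centerline_vox=cl_vox, diameter_at=diameter_at, length_mm=length)


def bifurcation_phantom(
    trunk_radius: float = 8.0,
    branch_radius: float = 4.0,
    trunk_length: float = 40.0,
    branch_length: float = 35.0,
    branch_angle_deg: float = 30.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin_mm: float = 4.0,
) -> tuple[Volume, TubeTruth]:
    """Aorto-iliac-style bifurcation: a vertical trunk (superior) splitting
    into two branches descending at +/- the branch angle in the z-x plane.

    The principal (longest-shortest) path traverses the trunk and one branch.
    The analytic truth follows trunk + the +angle branch.
    """
    spec = PhantomSpec(
        shape="bifurcation", radius=trunk_radius, radius2=branch_radius,
        length=trunk_length, branch_angle_deg=branch_angle_deg, spacing=spacing,
        margin_mm=margin_mm,
    )
    sp = np.asarray(spec.spacing)
    a = np.deg2rad(branch_angle_deg)
    d_plus = np.array([-np.cos(a), 0.0, np.sin(a)])  # descending, +x
    d_minus = np.array([-np.cos(a), 0.0, -np.sin(a)])

    rmax = max(trunk_radius, branch_radius)
    bx = branch_length * np.sin(a) + branch_radius
    junction = np.array(
        [branch_length * np.cos(a) + rmax + margin_mm, 0.0, bx + margin_mm]
    )
    junction[1] = rmax + margin_mm
    top = junction + np.array([trunk_length, 0.0, 0.0])
    extent = np.array(
        [top[0] + trunk_radius + margin_mm,
         2 * junction[1],
         2 * junction[2]]
    )
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, sp))

    zz, yy, xx = _voxel_centers(shape, sp)

    def capsule(p0: np.ndarray, direction: np.ndarray, length: float, radius: float):
        dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
        t = np.clip(dz * direction[0] + dy * direction[1] + dx * direction[2], 0.0, length)
        return (
            (dz - t * direction[0]) ** 2
            + (dy - t * direction[1]) ** 2
            + (dx - t * direction[2]) ** 2
        ) <= radius**2

    data = (
        capsule(junction, np.array([1.0, 0.0, 0.0]), trunk_length, trunk_radius)
        | capsule(junction, d_plus, branch_length, branch_radius)
        | capsule(junction, d_minus, branch_length, branch_radius)
    )
    data = np.ascontiguousarray(data.astype(np.uint8))
    _check_margin(data.astype(bool))
    mask = Volume(data=data, spacing=tuple(sp))

    # truth path: branch(+) tip -> junction -> trunk top (inferior to superior)
    n_b = max(int(np.ceil(branch_length)), 2)
    n_t = max(int(np.ceil(trunk_length)), 2)
    branch_pts = junction[None, :] + np.linspace(branch_length, 0, n_b)[:, None] * d_plus[None, :]
    trunk_pts = junction[None, :] + np.linspace(0, trunk_length, n_t)[1:, None] * np.array(
        [1.0, 0.0, 0.0]
    )[None, :]
    cl_phys = np.vstack([branch_pts, trunk_pts])
    cl_vox = cl_phys / sp

    def diameter_at(p_vox: np.ndarray) -> float:
        p = np.asarray(p_vox, dtype=float) * sp
        # distance to trunk axis vs branch axes decides the local calibre
        def seg_dist(p0, direction, length):
            d = p - p0
            t = float(np.clip(np.dot(d, direction), 0.0, length))
            return float(np.linalg.norm(d - t * direction))

        d_trunk = seg_dist(junction, np.array([1.0, 0.0, 0.0]), trunk_length) - trunk_radius
        d_b1 = seg_dist(junction, d_plus, branch_length) - branch_radius
        d_b2 = seg_dist(junction, d_minus, branch_length) - branch_radius
        nearest = int(np.argmin([d_trunk, d_b1, d_b2]))
        return 2.0 * (trunk_radius if nearest == 0 else branch_radius)

    length = trunk_length + branch_length
    return mask, TubeTruth(centerline_vox=cl_vox, diameter_at=diameter_at, length_mm=length)


def make_tube_mask(spec: PhantomSpec) -> tuple[Volume, TubeTruth]:
    """Dispatch a :class:`PhantomSpec` to the matching generator."""
    if spec.shape == "cylinder":
        return _segment_phantom(spec, tapered=False)
    if spec.shape == "tapered":
        if spec.radius2 is None:
            raise ValueError("tapered phantom needs radius2")
        return _segment_phantom(spec, tapered=True)
    if spec.shape == "torus_segment":
        return torus_phantom(
            tube_radius=spec.radius, bend_radius=spec.bend_radius,
            spacing=spec.spacing, margin_mm=spec.margin_mm,
        )
    if spec.shape == "bifurcation":
        return bifurcation_phantom(
            trunk_radius=spec.radius,
            branch_radius=spec.radius2 or spec.radius / 2,
            trunk_length=spec.length,
            branch_angle_deg=spec.branch_angle_deg,
            spacing=spec.spacing,
            margin_mm=spec.margin_mm,
        )
    raise ValueError(f"unknown phantom shape {spec.shape!r}")


def make_probability_map(
    mask: Volume,
    p_in: float = 0.95,
    p_boundary: float = 0.7,
    boundary_width: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Volume:
    """Probability-map phantom with controllable confidence.

    Interior voxels sit near ``p_in``, a ``boundary_width``-voxel shell near
    ``p_boundary``, background at exactly 0. Gaussian noise of the given SD
    is added to the foreground only (so the background stays clean) and the
    result is clipped to [0, 1]. Deterministic given ``seed``.
    """
    for name, p in (("p_in", p_in), ("p_boundary", p_boundary)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    fg = mask.data.astype(bool)
    if boundary_width > 0:
        interior = ndimage.binary_erosion(fg, iterations=boundary_width)
    else:
        interior = fg
    shell = fg & ~interior
    prob = np.zeros(mask.shape, dtype=np.float64)
    prob[interior] = p_in
    prob[shell] = p_boundary
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        prob[fg] += rng.normal(0.0, noise_sd, size=int(fg.sum()))
    np.clip(prob, 0.0, 1.0, out=prob)
    return Volume(data=prob, spacing=mask.spacing)
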