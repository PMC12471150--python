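"""Hybrid diameter profiling along a refined centerline.

At each centerline point P_k the local lumen diameter is estimated twice and
the two estimates are averaged:

* **distance-transform diameter** ``D_DT = 2 * EDT(P_k)`` — twice the
  spacing-aware Euclidean distance to the nearest background voxel, i.e. the
  inscribed-sphere diameter;
* **ray-casting diameter** — N_rays rays are cast in the plane orthogonal to
  the local tangent; each ray marches in both directions until it exits the
  mask, and its diameter is the spacing-weighted norm of the exit-point
  difference ``||(B+ - B-) . S||``. The median over rays is kept.

The raw profile ``(D_DT + median(D_ray)) / 2`` may contain missing values
(points that fell outside the mask, or rays that never exited); these are
linearly interpolated over the point index, and a Savitzky-Golay filter
(polynomial order 3, window up to 51 points) yields the final smooth profile.

The orthogonal plane is the YX slice when the tangent is nearly parallel to
the z-axis; otherwise an orthonormal basis is completed branchlessly from the
tangent (Frisvad construction), which is stable for any direction including
the near-antiparallel case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter

from .centerline import Centerline
from .volumes import Volume

__all__ = [
    "DiameterConfig",
    "FramedPoint",
    "DiameterProfile",
    "edt_diameter",
    "local_tangent",
    "frisvad_basis",
    "orthonormal_frame",
    "cast_ray",
    "ray_diameters",
    "combined_diameter",
    "finalize_profile",
    "compute_profile",
]


@dataclass
class DiameterConfig:
    """Tunables of the diameter estimator.

    n_rays
        Rays per point, spanning half-plane angles i*pi/n_rays (each ray is
        cast in both +d and -d, so 8 rays probe 16 half-directions).
    theta_thresh_deg
        Tangents within this angle of the z-axis use the cheap YX-slice plane.
    sg_polyorder / sg_max_window
        Savitzky-Golay smoothing of the final profile; the window shrinks to
        the largest odd number <= N_p for short centerlines.
    march_step_factor
        Ray-marching step as a fraction of the smallest voxel spacing.
    cap_reject_angle_deg
        Near a vessel end the nearest background voxel sits on the
        truncation cap, and the distance transform measures the cut rather
        than the lumen. When the direction to the nearest background voxel
        is within this angle of the local tangent, the distance-transform
        estimate is recorded as missing and recovered by interpolation.
        Set to None to disable.
    tangent_outlier_deg
        A tangent that deviates more than this angle from the mean of its
        neighbours' tangents (window of 3 each side) is replaced by that
        mean — the analogue, for the derived tangent field, of the
        centerline's coordinate jump correction. Guards the ray-casting
        plane against isolated kinks, e.g. where an endpoint was snapped to
        a slice centre of mass. Set to None to disable.
    """

    n_rays: int = 8
    theta_thresh_deg: float = 10.0
    sg_polyorder: int = 3
    sg_max_window: int = 51
    march_step_factor: float = 0.25
    cap_reject_angle_deg: float | None = 45.0
    tangent_outlier_deg: float | None = 30.0


@dataclass
class FramedPoint:
    """A centerline point with its tangent and orthogonal in-plane basis."""

    tangent: np.ndarray  # unit, physical ZYX
    u: np.ndarray
    v: np.ndarray
    plane_mode: str  # "yx_slice" | "frisvad"
    point: np.ndarray | None = None  # voxel ZYX


@dataclass
class DiameterProfile:
    """Per-centerline-point diameter record (all diameters in mm)."""

    points: np.ndarray  # (N, 3) voxel ZYX
    spacing: tuple[float, float, float]
    d_dt: np.ndarray  # NaN where missing
    d_rays: list[np.ndarray]  # per point, possibly empty
    d_raw: np.ndarray  # NaN where missing
    d_final: np.ndarray  # no NaN

    def __len__(self) -> int:
        return len(self.points)

    def arc_lengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0) * np.asarray(self.spacing), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def min_diameter_mm(self) -> float:
        return float(np.min(self.d_final))

    def to_dataframe(self) -> pd.DataFrame:
        med = np.array([np.median(r) if len(r) else np.nan for r in self.d_rays])
        return pd.DataFrame(
            {
                "k": np.arange(len(self)),
                "z": self.points[:, 0],
                "y": self.points[:, 1],
                "x": self.points[:, 2],
                "d_dt_mm": self.d_dt,
                "d_ray_median_mm": med,
                "d_raw_mm": self.d_raw,
                "d_final_mm": self.d_final,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _inside(mask_data: np.ndarray, vox: np.ndarray) -> bool:
    """Nearest-voxel foreground lookup; out-of-grid counts as background."""
    idx = np.rint(vox).astype(int)
    if (idx < 0).any() or (idx >= np.asarray(mask_data.shape)).any():
        return False
    return bool(mask_data[idx[0], idx[1], idx[2]])


def edt_diameter(mask: Volume, p, edt: np.ndarray | None = None) -> float:
    """Distance-transform diameter 2*EDT(p) in mm at voxel point ``p``.

    The EDT is computed with the physical spacing as sampling; at non-integer
    points it is sampled trilinearly. Returns NaN (missing) when the nearest
    voxel to ``p`` is background.
    """
    p = np.asarray(p, dtype=float)
    if not _inside(mask.data, p):
        return float("nan")
    if edt is None:
        edt = ndimage.distance_transform_edt(mask.data.astype(bool), sampling=mask.spacing)
    val = ndimage.map_coordinates(edt, p.reshape(3, 1), order=1, mode="nearest")[0]
    return float(2.0 * val)


def local_tangent(c: Centerline, k: int) -> np.ndarray:
    """Unit tangent (physical ZYX) at point k by finite differences.

    Central difference for interior points, one-sided at the ends; the
    stencil widens past coincident neighbours.
    """
    n = len(c)
    sp = np.asarray(c.spacing)
    lo, hi = max(k - 1, 0), min(k + 1, n - 1)
    d = (c.points[hi] - c.points[lo]) * sp
    while np.linalg.norm(d) == 0.0 and (lo > 0 or hi < n - 1):
        lo, hi = max(lo - 1, 0), min(hi + 1, n - 1)
        d = (c.points[hi] - c.points[lo]) * sp
    nrm = np.linalg.norm(d)
    if nrm == 0.0:
        raise ValueError("all centerline points coincide; tangent undefined")
    return d / nrm


def frisvad_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Branchless orthonormal basis completion from a unit vector.

    Treats the components of ``n`` as (x, y, z) of the published construction,
    including the z ~ -1 guard required for numerical stability.
    """
    x, y, z = float(n[0]), float(n[1]), float(n[2])
    if z < -0.9999999:
        return np.array([0.0, -1.0, 0.0]), np.array([-1.0, 0.0, 0.0])
    a = 1.0 / (1.0 + z)
    b = -x * y * a
    b1 = np.array([1.0 - x * x * a, b, -x])
    b2 = np.array([b, 1.0 - y * y * a, -y])
    return b1, b2


def orthonormal_frame(tangent: np.ndarray, theta_thresh_deg: float = 10.0) -> FramedPoint:
    """In-plane basis (u, v) orthogonal to the tangent.

    When the tangent is within ``theta_thresh_deg`` of the z-axis
    (|T.z| > cos(theta)), the YX slice plane is used (u = Y axis, v = X
    axis); otherwise the basis is completed with the Frisvad construction.
    """
    t = np.asarray(tangent, dtype=float)
    nrm = np.linalg.norm(t)
    if nrm == 0.0:
        raise ValueError("zero tangent vector")
    t = t / nrm
    if abs(t[0]) > np.cos(np.deg2rad(theta_thresh_deg)):
        u = np.array([0.0, 1.0, 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return FramedPoint(tangent=t, u=u, v=v, plane_mode="yx_slice")
    u, v = frisvad_basis(t)
    return FramedPoint(tangent=t, u=u, v=v, plane_mode="frisvad")


def _march_exit(
    mask_data: np.ndarray,
    spacing: np.ndarray,
    origin_phys: np.ndarray,
    direction: np.ndarray,
    step: float,
    max_len: float,
) -> np.ndarray | None:
    """First physical position along ``direction`` where the mask is exited.

    Samples every ``step`` mm with nearest-voxel lookup, then refines the
    boundary to sub-voxel accuracy by bisection between the last inside and
    first outside sample. Returns None when no exit is found within
    ``max_len`` mm.
    """
    ts = np.arange(step, max_len + step, step)
    pos = origin_phys[None, :] + ts[:, None] * direction[None, :]
    vox = np.rint(pos / spacing).astype(int)
    shape = np.asarray(mask_data.shape)
    in_bounds = ((vox >= 0) & (vox < shape)).all(axis=1)
    values = np.zeros(len(ts), dtype=bool)
    ib = np.flatnonzero(in_bounds)
    if len(ib):
        values[ib] = mask_data[vox[ib, 0], vox[ib, 1], vox[ib, 2]].astype(bool)
    outside = np.flatnonzero(~values)
    if len(outside) == 0:
        return None  # never exited within max_len
    first_out = int(outside[0])
    t_out = ts[first_out]
    t_in = ts[first_out - 1] if first_out > 0 else 0.0
    for _ in range(24):  # bisect to sub-voxel precision
        t_mid = 0.5 * (t_in + t_out)
        p_mid = origin_phys + t_mid * direction
        if _inside(mask_data, p_mid / spacing):
            t_in = t_mid
        else:
            t_out = t_mid
    t_exit = 0.5 * (t_in + t_out)
    return origin_phys + t_exit * direction


def cast_ray(
    mask: Volume,
    origin,
    direction,
    step: float | None = None,
    max_len: float | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Cast a ray in both directions from a voxel point inside the mask.

    Returns the exit points ``(B_plus, B_minus)`` in real voxel coordinates,
    or None (missing) when the origin is outside the mask or either exit is
    not found within ``max_len`` mm (default: half the volume diagonal).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    sp = np.asarray(mask.spacing)
    if not _inside(mask.data, origin):
        return None
    if step is None:
        step = 0.25 * float(sp.min())
    if max_len is None:
        max_len = 0.5 * float(np.linalg.norm(np.asarray(mask.shape) * sp))
    origin_phys = origin * sp
    b_plus = _march_exit(mask.data, sp, origin_phys, direction, step, max_len)
    b_minus = _march_exit(mask.data, sp, origin_phys, -direction, step, max_len)
    if b_plus is None or b_minus is None:
        return None
    return b_plus / sp, b_minus / sp


def ray_diameters(
    mask: Volume,
    fp: FramedPoint,
    n_rays: int = 8,
    step: float | None = None,
    max_len: float | None = None,
) -> np.ndarray:
    """Per-ray diameters (mm) for ``n_rays`` directions spanning the half-plane.

    Direction i is ``cos(i*pi/n_rays)*u + sin(i*pi/n_rays)*v``; the diameter
    is the spacing-weighted Euclidean norm of the exit-point difference.
    Missing rays are omitted, so the result may be shorter than ``n_rays``.
    """
    if n_rays < 2:
        raise ValueError(f"n_rays must be >= 2, got {n_rays}")
    if fp.point is None:
        raise ValueError("FramedPoint must carry its centerline point for ray casting")
    sp = np.asarray(mask.spacing)
    out = []
    for i in range(n_rays):
        ang = i * np.pi / n_rays
        d = np.cos(ang) * fp.u + np.sin(ang) * fp.v
        exits = cast_ray(mask, fp.point, d, step=step, max_len=max_len)
        if exits is None:
            continue
        b_plus, b_minus = exits
        out.append(float(np.linalg.norm((b_plus - b_minus) * sp)))
    return np.asarray(out, dtype=float)


def combined_diameter(d_dt: float, d_rays) -> float:
    """Hybrid raw diameter ``(D_DT + median(D_ray)) / 2``; NaN when either
    the distance-transform estimate is missing or no ray survived."""
    d_rays = np.asarray(d_rays, dtype=float)
    if not np.isfinite(d_dt) or len(d_rays) == 0:
        return float("nan")
    return float(0.5 * (d_dt + np.median(d_rays)))


def finalize_profile(raw, polyorder: int = 3, max_window: int = 51) -> np.ndarray:
    """Interpolate missing values and smooth the raw diameter profile.

    Interior NaNs are linearly interpolated over the point index; leading and
    trailing NaNs take the nearest valid value. A Savitzky-Golay filter of
    order ``polyorder`` is then applied with window
    ``min(max_window, largest odd <= N)``; smoothing is skipped when the
    window would not exceed the polynomial order. Negative smoothed values
    (possible near sharp steps) are clamped to the smallest positive raw
    value with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    valid = np.isfinite(raw)
    if valid.sum() < 2:
        raise ValueError("need at least 2 non-missing diameters to build a profile")
    idx = np.arange(n)
    filled = np.interp(idx, idx[valid], raw[valid])  # edges -> nearest valid
    window = min(max_window, n if n % 2 == 1 else n - 1)
    if window > polyorder:
        smoothed = savgol_filter(filled, window_length=window, polyorder=polyorder)
    else:
        smoothed = filled
    if (smoothed <= 0).any():
        floor = float(raw[valid][raw[valid] > 0].min())
        warnings.warn(
            "Savitzky-Golay smoothing produced non-positive diameters; "
            f"clamping to {floor:.3f} mm",
            RuntimeWarning,
            stacklevel=2,
        )
        smoothed = np.where(smoothed <= 0, floor, smoothed)
    return smoothed


def _correct_tangent_outliers(tangents: np.ndarray, max_angle_deg: float) -> np.ndarray:
    """Replace tangents that kink away from the local tangent field.

    Each tangent is compared with the normalized mean of its neighbours
    (window of 3 each side, excluding itself); deviations beyond
    ``max_angle_deg`` take the neighbour mean instead.
    """
    n = len(tangents)
    out = tangents.copy()
    cos_max = np.cos(np.deg2rad(max_angle_deg))
    for k in range(n):
        lo, hi = max(0, k - 3), min(n, k + 4)
        neigh = [tangents[j] for j in range(lo, hi) if j != k]
        if not neigh:
            continue
        ref = np.mean(neigh, axis=0)
        nrm = np.linalg.norm(ref)
        if nrm == 0:
            continue
        ref /= nrm
        if float(np.dot(out[k], ref)) < cos_max:
            out[k] = ref
    return out


def compute_profile(
    mask: Volume, c: Centerline, config: DiameterConfig | None = None
) -> DiameterProfile:
    """End-to-end diameter profile along an endpoint-corrected centerline."""
    if config is None:
        config = DiameterConfig()
    if c.stage != "endpoint_corrected":
        raise ValueError(
            f"compute_profile expects an endpoint_corrected centerline, got {c.stage!r}"
        )
    if not mask.is_binary():
        raise ValueError("compute_profile expects a binary mask")
    fg = mask.data.astype(bool)
    if config.cap_reject_angle_deg is not None:
        edt, nearest_bg = ndimage.distance_transform_edt(
            fg, sampling=mask.spacing, return_indices=True
        )
        cap_cos = np.cos(np.deg2rad(config.cap_reject_angle_deg))
    else:
        edt = ndimage.distance_transform_edt(fg, sampling=mask.spacing)
        nearest_bg = None
        cap_cos = None
    sp = np.asarray(mask.spacing)
    step = config.march_step_factor * float(min(mask.spacing))
    n = len(c)
    tangents = np.stack([local_tangent(c, k) for k in range(n)])
    if config.tangent_outlier_deg is not None:
        tangents = _correct_tangent_outliers(tangents, config.tangent_outlier_deg)
    d_dt = np.empty(n)
    d_rays: list[np.ndarray] = []
    d_raw = np.empty(n)
    for k in range(n):
        p = c.points[k]
        d_dt[k] = edt_diameter(mask, p, edt=edt)
        fp = orthonormal_frame(tangents[k], config.theta_thresh_deg)
        fp.point = p
        if nearest_bg is not None and np.isfinite(d_dt[k]):
            # reject EDT values that measure the vessel truncation cap
            pi = np.rint(p).astype(int)
            bg = nearest_bg[:, pi[0], pi[1], pi[2]].astype(float)
            to_bg = (bg - p) * sp
            nrm = np.linalg.norm(to_bg)
            if nrm > 0 and abs(float(np.dot(to_bg / nrm, fp.tangent))) > cap_cos:
                d_dt[k] = float("nan")
        rays = ray_diameters(mask, fp, n_rays=config.n_rays, step=step)
        d_rays.append(rays)
        d_raw[k] = combined_diameter(d_dt[k], rays)
    d_final = finalize_profile(d_raw, polyorder=config.sg_polyorder, max_window=config.sg_max_window)
    return DiameterProfile(
        points=c.points.copy(),
        spacing=c.spacing,
        d_dt=d_dt,
        d_rays=d_rays,
        d_raw=d_raw,
        d_final=d_final,
    )
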