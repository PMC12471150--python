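"""NIfTI volume ingestion and grid normalisation.

Every array inside this package is indexed ``(z, y, x)`` with ``z`` the
superior axis, and carries an explicit physical voxel spacing in millimetres.
Volumes are normalised to the RAS (Right-Anterior-Superior) world orientation
at load time, so downstream slice-wise operations (slice centre of mass,
YX-plane ray casting) can assume axis alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume", "load_volume", "save_volume", "resample_isotropic"]


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data
        3D array indexed (z, y, x). Binary {0, 1} for masks, [0, 1] reals for
        probability maps.
    spacing
        Physical voxel size in mm per axis, (z, y, x) order.
    axis_order, orientation
        Bookkeeping tags; after ingestion always ``"ZYX"`` / ``"RAS"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "ZYX"
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def foreground_volume_mm3(self) -> float:
        """Physical volume of the nonzero voxels (meaningful for masks)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3

    def astype_mask(self) -> "Volume":
        if not self.is_binary():
            raise ValueError("volume is not binary; cannot interpret as mask")
        return replace(self, data=self.data.astype(np.uint8))


def _is_axis_aligned(affine: np.ndarray, tol: float = 1e-4) -> bool:
    """True when each voxel axis maps onto a single world axis (pure
    permutation/flip/scale affine)."""
    rzs = affine[:3, :3]
    norms = np.linalg.norm(rzs, axis=0)
    unit = rzs / norms
    return bool((np.abs(np.abs(unit).max(axis=0) - 1.0) < tol).all())


def _resample_oblique_to_ras(
    data: np.ndarray, affine: np.ndarray, nearest: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an obliquely-gridded volume onto the nearest RAS-aligned grid.

    Returns data in (x, y, z) index order plus its RAS affine.
    """
    zooms = nib.affines.voxel_sizes(affine)
    shape = np.asarray(data.shape)
    corners = np.array(list(itertools.product(*[(0, n - 1) for n in shape])), dtype=float)
    world = nib.affines.apply_affine(affine, corners)
    lo, hi = world.min(axis=0), world.max(axis=0)

    # pick, for each world axis, the spacing of the input axis most aligned with it
    unit = affine[:3, :3] / zooms
    out_spacing = np.array([zooms[int(np.argmax(np.abs(unit[a])))] for a in range(3)])
    out_shape = np.maximum(np.floor((hi - lo) / out_spacing).astype(int) + 1, 1)

    out_affine = np.eye(4)
    out_affine[:3, :3] = np.diag(out_spacing)
    out_affine[:3, 3] = lo

    m = np.linalg.inv(affine) @ out_affine  # output ijk -> input ijk
    order = 0 if nearest else 1
    out = ndimage.affine_transform(
        np.asarray(data, dtype=float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=tuple(out_shape),
        order=order,
        mode="grid-constant",
        cval=0.0,
        prefilter=False,
    )
    return out, out_affine


def load_volume(path: str, nearest: bool | None = None) -> Volume:
    """Read a NIfTI volume, reorient to RAS and reindex to (z, y, x).

    Spacing is taken from the affine. Axis-aligned affines are handled by
    exact axis permutation/flips; oblique affines are resampled onto the
    nearest RAS-aligned grid (trilinear, or nearest-neighbour when the data
    is binary or ``nearest=True``).
    """
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    affine = img.affine
    if affine is None or not np.isfinite(affine).all():
        raise ValueError(f"NIfTI file {path!r} has a missing or non-finite affine")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"NIfTI file {path!r} has a singular affine")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path!r}, got shape {data.shape}")

    if nearest is None:
        nearest = bool(np.isin(np.unique(data), (0, 1)).all())

    if _is_axis_aligned(affine):
        ornt = nib.orientations.io_orientation(affine)
        data_xyz = nib.orientations.apply_orientation(data, ornt)
        zooms = nib.affines.voxel_sizes(affine)
        spacing_xyz = np.empty(3)
        for in_ax in range(3):
            spacing_xyz[int(ornt[in_ax, 0])] = zooms[in_ax]
    else:
        data_xyz, out_affine = _resample_oblique_to_ras(data, affine, nearest)
        spacing_xyz = np.diag(out_affine[:3, :3]).copy()
        if nearest:
            data_xyz = np.rint(data_xyz).astype(np.uint8)

    data_zyx = np.ascontiguousarray(data_xyz.transpose(2, 1, 0))
    spacing_zyx = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    return Volume(data=data_zyx, spacing=spacing_zyx)


def save_volume(v: Volume, path: str) -> None:
    """Write a Volume as NIfTI with an RAS-aligned diagonal affine."""
    data_xyz = np.ascontiguousarray(v.data.transpose(2, 1, 0))
    if data_xyz.dtype == bool:
        data_xyz = data_xyz.astype(np.uint8)
    affine = np.diag([v.spacing[2], v.spacing[1], v.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data_xyz, affine), path)


def resample_isotropic(v: Volume, target: float, mode: str = "trilinear") -> Volume:
    """Resample to isotropic ``target`` mm spacing.

    ``mode="trilinear"`` for images/probability maps, ``mode="nearest"`` for
    masks (preserves binarity). Grid cells are treated as extent-preserving
    boxes, so the physical field of view changes by less than one voxel.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    factors = [s / target for s in v.spacing]
    order = 0 if mode == "nearest" else 1
    data = v.data if order == 0 else np.asarray(v.data, dtype=np.float64)
    out = ndimage.zoom(
        data,
        zoom=factors,
        order=order,
        mode="nearest",  # edge samples clamp to the border voxel
        grid_mode=True,
        prefilter=False,
    )
    return Volume(data=out, spacing=(target, target, target))
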