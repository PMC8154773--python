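"""Volume containers, NIfTI/DICOM input-output and rigid resampling.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``values[i, j, k]`` with the first two axes in-plane
  and the third through-slice; indices are 0-based.
* Voxel ``(i, j, k)`` samples the world point ``origin + (i*dx, j*dy, k*dz)``
  (in mm) and covers the half-open box up to the next sample point.
* Rigid transforms are parameterised by three Euler angles in degrees
  (extrinsic x-y-z order) and three translations in mm, applied about an
  explicit center point in world coordinates.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


class VolumeError(ValueError):
    """Invalid volume data or geometry."""


class GridMismatchError(VolumeError):
    """Two objects that must share a grid do not."""


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar field with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeError(f"expected 3D data, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.values.dtype.kind == "f" and not np.all(np.isfinite(self.values)):
            raise VolumeError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinates of the geometric center of the sample grid."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def same_grid(self, other: "Volume3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_grid(self, other: "Volume3D") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.grid()} vs {other.grid()}"
            )

    def copy_with(self, values: np.ndarray) -> "Volume3D":
        return type(self)(values, self.spacing, self.origin)


class BinaryMask(Volume3D):
    """A boolean voxel mask sharing the grid of an owning volume."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise VolumeError("mask values must be boolean / {0,1}")
            self.values = self.values.astype(bool)
        super().__post_init__()

    @classmethod
    def like(cls, volume: Volume3D, values: np.ndarray) -> "BinaryMask":
        return cls(values, volume.spacing, volume.origin)

    @property
    def volume_cm3(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_mm3 / 1000.0


class WeightMap(Volume3D):
    """Per-voxel plate-likeness weight in [0, 1] (fascia evidence field)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < -1e-9 or vmax > 1 + 1e-9:
            raise VolumeError(f"weights must lie in [0,1], got [{vmin}, {vmax}]")


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform: extrinsic x-y-z Euler angles (deg) and
    translation (mm), applied about ``center_mm``:

        p' = R (p - c) + c + t
    """

    rotation_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_deg", tuple(float(a) for a in self.rotation_deg))
        object.__setattr__(self, "translation_mm", tuple(float(t) for t in self.translation_mm))
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))

    @staticmethod
    def identity(center_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), tuple(center_mm))

    def _rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix equivalent."""
        R = self._rotation().as_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    @classmethod
    def from_matrix(
        cls, M: np.ndarray, center_mm: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        R = np.asarray(M)[:3, :3]
        v = np.asarray(M)[:3, 3]
        c = np.asarray(center_mm, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = v - c + R @ c
        return cls(tuple(angles), tuple(t), tuple(c))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        R = self._rotation().as_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        R = self._rotation()
        Rinv = R.inv()
        t = np.asarray(self.translation_mm)
        angles = Rinv.as_euler("xyz", degrees=True)
        t_inv = -Rinv.as_matrix() @ t
        return RigidTransform(tuple(angles), tuple(t_inv), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``self`` first, then ``other``."""
        M = other.matrix() @ self.matrix()
        return RigidTransform.from_matrix(M, self.center_mm)


def transform_difference(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """Rotation magnitude (deg) and center displacement (mm) of a relative
    to b — (0, 0) iff the transforms act identically."""
    d = b.inverse().compose(a)
    rot = float(np.linalg.norm(Rotation.from_euler("xyz", d.rotation_deg, degrees=True).as_rotvec(degrees=True)))
    c = np.asarray(a.center_mm)
    trans = float(np.linalg.norm(d.apply(c)[0] - c))
    return rot, trans


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI file or a DICOM series directory into the internal
    axis convention. Axis flips/permutations in the file are resolved so
    that world coordinates of every voxel are preserved."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    import nibabel as nib

    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeError(f"expected a 3D volume, file has shape {img.shape}")
    if np.issubdtype(img.get_data_dtype(), np.complexfloating):
        raise VolumeError("complex-valued data is not supported")
    img = nib.as_closest_canonical(img)
    A = img.affine
    lin = A[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-4 * max(1.0, np.abs(lin).max())):
        raise VolumeError("oblique affines are not supported")
    spacing = tuple(np.diag(lin))
    if any(s <= 0 for s in spacing):
        raise VolumeError(f"non-positive spacing in affine: {spacing}")
    values = np.asarray(img.dataobj)
    return Volume3D(values, spacing, tuple(A[:3, 3]))


def _read_dicom_series(path: Path) -> Volume3D:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(path))
    if not names:
        raise VolumeError(f"no DICOM series found in {path}")
    reader.SetFileNames(names)
    img = reader.Execute()
    if img.GetDimension() != 3:
        raise VolumeError("expected a 3D DICOM series")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-3):
        raise VolumeError("non-axis-aligned DICOM series are not supported")
    # sitk arrays come back (z, y, x); transpose to (x, y, z)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume3D(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume (or mask, as uint8 {0,1}) as NIfTI-1."""
    import nibabel as nib

    values = volume.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    A = np.eye(4)
    A[:3, :3] = np.diag(volume.spacing)
    A[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(values, A), str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(v.values > 0.5, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(
    volume: Volume3D,
    transform: RigidTransform,
    target: Volume3D | tuple,
    mode: str | None = None,
    fill: float = 0.0,
) -> Volume3D:
    """Resample ``volume`` onto the grid of ``target``.

    The transform maps target-grid world points into the source volume's
    world space: ``out[x] = volume(T(x))``. Scalar volumes use linear
    interpolation, masks nearest-neighbour (overridable via ``mode``).
    Out-of-field voxels take ``fill``.
    """
    if isinstance(target, Volume3D):
        t_shape, t_spacing, t_origin = target.shape, target.spacing, target.origin
    else:
        t_shape, t_spacing, t_origin = target
    is_mask = isinstance(volume, BinaryMask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    order = 0 if mode == "nearest" else 1

    idx = np.indices(t_shape, dtype=float).reshape(3, -1).T
    world = np.asarray(t_origin) + idx * np.asarray(t_spacing)
    src = transform.apply(world)
    src_idx = (src - np.asarray(volume.origin)) / np.asarray(volume.spacing)

    values = volume.values.astype(np.uint8) if is_mask else np.asarray(volume.values, dtype=float)
    out = ndimage.map_coordinates(
        values, src_idx.T, order=order, mode="constant", cval=fill, prefilter=False
    ).reshape(t_shape)
    if is_mask:
        return BinaryMask(out > 0.5, t_spacing, t_origin)
    return Volume3D(out, t_spacing, t_origin)
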