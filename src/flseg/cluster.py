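"""Fuzzy c-means intensity clustering and morphological thigh/femur masks.

Step 1 of the pipeline: cluster T1w intensities into four tissue classes
(bone/background < fibrous < muscle < adipose, by ascending center), then
derive the thigh surface (skin removed) and the femur from the hardened
labels with in-plane morphology.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, Volume3D, VolumeError

TISSUE_NAMES = ("bone_background", "fibrous", "muscle", "adipose")


class DegenerateIntensityError(VolumeError):
    """Too few distinct intensities to cluster."""


class EmptyRegionError(VolumeError):
    """A required anatomical region could not be found."""


class FCMConvergenceWarning(UserWarning):
    pass


@dataclasses.dataclass
class MembershipMap:
    """Fuzzy memberships (one channel per cluster, ascending center)."""

    memberships: np.ndarray  # (k, nx, ny, nz) float32, zero outside mask
    centers: np.ndarray  # ascending intensities
    m: float
    mask: BinaryMask
    converged: bool
    n_iter: int
    objective: np.ndarray  # per-iteration FCM objective

    @property
    def k(self) -> int:
        return len(self.centers)


@dataclasses.dataclass
class TissueLabelMap:
    """Hardened per-voxel labels; index i corresponds to ``names[i]``."""

    labels: np.ndarray  # uint8, full grid (0 == bone/background outside mask)
    centers: np.ndarray  # ascending
    names: tuple[str, ...]
    mask: BinaryMask

    def tissue(self, name: str) -> np.ndarray:
        return self.labels == self.names.index(name)


def _membership_update(d: np.ndarray, m: float) -> np.ndarray:
    """u_ik = [sum_j (d_ik / d_jk)^(2/(m-1))]^-1, with exact-center voxels
    assigned full membership at their center(s)."""
    p = 2.0 / (m - 1.0)
    zero = d < 1e-12
    with np.errstate(divide="ignore"):
        w = d ** (-p)
    u = w / w.sum(axis=1, keepdims=True)
    rows = zero.any(axis=1)
    if rows.any():
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return u


def fcm(
    volume: Volume3D,
    mask: BinaryMask,
    k: int = 4,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = None,
) -> MembershipMap:
    """Scalar-intensity fuzzy c-means.

    Centers are initialized at fixed intensity percentiles of the mask, so
    the result is deterministic; ``seed`` is accepted for interface
    stability but unused. ``tol`` is relative to the intensity range.
    """
    volume.require_same_grid(mask)
    x = volume.values[mask.values].astype(float)
    if np.unique(x).size < k:
        raise DegenerateIntensityError(
            f"mask holds fewer than k={k} distinct intensities"
        )
    rng_span = float(np.ptp(x))
    centers = np.percentile(x, np.linspace(5, 95, k))
    objective = []
    converged = False
    u = None
    it = 0
    for it in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centers[None, :])
        u = _membership_update(d, m)
        um = u**m
        objective.append(float((um * d**2).sum()))
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers)) / rng_span
        centers = new_centers
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"FCM did not converge in {max_iter} iterations", FCMConvergenceWarning)
    # final memberships for the converged centers, sorted ascending
    d = np.abs(x[:, None] - centers[None, :])
    u = _membership_update(d, m)
    order = np.argsort(centers)
    centers = centers[order]
    u = u[:, order]

    full = np.zeros((k,) + volume.shape, dtype=np.float32)
    for i in range(k):
        chan = np.zeros(volume.shape, dtype=np.float32)
        chan[mask.values] = u[:, i]
        full[i] = chan
    return MembershipMap(
        memberships=full,
        centers=centers,
        m=m,
        mask=mask,
        converged=converged,
        n_iter=it,
        objective=np.asarray(objective),
    )


def harden(members: MembershipMap) -> TissueLabelMap:
    """Argmax labels with tissue names assigned by ascending center
    intensity; ties break toward the lower-intensity cluster. The result is
    invariant to any permutation of the input cluster channels."""
    order = np.argsort(members.centers)
    centers = members.centers[order]
    mem = members.memberships[order]
    labels = np.argmax(mem, axis=0).astype(np.uint8)
    labels[~members.mask.values] = 0
    names = TISSUE_NAMES if len(centers) == 4 else tuple(
        f"cluster_{i}" for i in range(len(centers))
    )
    return TissueLabelMap(labels=labels, centers=centers, names=names, mask=members.mask)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _disk_2d(radius: int) -> np.ndarray:
    from skimage.morphology import disk

    return disk(radius)[:, :, None].astype(bool)


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        raise EmptyRegionError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _fill_slices(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for z in range(out.shape[2]):
        out[:, :, z] = ndimage.binary_fill_holes(out[:, :, z])
    return out


def thigh_surface(
    labels: TissueLabelMap,
    volume: Volume3D,
    skin_thickness_vox: int = 2,
    closing_radius: int = 2,
) -> BinaryMask:
    """Thigh mask from the bone/background cluster: everything that is not
    border-connected background, closed per slice, largest 3D component,
    with a bright outer rind (skin) of the declared thickness removed."""
    bg = labels.tissue("bone_background") | ~labels.mask.values
    lab, _ = ndimage.label(bg)
    border = np.unique(
        np.concatenate(
            [lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(), lab[:, -1].ravel()]
        )
    )
    border = border[border > 0]
    air = np.isin(lab, border)
    fg = ~air
    if not fg.any():
        raise EmptyRegionError("no foreground component (empty thigh)")
    fg = ndimage.binary_closing(fg, structure=_disk_2d(closing_radius))
    fg = _fill_slices(fg)
    fg = _largest_cc(fg)
    # skin removal: outer rind above the muscle/adipose midpoint intensity
    eroded = ndimage.binary_erosion(fg, structure=_disk_2d(skin_thickness_vox))
    rind = fg & ~eroded
    skin_thr = 0.5 * (labels.centers[2] + labels.centers[3])
    fg &= ~(rind & (volume.values > skin_thr))
    fg = _fill_slices(fg)
    fg = _largest_cc(fg)
    return BinaryMask.like(volume, fg)


def segment_femur(
    labels: TissueLabelMap,
    thigh: BinaryMask,
    min_size_vox: int = 30,
) -> BinaryMask:
    """Interior bone component nearest the thigh centroid, closed per slice
    to include the marrow; fully contained in the thigh."""
    interior = ndimage.binary_erosion(thigh.values, structure=_disk_2d(2))
    bone = labels.tissue("bone_background") & interior
    lab, n = ndimage.label(bone)
    if n == 0:
        raise EmptyRegionError("no interior bone component (femur not found)")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size_vox) + 1
    if keep.size == 0:
        raise EmptyRegionError("no interior bone component large enough for a femur")
    thigh_centroid = np.array(ndimage.center_of_mass(thigh.values))
    cents = np.array(ndimage.center_of_mass(bone, lab, index=keep))
    spacing = np.asarray(thigh.spacing)
    dists = np.linalg.norm((cents - thigh_centroid) * spacing, axis=1)
    femur = lab == keep[int(np.argmin(dists))]
    femur = _fill_slices(femur)
    femur = ndimage.binary_closing(femur, structure=_disk_2d(2))
    femur = _fill_slices(femur)
    femur &= interior
    return BinaryMask.like(thigh, femur)
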