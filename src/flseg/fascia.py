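"""Plate-likeness filtering of the fibrous cluster and the fascia lata
surface.

The fascia lata is a thin dark sheet inside bright SAT. Candidate voxels
(fibrous cluster, outside the muscle envelope) are scored with a
Frangi-style sheetness built from scale-normalized Hessian eigenvalues; a
second contractive level set, locked open inside the muscle envelope, then
shrinks from the thigh surface and settles on the closed weighted sheet,
yielding the intra-fascia (IF) volume of interest. Open fascia-like
fragments (e.g. the saphenous fascia arc) do not enclose the muscle
ensemble, so the front passes around them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .envelope import LevelSetParams, morph_gac
from .volio import BinaryMask, Volume3D, VolumeError, WeightMap


@dataclasses.dataclass
class EigenField:
    """Hessian eigenvalues per voxel, ordered |l1| <= |l2| <= |l3|."""

    lam: np.ndarray  # (3, nx, ny, nz)
    sigma_mm: float
    spacing: tuple[float, float, float]


@dataclasses.dataclass
class FasciaSurface:
    if_voi: BinaryMask
    contours: dict[int, list[np.ndarray]]  # slice -> ordered (N, 2) vertex arrays
    fallback: bool  # True when the front collapsed onto the envelope
    info: dict


def hessian_eigen(
    volume: Volume3D,
    sigma_mm: float,
    z_downweight: bool = True,
) -> EigenField:
    """Scale-normalized (gamma=1, factor sigma^2) Hessian eigenvalues of the
    Gaussian-smoothed volume, derivatives taken in mm.

    Through-slice derivative entries are down-weighted by the in-plane/slice
    spacing ratio because thick slices undersample the sheet.
    """
    dx, dy, dz = volume.spacing
    if sigma_mm < max(dx, dy) - 1e-9:
        raise VolumeError(
            f"sigma {sigma_mm} mm is below the in-plane spacing {max(dx, dy)} mm"
        )
    spacing = np.array([dx, dy, dz])
    sm = ndimage.gaussian_filter(np.asarray(volume.values, dtype=float), sigma=sigma_mm / spacing)
    g = np.gradient(sm, *spacing)
    H = np.empty(volume.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(g[i], *spacing)
        for j in range(3):
            H[..., i, j] = gi[j]
    H = 0.5 * (H + np.swapaxes(H, -1, -2))
    if z_downweight:
        rho = max(dx, dy) / dz
        H[..., 0, 2] *= rho
        H[..., 2, 0] *= rho
        H[..., 1, 2] *= rho
        H[..., 2, 1] *= rho
        H[..., 2, 2] *= rho * rho
    H *= sigma_mm**2
    lam = np.linalg.eigvalsh(H.reshape(-1, 3, 3))
    order = np.argsort(np.abs(lam), axis=1)
    lam = np.take_along_axis(lam, order, axis=1)
    lam = lam.T.reshape((3,) + volume.shape)
    return EigenField(lam=lam, sigma_mm=sigma_mm, spacing=volume.spacing)


def plate_weight(
    eig: EigenField | Sequence[EigenField],
    fibrous: BinaryMask,
    me: BinaryMask,
    alpha: float = 0.5,
    beta: float = 0.5,
    c: float | None = None,
) -> WeightMap:
    """Sheetness in [0, 1] for dark plates on bright background.

    weight = exp(-R_sheet^2/2a^2) * exp(-R_blob^2/2b^2) * (1 - exp(-S^2/2c^2))
    with R_sheet = |l2|/|l3|, R_blob = |l1|/sqrt(|l2 l3|), S the Frobenius
    eigen-norm; zero where l3 <= 0 (bright plates) and outside
    fibrous-and-not-envelope. Multiple scales are combined by the maximum;
    ``c=None`` adapts per scale to a quarter of the maximum S over the
    support, so the strongest sheet responses saturate near weight 1 while
    weak unstructured responses are suppressed.
    """
    fibrous.require_same_grid(me)
    eigs = [eig] if isinstance(eig, EigenField) else list(eig)
    support = fibrous.values & ~me.values
    w_best = np.zeros(fibrous.shape)
    for e in eigs:
        l1, l2, l3 = e.lam
        a1, a2, a3 = np.abs(l1), np.abs(l2), np.abs(l3)
        S = np.sqrt(l1**2 + l2**2 + l3**2)
        if c is None:
            s_max = float(S[support].max()) if support.any() else 0.0
            c_s = 0.25 * s_max
        else:
            c_s = c
        with np.errstate(divide="ignore", invalid="ignore"):
            r_sheet = np.where(a3 > 1e-12, a2 / np.maximum(a3, 1e-30), 0.0)
            prod = a2 * a3
            r_blob = np.where(prod > 1e-24, a1 / np.sqrt(np.maximum(prod, 1e-30)), 0.0)
        if c_s > 0:
            structure = 1.0 - np.exp(-(S**2) / (2 * c_s**2))
        else:
            structure = np.zeros_like(S)
        w = (
            np.exp(-(r_sheet**2) / (2 * alpha**2))
            * np.exp(-(r_blob**2) / (2 * beta**2))
            * structure
        )
        w[l3 <= 0] = 0.0
        w_best = np.maximum(w_best, w)
    w_best[~support] = 0.0
    return WeightMap(np.clip(w_best, 0.0, 1.0), fibrous.spacing, fibrous.origin)


def fl_surface(
    me: BinaryMask,
    weights: WeightMap,
    thigh: BinaryMask,
    params: LevelSetParams | None = None,
) -> FasciaSurface:
    """Second level set: shrink from the thigh surface with edge map
    g = 1 - weight, locked open inside the muscle envelope. Returns the
    intra-fascia region (ME subset IF subset thigh) and its per-slice
    boundary contours. With no fascia evidence the front collapses onto the
    envelope; that degenerate case returns IF = ME with ``fallback=True``.
    """
    from skimage import measure

    params = params or LevelSetParams(threshold=0.35, edge_floor=0.1)
    me.require_same_grid(thigh)
    me.require_same_grid(weights)
    # in-plane grey max-filter bridges single-voxel holes in the weighted
    # sheet so the contracting front cannot slip through them
    w = ndimage.maximum_filter(np.asarray(weights.values, dtype=float), size=(3, 3, 1))
    g = np.clip(1.0 - w, 0.0, 1.0)
    u, info = morph_gac(
        g, thigh.values, params, domain=thigh.values, freeze=me.values
    )
    fallback = not (u & ~me.values).any()
    if fallback:
        u = me.values.copy()
    else:
        lab, n = ndimage.label(u)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            u = lab == (1 + int(np.argmax(sizes)))
            u |= me.values
        for z in range(u.shape[2]):
            u[:, :, z] = ndimage.binary_fill_holes(u[:, :, z])
    if_voi = BinaryMask.like(thigh, u)
    contours: dict[int, list[np.ndarray]] = {}
    for z in range(u.shape[2]):
        cs = measure.find_contours(u[:, :, z].astype(float), 0.5)
        contours[z] = [np.asarray(ci) for ci in cs]
    return FasciaSurface(if_voi=if_voi, contours=contours, fallback=fallback, info=info)
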