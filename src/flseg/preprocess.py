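"""Multiplicative intensity-inhomogeneity (bias field) correction.

The scanner bias is modelled as ``exp(P(x, y, z))`` with P a low-order
polynomial over normalized coordinates — strictly positive by construction.
The fit alternates a coarse k-means tissue assignment on log intensity with
a least-squares polynomial fit of the log residuals, until the incremental
field change falls below tolerance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .volio import BinaryMask, Volume3D, VolumeError


class BiasCorrectionWarning(UserWarning):
    pass


@dataclasses.dataclass
class BiasModel:
    order: int
    coeffs: np.ndarray  # log-domain coefficients per monomial (n_terms,)
    exponents: np.ndarray  # (n_terms, 3) monomial powers
    field: np.ndarray  # evaluated multiplicative field, mean 1 over the mask
    mask: BinaryMask
    converged: bool
    n_iter: int


def _monomial_exponents(order: int) -> np.ndarray:
    exps = [
        (i, j, k)
        for i in range(order + 1)
        for j in range(order + 1)
        for k in range(order + 1)
        if 0 < i + j + k <= order
    ]
    return np.asarray(exps, dtype=int)


def _design(coords: np.ndarray, exponents: np.ndarray) -> np.ndarray:
    # coords (n, 3) in [-1, 1]
    return np.prod(coords[:, None, :] ** exponents[None, :, :], axis=2)


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Deterministic 1D k-means (percentile init); returns class centers
    indexed by the per-sample assignment."""
    centers = np.percentile(x, np.linspace(5, 95, k))
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for i in range(k):
            sel = assign == i
            if sel.any():
                new[i] = x[sel].mean()
        if np.max(np.abs(new - centers)) < 1e-9 * max(np.ptp(x), 1e-12):
            centers = new
            break
        centers = new
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return centers[assign]


def correct_bias(
    volume: Volume3D,
    mask: BinaryMask,
    order: int = 3,
    n_classes: int = 6,
    tol: float = 1e-3,
    max_iter: int = 20,
    subsample: int = 3,
) -> tuple[Volume3D, BiasModel]:
    """Estimate and divide out a smooth multiplicative field.

    The returned field has mean 1 over ``mask``; the corrected volume is
    ``input / field``. Voxels darker than 2% of the bright-intensity
    reference (bone cortex, residual air) carry no multiplicative
    information on a log scale and are excluded from the fit, though the
    field is applied everywhere. Non-convergence returns the last iterate
    and raises a ``BiasCorrectionWarning``.
    """
    volume.require_same_grid(mask)
    if not mask.values.any():
        raise VolumeError("bias correction requires a non-empty mask")
    if order < 1:
        raise VolumeError("polynomial order must be >= 1")

    nx, ny, nz = volume.shape
    grids = [np.linspace(-1, 1, n) for n in (nx, ny, nz)]
    Xn, Yn, Zn = np.meshgrid(*grids, indexing="ij")
    exps = _monomial_exponents(order)

    all_vals = volume.values[mask.values].astype(float)
    bright_ref = float(np.percentile(all_vals, 99))
    fit_mask = mask.values & (volume.values > 0.02 * bright_ref)
    if not fit_mask.any():
        raise VolumeError("no voxels bright enough for a log-domain bias fit")
    coords_full = np.stack([Xn[fit_mask], Yn[fit_mask], Zn[fit_mask]], axis=1)

    vals = volume.values[fit_mask].astype(float)
    floor = max(1e-6, 1e-6 * float(vals.max()))
    logI = np.log(np.clip(vals, floor, None))

    fit_sel = slice(None, None, max(1, subsample))
    A_fit = _design(coords_full[fit_sel], exps)
    A_mask = _design(coords_full, exps)

    coeffs = np.zeros(len(exps))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = logI[fit_sel] - _kmeans_1d(logI[fit_sel], n_classes)
        c_step, *_ = np.linalg.lstsq(A_fit, resid, rcond=None)
        delta_mask = A_mask @ c_step
        delta_mask -= delta_mask.mean()
        # RMS relative change of the multiplicative field over the mask
        change = float(np.sqrt(np.mean(np.expm1(delta_mask) ** 2)))
        coeffs += c_step
        total = A_mask @ coeffs
        logI = np.log(np.clip(vals, floor, None)) - (total - total.mean())
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"bias correction did not converge in {max_iter} iterations",
            BiasCorrectionWarning,
        )

    # evaluate the accumulated log-field on the full grid
    coords_all = np.stack([Xn.ravel(), Yn.ravel(), Zn.ravel()], axis=1)
    log_field = (_design(coords_all, exps) @ coeffs).reshape(volume.shape)
    field = np.exp(log_field)
    field /= field[mask.values].mean()
    corrected = volume.copy_with(volume.values / field)
    model = BiasModel(
        order=order,
        coeffs=coeffs,
        exponents=exps,
        field=field,
        mask=mask,
        converged=converged,
        n_iter=it,
    )
    return corrected, model


def foreground_mask(volume: Volume3D) -> BinaryMask:
    """Rough body mask (Otsu threshold + largest component + per-slice hole
    fill) used to seed the bias fit before any tissue segmentation exists."""
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(volume.values)
    # Otsu on a thigh stack separates muscle-and-brighter from air; relax it
    # toward zero so dark tissue (fibrous) stays inside the mask
    fg = volume.values > 0.35 * thr
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3, 1), dtype=bool))
    lab, n = ndimage.label(fg)
    if n == 0:
        raise VolumeError("no foreground found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    fg = lab == (1 + int(np.argmax(sizes)))
    for k in range(fg.shape[2]):
        fg[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    return BinaryMask.like(volume, fg)
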