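"""IMAT volume, T1w-to-Dixon rigid registration, muscle-tissue threshold
and fat fraction of muscle tissue.

FF maps encode proton-density fat fraction on a 0-1000 intensity scale
(FF% = intensity / 10). IMAT is the summed adipose-cluster volume inside a
region of interest (intra-fascia VOI or muscle envelope), femur excluded.
Muscle tissue on the FF grid is separated from adipose tissue at the
minimum of the log-scaled FF histogram inside the IF VOI.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize
from scipy.signal import find_peaks

from .cluster import TissueLabelMap
from .volio import BinaryMask, RigidTransform, Volume3D, VolumeError

#: intensity units per FF percent on the scanner scale (0-1000 == 0-100%)
FF_UNITS_PER_PERCENT = 10.0


def ff_to_percent(intensity):
    """Convert FF-map intensity (0-1000) to fat fraction in percent."""
    return np.asarray(intensity, dtype=float) / FF_UNITS_PER_PERCENT


@dataclasses.dataclass
class MTThreshold:
    """Muscle/adipose separation threshold on the 0-1000 FF scale."""

    value: float
    fallback: bool  # True when the histogram was unimodal (value = 500)


@dataclasses.dataclass
class QuantReport:
    volume_total_cm3: float
    imat_fl_cm3: float
    imat_me_cm3: float
    slices_analyzed: int
    ff_mt_pct: float | None = None
    mt_threshold: float | None = None
    mt_threshold_fallback: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def delta_imat_cm3(self) -> float:
        return self.imat_fl_cm3 - self.imat_me_cm3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_imat_cm3"] = self.delta_imat_cm3
        d["warnings"] = list(self.warnings)
        return d


def trim_slices(mask: BinaryMask, n: int = 3) -> BinaryMask:
    """Zero the first and last ``n`` slices (edge slices are unreliable)."""
    nz = mask.shape[2]
    if n < 0:
        raise VolumeError("n must be >= 0")
    if n > 0 and nz <= 2 * n:
        raise VolumeError(f"stack of {nz} slices too short to trim {n} from each end")
    out = mask.values.copy()
    if n > 0:
        out[:, :, :n] = False
        out[:, :, -n:] = False
    return BinaryMask.like(mask, out)


def imat_volume(
    labels: TissueLabelMap,
    region: BinaryMask,
    femur: BinaryMask | None = None,
) -> float:
    """Adipose-cluster volume (cm^3) inside ``region`` minus the femur."""
    labels.mask.require_same_grid(region)
    sel = labels.tissue("adipose") & region.values
    if femur is not None:
        region.require_same_grid(femur)
        sel &= ~femur.values
    return float(sel.sum()) * region.voxel_volume_mm3 / 1000.0


def region_volume(region: BinaryMask, femur: BinaryMask | None = None) -> float:
    sel = region.values
    if femur is not None:
        region.require_same_grid(femur)
        sel = sel & ~femur.values
    return float(sel.sum()) * region.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Rigid registration (masked mutual information, gradient-free)
# ---------------------------------------------------------------------------

def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    h, _, _ = np.histogram2d(a, b, bins=bins)
    return _mi_from_joint(h)


def _mi_from_joint(h: np.ndarray) -> float:
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px[:, None] * py[None, :])[nz])).sum())


def _bin_index(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    scale = (bins - 1e-6) / max(hi - lo, 1e-12)
    return np.clip(((values - lo) * scale).astype(np.int32), 0, bins - 1)


_CORNERS = [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]


def _neg_mi_pv(
    src: np.ndarray,
    f_bin: np.ndarray,
    m_bin_vol: np.ndarray,
    m_mask: np.ndarray | None,
    bins: int,
) -> float:
    """Negative MI with partial-volume joint-histogram accumulation: each
    sample distributes trilinear weights over the moving volume's eight
    neighbouring voxel bins instead of interpolating intensities — the
    resulting metric has no grid-aligned interpolation bias."""
    shape = m_bin_vol.shape
    fl = np.floor(src).astype(np.int32)
    valid = np.all(fl >= 0, axis=1)
    for ax in range(3):
        valid &= fl[:, ax] < shape[ax] - 1
    if m_mask is not None:
        near = np.clip(np.rint(src).astype(np.int32), 0, np.asarray(shape) - 1)
        valid &= m_mask[near[:, 0], near[:, 1], near[:, 2]]
    if valid.sum() < 50:
        return 0.0
    fl = fl[valid]
    frac = src[valid] - fl
    fb = f_bin[valid].astype(np.int64)
    h = np.zeros(bins * bins)
    for ci, cj, ck in _CORNERS:
        w = (
            (frac[:, 0] if ci else 1.0 - frac[:, 0])
            * (frac[:, 1] if cj else 1.0 - frac[:, 1])
            * (frac[:, 2] if ck else 1.0 - frac[:, 2])
        )
        mb = m_bin_vol[fl[:, 0] + ci, fl[:, 1] + cj, fl[:, 2] + ck].astype(np.int64)
        h += np.bincount(fb * bins + mb, weights=w, minlength=bins * bins)
    return -_mi_from_joint(h.reshape(bins, bins))


class RegistrationError(VolumeError):
    pass


def register_rigid(
    fixed: Volume3D,
    fixed_mask: BinaryMask,
    moving: Volume3D,
    moving_mask: BinaryMask | None = None,
    bins: int = 32,
    levels: tuple[tuple[tuple[float, float, float], int, float], ...] = (
        ((2.0, 2.0, 3.0), 4, 1e-3),
        ((1.0, 1.0, 2.0), 3, 1e-3),
        ((0.4, 0.4, 1.5), 2, 1e-4),
    ),
) -> RigidTransform:
    """6-DOF transform mapping fixed-grid world points into the moving
    volume's space, maximizing histogram mutual information inside the
    masks. Multi-resolution (per-axis smoothing sigma in mm, sample stride,
    Powell xtol) refinement from a mask-centroid translation init;
    deterministic.
    The through-slice sigma stays at about half the slice thickness even at
    the finest level: thick slices undersample the anatomy in z and an
    unsmoothed metric is biased for the out-of-plane parameters.
    """
    fixed.require_same_grid(fixed_mask)
    if moving_mask is not None:
        moving.require_same_grid(moving_mask)
    if not fixed_mask.values.any():
        raise RegistrationError("empty fixed mask")
    if moving_mask is not None and not moving_mask.values.any():
        raise RegistrationError("empty moving mask")

    center = fixed.center_mm
    f_idx = np.argwhere(fixed_mask.values)
    f_pts_all = fixed.voxel_to_world(f_idx)
    # deterministic sub-voxel jitter of the sample planes along z: with
    # equal slice thickness in both stacks, grid-coincident sampling pulls
    # the z-translation toward alignment (the partial-volume artifact);
    # off-grid samples decorrelate it
    jit = np.random.default_rng(0).uniform(-0.5, 0.5, len(f_pts_all))
    f_pts_all = f_pts_all + np.stack(
        [np.zeros_like(jit), np.zeros_like(jit), jit * fixed.spacing[2]], axis=1
    )

    cf = f_pts_all.mean(axis=0)
    if moving_mask is not None:
        cm = moving.voxel_to_world(np.argwhere(moving_mask.values)).mean(axis=0)
    else:
        cm = moving.center_mm
    p = np.array([0.0, 0.0, 0.0, *(cm - cf)])

    m_spacing = np.asarray(moving.spacing)
    m_origin = np.asarray(moving.origin)

    f_spacing = np.asarray(fixed.spacing)
    f_origin = np.asarray(fixed.origin)
    for sigma_mm, stride, xtol in levels:
        sig = np.asarray(sigma_mm, dtype=float) * np.ones(3)
        if np.any(sig > 0):
            f_sm = ndimage.gaussian_filter(fixed.values.astype(float), sig / f_spacing)
            m_sm = ndimage.gaussian_filter(moving.values.astype(float), sig / m_spacing)
        else:
            f_sm = np.asarray(fixed.values, dtype=float)
            m_sm = np.asarray(moving.values, dtype=float)
        pts = f_pts_all[::stride]
        f_vox = ((pts - f_origin) / f_spacing).T
        f_vals = ndimage.map_coordinates(f_sm, f_vox, order=1, mode="nearest")
        f_bin = _bin_index(f_vals, bins)
        m_bin_vol = _bin_index(m_sm, bins)
        m_mask = moving_mask.values if moving_mask is not None else None

        def neg_mi(q, pts=pts, f_bin=f_bin, m_bin_vol=m_bin_vol, m_mask=m_mask):
            T = RigidTransform(tuple(q[:3]), tuple(q[3:]), tuple(center))
            src = (T.apply(pts) - m_origin) / m_spacing
            return _neg_mi_pv(src, f_bin, m_bin_vol, m_mask, bins)

        res = optimize.minimize(
            neg_mi,
            p,
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-8, "maxiter": 25},
        )
        if not np.all(np.isfinite(res.x)):
            raise RegistrationError(f"optimizer diverged: {res.message}")
        p = res.x
    return RigidTransform(tuple(p[:3]), tuple(p[3:]), tuple(center))


# ---------------------------------------------------------------------------
# Muscle-tissue threshold and FF_MT
# ---------------------------------------------------------------------------

def mt_threshold(
    ff: Volume3D,
    if_voi: BinaryMask,
    bin_width: float = 10.0,
    smooth_window: int = 5,
) -> MTThreshold:
    """Threshold separating muscle from adipose tissue: the minimum of the
    log-scaled, moving-average-smoothed FF histogram inside the IF VOI,
    between its two highest-prominence modes. A unimodal histogram returns
    the fallback value 500 with ``fallback=True``."""
    ff.require_same_grid(if_voi)
    vals = ff.values[if_voi.values]
    if vals.size == 0:
        raise VolumeError("empty IF VOI on the FF grid")
    edges = np.arange(0.0, 1000.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(vals, 0, 1000), bins=edges)
    logc = np.log1p(counts.astype(float))
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(logc, kernel, mode="same")
    peaks, props = find_peaks(sm, prominence=1e-9)
    if len(peaks) < 2:
        return MTThreshold(value=500.0, fallback=True)
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    between = sm[lo : hi + 1]
    # middle of the minimal plateau: with well-separated modes the count
    # floor spans many bins and the density valley lies at its center
    at_min = np.flatnonzero(between <= between.min() + 1e-12)
    valley = lo + int(round(0.5 * (at_min[0] + at_min[-1])))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return MTThreshold(value=float(centers[valley]), fallback=False)


def muscle_tissue_mask(
    ff: Volume3D,
    if_voi: BinaryMask,
    threshold: float,
    femur: BinaryMask | None = None,
) -> BinaryMask:
    """MT = IF voxels (femur excluded) with FF strictly below the threshold."""
    ff.require_same_grid(if_voi)
    sel = if_voi.values & (ff.values < threshold)
    if femur is not None:
        sel &= ~femur.values
    return BinaryMask.like(if_voi, sel)


def ff_mt(ff: Volume3D, mt_mask: BinaryMask) -> float:
    """Mean fat fraction over the muscle-tissue mask, in percent."""
    ff.require_same_grid(mt_mask)
    vals = ff.values[mt_mask.values]
    if vals.size == 0:
        raise VolumeError("empty muscle-tissue mask")
    return float(ff_to_percent(vals.mean()))


def ff_thigh_mask(ff: Volume3D, min_intensity: float = 30.0) -> BinaryMask:
    """Rough thigh mask on the FF grid (every tissue class exceeds the air
    noise floor): threshold, in-plane opening, largest component, per-slice
    hole fill."""
    fg = ff.values > min_intensity
    fg = ndimage.binary_opening(fg, structure=np.ones((3, 3, 1), dtype=bool))
    fg = ndimage.binary_closing(fg, structure=np.ones((5, 5, 1), dtype=bool))
    lab, n = ndimage.label(fg)
    if n == 0:
        raise VolumeError("no foreground on the FF grid")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    fg = lab == (1 + int(np.argmax(sizes)))
    for z in range(fg.shape[2]):
        fg[:, :, z] = ndimage.binary_fill_holes(fg[:, :, z])
    return BinaryMask.like(ff, fg)
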