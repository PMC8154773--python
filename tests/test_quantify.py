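"""IMAT volumes, slice trimming, FF thresholding and rigid registration."""

import dataclasses

import numpy as np
import pytest

import flseg
from flseg.cluster import TISSUE_NAMES, TissueLabelMap
from flseg.quantify import (
    MTThreshold,
    ff_mt,
    ff_to_percent,
    ff_thigh_mask,
    imat_volume,
    mt_threshold,
    muscle_tissue_mask,
    register_rigid,
    region_volume,
    trim_slices,
)
from flseg.volio import BinaryMask, Volume3D, VolumeError


def labels_from(arr, spacing=(0.5, 0.5, 3.0)):
    arr = np.asarray(arr, dtype=np.uint8)
    mask = BinaryMask(np.ones(arr.shape, dtype=bool), spacing)
    return TissueLabelMap(arr, np.array([0.0, 150.0, 400.0, 800.0]), TISSUE_NAMES, mask)


class TestFFScale:
    def test_full_scale_is_hundred_percent(self):
        assert ff_to_percent(1000) == 100.0

    def test_zero_is_zero_percent(self):
        assert ff_to_percent(0) == 0.0


class TestTrim:
    def mask(self, nz=34):
        return BinaryMask(np.ones((4, 4, nz), dtype=bool), (0.5, 0.5, 3.0))

    def test_paper_stack_keeps_28_slices(self):
        out = trim_slices(self.mask(34), n=3)
        kept = np.flatnonzero(out.values.any(axis=(0, 1)))
        assert len(kept) == 28

    def test_zero_trim_is_identity(self):
        out = trim_slices(self.mask(6), n=0)
        np.testing.assert_array_equal(out.values, self.mask(6).values)

    def test_short_stack_rejected(self):
        with pytest.raises(VolumeError):
            trim_slices(self.mask(6), n=3)


class TestImatVolume:
    def test_no_adipose_gives_zero(self):
        labels = labels_from(np.full((4, 4, 4), 2))
        region = BinaryMask(np.ones((4, 4, 4), dtype=bool), (0.5, 0.5, 3.0))
        assert imat_volume(labels, region) == 0.0

    def test_thousand_voxels_at_paper_spacing(self):
        arr = np.full((10, 10, 10), 2, dtype=np.uint8)
        arr.flat[:1000] = 3  # adipose
        labels = labels_from(arr)
        region = BinaryMask(np.ones(arr.shape, dtype=bool), (0.5, 0.5, 3.0))
        # 1000 voxels x 0.75 mm^3 = 0.75 cm^3
        assert imat_volume(labels, region) == pytest.approx(0.75, abs=1e-12)

    def test_femur_excluded(self):
        arr = np.full((6, 6, 2), 3, dtype=np.uint8)
        labels = labels_from(arr)
        region = BinaryMask(np.ones(arr.shape, dtype=bool), (0.5, 0.5, 3.0))
        femur = BinaryMask(np.zeros(arr.shape, dtype=bool), (0.5, 0.5, 3.0))
        femur.values[:3] = True
        full = imat_volume(labels, region)
        assert imat_volume(labels, region, femur) == pytest.approx(full / 2)

    def test_grid_mismatch_rejected(self):
        labels = labels_from(np.full((4, 4, 4), 3))
        region = BinaryMask(np.ones((4, 4, 5), dtype=bool), (0.5, 0.5, 3.0))
        with pytest.raises(VolumeError):
            imat_volume(labels, region)

    def test_phantom_imat_within_five_percent(self, seg):
        femur = BinaryMask.like(seg.t1c, seg.truth.masks["femur"].values)
        est = imat_volume(seg.labels, seg.surf.if_voi, femur)
        assert est == pytest.approx(seg.truth.imat_fl_cm3, rel=0.05)


class TestMtThreshold:
    def volume_from(self, vals):
        vals = np.asarray(vals, dtype=float)
        side = int(np.ceil(len(vals) ** (1 / 3))) + 1
        grid = np.zeros(side**3)
        grid[: len(vals)] = vals
        grid = grid.reshape(side, side, side)
        vol = Volume3D(grid, (1, 1, 1))
        mask = BinaryMask.like(vol, np.zeros(vol.shape, dtype=bool))
        mask.values.flat[: len(vals)] = True
        return vol, mask

    def test_two_gaussian_mixture_matches_density_valley(self):
        # oracle: dense numeric minimization of the known mixture density
        from scipy.stats import norm

        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(70, 30, 150000), rng.normal(800, 30, 150000)])
        vol, mask = self.volume_from(np.clip(vals, 0, 1000))
        grid = np.linspace(100, 770, 67001)
        dens = 0.5 * norm.pdf(grid, 70, 30) + 0.5 * norm.pdf(grid, 800, 30)
        valley = grid[np.argmin(dens)]
        thr = mt_threshold(vol, mask)
        assert not thr.fallback
        assert abs(thr.value - valley) <= 20.0  # +/- 2 bins of 10

    def test_two_delta_populations_threshold_between(self):
        vals = np.array([50.0] * 500 + [800.0] * 500)
        vol, mask = self.volume_from(vals)
        thr = mt_threshold(vol, mask)
        assert 50.0 < thr.value < 800.0

    def test_count_scaling_leaves_argmin_unchanged(self):
        rng = np.random.default_rng(3)
        base = np.concatenate([rng.normal(100, 25, 2000), rng.normal(700, 25, 2000)])
        a = mt_threshold(*self.volume_from(np.clip(base, 0, 1000)))
        b = mt_threshold(*self.volume_from(np.clip(np.repeat(base, 10), 0, 1000)))
        assert a.value == b.value

    def test_unimodal_histogram_flags_fallback(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(300, 25, 3000)
        thr = mt_threshold(*self.volume_from(np.clip(vals, 0, 1000)))
        assert thr.fallback
        assert thr.value == 500.0

    def test_empty_voi_rejected(self):
        vol = Volume3D(np.zeros((4, 4, 4)), (1, 1, 1))
        empty = BinaryMask.like(vol, np.zeros(vol.shape, dtype=bool))
        with pytest.raises(VolumeError):
            mt_threshold(vol, empty)


class TestFfMt:
    def uniform(self, value, n=50):
        vol = Volume3D(np.full((5, 5, 2), float(value)), (1, 1, 1))
        mask = BinaryMask.like(vol, np.ones(vol.shape, dtype=bool))
        return vol, mask

    def test_full_scale_reads_hundred_percent(self):
        assert ff_mt(*self.uniform(1000)) == 100.0

    def test_zero_reads_zero_percent(self):
        assert ff_mt(*self.uniform(0)) == 0.0

    def test_mixed_mask_mean(self):
        vol = Volume3D(np.zeros((2, 2, 2)), (1, 1, 1))
        vol.values[0] = 40.0
        vol.values[1] = 100.0
        mask = BinaryMask.like(vol, np.ones(vol.shape, dtype=bool))
        assert ff_mt(vol, mask) == pytest.approx(7.0)

    def test_empty_mask_rejected(self):
        vol = Volume3D(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(VolumeError):
            ff_mt(vol, BinaryMask.like(vol, np.zeros(vol.shape, dtype=bool)))

    def test_monotone_in_threshold(self, seg):
        ffm = ff_thigh_mask(seg.ff)
        thr_hi = 500.0
        thr_lo = 200.0
        hi = ff_mt(seg.ff, muscle_tissue_mask(seg.ff, ffm, thr_hi))
        lo = ff_mt(seg.ff, muscle_tissue_mask(seg.ff, ffm, thr_lo))
        assert lo <= hi


class TestRegistration:
    def test_self_registration_is_identity(self, seg):
        T = register_rigid(seg.t1c, seg.thigh, seg.t1c, seg.thigh)
        rot, trans = flseg.transform_difference(
            T, flseg.RigidTransform.identity(seg.t1c.center_mm)
        )
        assert rot < 0.1 and trans < 0.1

    def test_known_offset_recovered(self, seg):
        ffm = ff_thigh_mask(seg.ff)
        T = register_rigid(seg.ff, ffm, seg.t1c, seg.fg)
        rot, trans = flseg.transform_difference(T, seg.truth.rigid_offset)
        assert rot <= 0.5 and trans <= 0.5

    def test_inverse_consistency(self, seg):
        ffm = ff_thigh_mask(seg.ff)
        fwd = register_rigid(seg.ff, ffm, seg.t1c, seg.fg)
        bwd = register_rigid(seg.t1c, seg.fg, seg.ff, ffm)
        comp = fwd.compose(bwd)
        rot, trans = flseg.transform_difference(
            comp, flseg.RigidTransform.identity(fwd.center_mm)
        )
        assert rot <= 0.5 and trans <= 0.5

    def test_empty_mask_rejected(self, seg):
        empty = BinaryMask.like(seg.ff, np.zeros(seg.ff.shape, dtype=bool))
        with pytest.raises(VolumeError):
            register_rigid(seg.ff, empty, seg.t1c, seg.thigh)


class TestRegionVolume:
    def test_region_minus_femur(self):
        region = BinaryMask(np.ones((10, 10, 2), dtype=bool), (0.5, 0.5, 3.0))
        femur = BinaryMask(np.zeros((10, 10, 2), dtype=bool), (0.5, 0.5, 3.0))
        femur.values[:5] = True
        assert region_volume(region, femur) == pytest.approx(100 * 0.75 / 1000.0)
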