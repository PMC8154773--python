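"""Hessian sheetness filtering and the fascia lata surface."""

import numpy as np
import pytest

import flseg
from flseg.envelope import LevelSetParams
from flseg.fascia import fl_surface, hessian_eigen, plate_weight
from flseg.volio import BinaryMask, Volume3D, VolumeError, WeightMap

from conftest import dice


def gaussian_sheet_volume(A=300.0, B=800.0, w=2.0, spacing=(0.5, 0.5, 3.0), shape=(80, 40, 6)):
    """Dark Gaussian sheet (normal along x) on a bright background."""
    x = np.arange(shape[0]) * spacing[0]
    x0 = x[shape[0] // 2]
    profile = B - A * np.exp(-((x - x0) ** 2) / (2 * w**2))
    vals = np.tile(profile[:, None, None], (1, shape[1], shape[2]))
    return Volume3D(vals, spacing), shape[0] // 2


class TestHessianEigen:
    def test_linear_ramp_has_zero_curvature(self):
        x = np.arange(40) * 0.5
        vals = np.tile((3.0 * x)[:, None, None], (1, 20, 4))
        vol = Volume3D(vals, (0.5, 0.5, 3.0))
        eig = hessian_eigen(vol, sigma_mm=1.0)
        interior = np.abs(eig.lam[:, 12:-12, 5:-5, 1:-1])
        # compare against the sheet-scale response (~100): curvature of the
        # ramp is zero up to boundary-reflection leakage of the smoother
        assert interior.max() < 1e-2

    def test_sheet_center_matches_finite_difference_oracle(self):
        # analytic smoothed profile: Gaussian (width w) convolved with the
        # filter Gaussian (sigma) stays Gaussian with s^2 = w^2 + sigma^2;
        # the oracle takes dense central differences on that closed form
        A, w = 300.0, 2.0
        sigma = 2.0
        vol, ic = gaussian_sheet_volume(A=A, w=w)
        s2 = w**2 + sigma**2
        h = 1e-3
        f = lambda x: -A * (w / np.sqrt(s2)) * np.exp(-(x**2) / (2 * s2))
        # a dark dip has positive curvature across the sheet
        oracle_l3 = sigma**2 * (f(h) - 2 * f(0.0) + f(-h)) / h**2
        eig = hessian_eigen(vol, sigma_mm=sigma)
        l1, l2, l3 = (eig.lam[i][ic, 20, 3] for i in range(3))
        assert l3 == pytest.approx(oracle_l3, rel=0.05)
        assert abs(l1) < 0.05 * abs(l3)
        assert abs(l2) < 0.05 * abs(l3)

    def test_in_plane_rotation_changes_center_response_little(self):
        A, w, sigma = 300.0, 2.0, 2.0
        shape = (80, 80, 4)
        spacing = (0.5, 0.5, 3.0)
        ii, jj = np.mgrid[: shape[0], : shape[1]]
        x = ii * spacing[0] - 20.0
        y = jj * spacing[1] - 20.0
        out = {}
        for ang in (0.0, 30.0):
            t = np.deg2rad(ang)
            d = x * np.cos(t) + y * np.sin(t)
            vals = np.repeat((800.0 - A * np.exp(-(d**2) / (2 * w**2)))[:, :, None], shape[2], 2)
            eig = hessian_eigen(Volume3D(vals, spacing), sigma_mm=sigma)
            out[ang] = eig.lam[2][40, 40, 2]
        assert out[30.0] == pytest.approx(out[0.0], rel=0.05)

    def test_sigma_below_spacing_rejected(self):
        vol = Volume3D(np.zeros((10, 10, 2)), (0.5, 0.5, 3.0))
        with pytest.raises(VolumeError):
            hessian_eigen(vol, sigma_mm=0.2)


class TestPlateWeight:
    def masks_for(self, vol, support):
        fib = BinaryMask.like(vol, support)
        me = BinaryMask.like(vol, np.zeros(vol.shape, dtype=bool))
        return fib, me

    def test_sheet_scores_high_blob_scores_lower(self):
        spacing = (0.5, 0.5, 3.0)
        shape = (80, 80, 6)
        ii, jj = np.mgrid[: shape[0], : shape[1]]
        x = ii * spacing[0] - 20.0
        y = jj * spacing[1] - 20.0
        w_sheet = 0.75
        sheet2d = 800.0 - 650.0 * np.exp(-(x**2) / (2 * w_sheet**2))
        blob2d = -650.0 * np.exp(-((x - 10.0) ** 2 + y**2) / (2 * w_sheet**2))
        vals = np.repeat((sheet2d + blob2d)[:, :, None], shape[2], 2)
        vol = Volume3D(vals, spacing)
        eigs = [hessian_eigen(vol, s) for s in (1.0, 1.5, 2.5)]
        support = np.zeros(shape, dtype=bool)
        support[38:42, :, :] = True  # sheet band
        support[56:64, 36:44, :] = True  # blob region
        fib, me = self.masks_for(vol, support)
        w = plate_weight(eigs, fib, me)
        sheet_scores = w.values[40, 10:30, 2:4]
        blob_score = w.values[60, 40, 2]
        assert np.median(sheet_scores) >= 0.9
        assert blob_score < 0.5 * np.median(sheet_scores)

    def test_uniform_region_zero_weight(self):
        vol = Volume3D(np.full((20, 20, 4), 500.0), (0.5, 0.5, 3.0))
        eig = hessian_eigen(vol, 1.0)
        fib, me = self.masks_for(vol, np.ones(vol.shape, dtype=bool))
        w = plate_weight(eig, fib, me)
        assert w.values.max() == 0.0

    def test_bright_plate_gated_out(self):
        vol, ic = gaussian_sheet_volume(A=-300.0, B=100.0)  # bright sheet
        eig = hessian_eigen(vol, 2.0)
        support = np.zeros(vol.shape, dtype=bool)
        support[ic - 1 : ic + 2] = True
        fib, me = self.masks_for(vol, support)
        w = plate_weight(eig, fib, me, c=100.0)
        assert w.values[ic, 20, 3] == 0.0

    def test_weight_invariant_under_intensity_offset(self, seg):
        shifted = Volume3D(seg.t1c.values + 123.0, seg.t1c.spacing, seg.t1c.origin)
        eigs_a = [hessian_eigen(seg.t1c, s) for s in (1.0, 1.5)]
        eigs_b = [hessian_eigen(shifted, s) for s in (1.0, 1.5)]
        fib = BinaryMask.like(seg.t1c, seg.labels.tissue("fibrous"))
        wa = plate_weight(eigs_a, fib, seg.me)
        wb = plate_weight(eigs_b, fib, seg.me)
        np.testing.assert_allclose(wa.values, wb.values, atol=1e-9)

    def test_support_restricted_to_fibrous_outside_envelope(self, seg):
        support = seg.labels.tissue("fibrous") & ~seg.me.values
        assert not (seg.weights.values > 0)[~support].any()
        assert seg.weights.values.min() >= 0.0 and seg.weights.values.max() <= 1.0


class TestFlSurface:
    def test_phantom_if_recovered(self, seg):
        assert dice(seg.surf.if_voi.values, seg.truth.masks["if_region"].values) >= 0.90
        assert (seg.surf.if_voi.values & ~seg.me.values).sum() > 0  # IF strictly > ME
        assert not seg.surf.fallback

    def test_sheet_centerline_weight_high(self, seg):
        sheet = seg.truth.masks["fl_sheet"].values & ~seg.me.values
        assert np.median(seg.weights.values[sheet]) >= 0.9

    def test_sandwich_containment(self, seg):
        u = seg.surf.if_voi.values
        assert not (seg.me.values & ~u).any()
        assert not (u & ~seg.thigh.values).any()

    def test_zero_weights_fall_back_to_envelope(self, seg):
        zero = WeightMap(np.zeros(seg.t1c.shape), seg.t1c.spacing, seg.t1c.origin)
        surf = fl_surface(seg.me, zero, seg.thigh)
        assert surf.fallback
        np.testing.assert_array_equal(surf.if_voi.values, seg.me.values)

    def test_decoy_arc_not_on_if_boundary(self, seg):
        from scipy import ndimage

        u = seg.surf.if_voi.values
        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)[:, :, None]
        boundary = u & ~ndimage.binary_erosion(u, structure=cross)
        decoy = seg.truth.masks["decoy"].values
        assert (boundary & decoy).sum() == 0

    def test_per_slice_single_closed_contour(self, seg):
        for z, contours in seg.surf.contours.items():
            assert len(contours) == 1
            assert np.allclose(contours[0][0], contours[0][-1])
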