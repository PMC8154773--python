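"""Livewire cost maps, A* optimality, seed propagation and contour editing."""

import heapq
import math

import numpy as np
import pytest

import flseg
from flseg.livewire import (
    ContourError,
    CostField,
    PathError,
    SeedSet,
    apply_refinement,
    cost_map,
    path_cost,
    propagate_seeds,
    shortest_path,
    trace_contour,
)
from flseg.volio import BinaryMask, Volume3D, VolumeError


def dijkstra_cost(c: np.ndarray, a, b) -> float:
    """Textbook Dijkstra over the same 8-connected edge weights (oracle)."""
    nx, ny = c.shape
    dist = {a: 0.0}
    heap = [(0.0, a)]
    done = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in done:
            continue
        done.add(node)
        if node == b:
            return d
        i, j = node
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if not (0 <= ni < nx and 0 <= nj < ny):
                    continue
                nd = d + 0.5 * (c[i, j] + c[ni, nj]) * math.hypot(di, dj)
                if nd < dist.get((ni, nj), math.inf):
                    dist[(ni, nj)] = nd
                    heapq.heappush(heap, (nd, (ni, nj)))
    raise AssertionError("unreachable")


def as_field(c2d: np.ndarray) -> CostField:
    return CostField(values=c2d[:, :, None], w_edge=0.6, w_fascia=0.4)


class TestShortestPath:
    def test_astar_equals_dijkstra_on_random_grids(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            c = rng.uniform(0.0, 1.0, (20, 20))
            a = tuple(rng.integers(0, 20, 2))
            b = tuple(rng.integers(0, 20, 2))
            field = as_field(c)
            path = shortest_path(field, 0, a, b)
            assert path[0] == a and path[-1] == b
            assert path_cost(c, path) == pytest.approx(dijkstra_cost(c, a, b), rel=1e-9, abs=1e-12)

    def test_uniform_grid_straight_line_cost(self):
        c = np.full((30, 30), 0.4)
        a, b = (2, 3), (12, 20)
        # 8-connected shortest route: diagonal moves for min(dx,dy), then straight
        dx, dy = abs(b[0] - a[0]), abs(b[1] - a[1])
        expected = 0.4 * (math.sqrt(2.0) * min(dx, dy) + abs(dx - dy))
        path = shortest_path(as_field(c), 0, a, b)
        assert path_cost(c, path) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_single_point(self):
        c = np.ones((5, 5))
        path = shortest_path(as_field(c), 0, (2, 2), (2, 2))
        assert path == [(2, 2)]
        assert path_cost(c, path) == 0.0

    def test_masked_target_unreachable(self):
        c = np.ones((5, 5))
        c[:, 2] = np.inf  # wall
        with pytest.raises(PathError):
            shortest_path(as_field(c), 0, (0, 0), (0, 4))


class TestCostMap:
    def test_uniform_image_cost_is_one(self):
        vol = Volume3D(np.full((8, 8, 2), 55.0), (1, 1, 1))
        field = cost_map(vol, None)
        np.testing.assert_allclose(field.values, 1.0)

    def test_cost_bounded_unit_interval(self):
        rng = np.random.default_rng(5)
        vol = Volume3D(rng.uniform(0, 1000, (16, 16, 3)), (0.5, 0.5, 3.0))
        field = cost_map(vol, None)
        assert field.values.min() >= 0.0 and field.values.max() <= 1.0

    def test_weights_must_sum_to_one(self):
        vol = Volume3D(np.zeros((4, 4, 1)), (1, 1, 1))
        with pytest.raises(VolumeError):
            cost_map(vol, None, w_edge=0.7, w_fascia=0.5)

    def test_fascia_centerline_cheaper_than_surroundings(self, seg):
        field = cost_map(seg.t1c, seg.weights)
        sheet = seg.truth.masks["fl_sheet"].values
        z = seg.t1c.shape[2] // 2
        rows = np.unique(np.argwhere(sheet[:, :, z])[:, 0])[5::10]
        for i in rows:
            cols = np.flatnonzero(sheet[i, :, z])
            if cols.size == 0:
                continue
            j = cols[0]
            on_cost = field.values[i, cols, z].min()
            far = [jj for jj in range(field.values.shape[1])
                   if np.abs(jj - cols).min() >= 3 and seg.truth.masks["sat"].values[i, jj, z]]
            if far:
                assert on_cost < field.values[i, far, z].min()


class TestPropagation:
    def test_stationary_cost_keeps_seeds(self):
        # identical slices, seeds on the (stationary) cost minima
        c = np.ones((15, 15, 6))
        c[4, 4, :] = 0.0
        c[10, 9, :] = 0.0
        seeds = SeedSet(points=[(0, (4, 4)), (0, (10, 9))])
        out = propagate_seeds(seeds, CostField(c, 0.6, 0.4), n_slices=4, window=2)
        assert len(out) == 4
        for step in out:
            assert [p for _, p in step.points] == [(4, 4), (10, 9)]

    def test_default_propagation_depth_is_ten_slices(self):
        import inspect

        assert inspect.signature(propagate_seeds).parameters["n_slices"].default == 10

    def test_drifting_minimum_is_tracked(self):
        # cost valley drifts one voxel per slice; window 2 must follow it
        nz, n = 6, 30
        c = np.ones((n, n, nz))
        for z in range(nz):
            c[10 + z, :, z] = 0.0
        seeds = SeedSet(points=[(0, (10, 15)), (0, (10, 5))])
        out = propagate_seeds(seeds, CostField(c, 0.6, 0.4), n_slices=5, window=2)
        for k, step in enumerate(out, start=1):
            for _, (i, _) in step.points:
                assert i == 10 + k

    def test_snap_outside_mask_flagged_unsnapped(self):
        c = np.ones((10, 10, 3))
        c[8, 8, 1] = 0.0  # tempting minimum outside the mask
        mask_vals = np.zeros((10, 10, 3), dtype=bool)
        mask_vals[:6, :6, :] = True
        mask = BinaryMask(mask_vals, (1, 1, 1))
        seeds = SeedSet(points=[(0, (5, 5)), (0, (1, 1))])
        out = propagate_seeds(seeds, CostField(c, 0.6, 0.4), n_slices=1, window=3, mask=mask)
        assert out[0].snapped == [False, True]
        assert out[0].points[0][1] == (5, 5)


class TestRefinement:
    def square(self, s, offset=2):
        o = offset
        return [(o, o), (o, o + s - 1), (o + s - 1, o + s - 1), (o + s - 1, o)]

    def empty_mask(self, shape=(20, 20, 3)):
        return BinaryMask(np.zeros(shape, dtype=bool), (1, 1, 1))

    def test_square_contour_fills_boundary_inclusive_area(self):
        s = 7
        out = apply_refinement(self.empty_mask(), 1, self.square(s))
        assert out.values[:, :, 1].sum() == s * s

    def test_other_slices_untouched(self):
        mask = self.empty_mask()
        mask.values[5, 5, 0] = True
        out = apply_refinement(mask, 1, self.square(5))
        np.testing.assert_array_equal(out.values[:, :, 0], mask.values[:, :, 0])
        np.testing.assert_array_equal(out.values[:, :, 2], mask.values[:, :, 2])

    def test_reapplication_is_idempotent(self):
        once = apply_refinement(self.empty_mask(), 1, self.square(6))
        twice = apply_refinement(once, 1, self.square(6))
        np.testing.assert_array_equal(once.values, twice.values)

    def test_self_intersecting_contour_rejected(self):
        bowtie = [(0, 0), (5, 5), (0, 5), (5, 0)]
        with pytest.raises(ContourError):
            apply_refinement(self.empty_mask(), 0, bowtie)

    def test_traced_contour_closes_loop(self):
        c = np.ones((20, 20, 2))
        field = CostField(c, 0.6, 0.4)
        seeds = SeedSet(points=[(0, (3, 3)), (0, (3, 15)), (0, (15, 15)), (0, (15, 3))])
        z, contour = trace_contour(field, seeds)
        assert z == 0
        assert len(contour) >= 4
        out = apply_refinement(self.empty_mask(), z, contour)
        assert out.values[:, :, 0].sum() > 100  # filled interior
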