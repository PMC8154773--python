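"""Scriptable livewire refinement of the fascia contour.

A per-slice cost field combines normalized T1w gradient edges with the
plate-likeness weights; A* finds globally cheapest 8-connected paths
between seed points (the heuristic is admissible and consistent, so path
costs equal Dijkstra's). Seeds placed on one slice propagate to the
following slices by snapping to the local cost minimum. The traced closed
contour replaces the intra-fascia region on the edited slice only.
"""

from __future__ import annotations

import dataclasses
import heapq
import math

import numpy as np

from .volio import BinaryMask, Volume3D, VolumeError, WeightMap


class PathError(VolumeError):
    """No admissible path between the requested seed points."""


class ContourError(VolumeError):
    """Invalid (e.g. self-intersecting) refinement contour."""


@dataclasses.dataclass
class CostField:
    """Per-voxel local cost in [0, 1]; low along strong edges and
    high-fascia-weight voxels."""

    values: np.ndarray  # (nx, ny, nz)
    w_edge: float
    w_fascia: float


@dataclasses.dataclass
class SeedSet:
    """Ordered seed points ``(slice, (ix, iy))``; closed-loop contours need
    at least two seeds."""

    points: list[tuple[int, tuple[int, int]]]
    closed: bool = True
    snapped: list[bool] | None = None  # False where snapping was refused

    def __post_init__(self) -> None:
        if self.closed and len(self.points) < 2:
            raise VolumeError("a closed-loop seed set needs at least 2 seeds")


def cost_map(
    volume: Volume3D,
    weights: WeightMap | None = None,
    w_edge: float = 0.6,
    w_fascia: float = 0.4,
) -> CostField:
    """cost = w_edge * (1 - G) + w_fascia * (1 - weight), with G the
    per-slice max-normalized in-plane gradient magnitude."""
    if abs(w_edge + w_fascia - 1.0) > 1e-9:
        raise VolumeError("w_edge + w_fascia must equal 1")
    dx, dy, _ = volume.spacing
    vals = np.asarray(volume.values, dtype=float)
    gx = np.gradient(vals, dx, axis=0)
    gy = np.gradient(vals, dy, axis=1)
    G = np.hypot(gx, gy)
    for z in range(G.shape[2]):
        mx = G[:, :, z].max()
        if mx > 0:
            G[:, :, z] /= mx
    if weights is not None:
        volume.require_same_grid(weights)
        w = np.asarray(weights.values, dtype=float)
    else:
        w = np.zeros_like(vals)
    cost = w_edge * (1.0 - G) + w_fascia * (1.0 - w)
    return CostField(values=np.clip(cost, 0.0, 1.0), w_edge=w_edge, w_fascia=w_fascia)


_STEPS = [
    (di, dj, math.hypot(di, dj))
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    if (di, dj) != (0, 0)
]


def path_cost(cost2d: np.ndarray, path: list[tuple[int, int]]) -> float:
    """Summed edge cost of a voxel path: mean of endpoint costs times the
    Euclidean step length."""
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        step = math.hypot(b[0] - a[0], b[1] - a[1])
        total += 0.5 * (cost2d[a] + cost2d[b]) * step
    return total


def shortest_path(
    cost: CostField,
    slice_index: int,
    a: tuple[int, int],
    b: tuple[int, int],
) -> list[tuple[int, int]]:
    """Globally optimal 8-connected path from a to b on one slice (A* with
    the admissible heuristic: Euclidean distance times the slice's minimum
    cost). Non-finite cost voxels are barriers. Ties break by lexicographic
    voxel order, so the result is deterministic."""
    c = np.asarray(cost.values[:, :, slice_index], dtype=float)
    nx, ny = c.shape
    a, b = tuple(map(int, a)), tuple(map(int, b))
    for p in (a, b):
        if not (0 <= p[0] < nx and 0 <= p[1] < ny):
            raise PathError(f"seed {p} outside the slice")
        if not np.isfinite(c[p]):
            raise PathError(f"seed {p} lies in a masked (non-traversable) region")
    if a == b:
        return [a]
    finite = c[np.isfinite(c)]
    hmin = float(finite.min()) if finite.size else 0.0
    dist = np.full(c.shape, np.inf)
    dist[a] = 0.0
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    heap: list[tuple[float, float, tuple[int, int]]] = []
    heapq.heappush(heap, (hmin * math.hypot(b[0] - a[0], b[1] - a[1]), 0.0, a))
    while heap:
        f, d, node = heapq.heappop(heap)
        if d > dist[node]:
            continue
        if node == b:
            path = [node]
            while node != a:
                node = parent[node]
                path.append(node)
            return path[::-1]
        ci, cj = node
        cn = c[node]
        for di, dj, step in _STEPS:
            ni, nj = ci + di, cj + dj
            if not (0 <= ni < nx and 0 <= nj < ny):
                continue
            cv = c[ni, nj]
            if not np.isfinite(cv):
                continue
            nd = d + 0.5 * (cn + cv) * step
            if nd < dist[ni, nj]:
                dist[ni, nj] = nd
                parent[(ni, nj)] = node
                h = hmin * math.hypot(b[0] - ni, b[1] - nj)
                heapq.heappush(heap, (nd + h, nd, (ni, nj)))
    raise PathError(f"no path from {a} to {b} on slice {slice_index}")


def propagate_seeds(
    seeds: SeedSet,
    cost: CostField,
    n_slices: int = 10,
    window: int = 3,
    mask: BinaryMask | None = None,
) -> list[SeedSet]:
    """Copy the seeds of one slice to the following ``n_slices`` slices,
    snapping each to the minimum-cost voxel inside a (2*window+1)^2
    neighbourhood (ties: lexicographic order). A snap that would leave
    ``mask`` keeps the unsnapped seed and flags it."""
    if n_slices < 1:
        raise VolumeError("n_slices must be >= 1")
    slices = {s for s, _ in seeds.points}
    if len(slices) != 1:
        raise VolumeError("propagation expects all seeds on a single slice")
    z0 = slices.pop()
    nz = cost.values.shape[2]
    out: list[SeedSet] = []
    current = [p for _, p in seeds.points]
    for z in range(z0 + 1, min(z0 + n_slices, nz - 1) + 1):
        c = cost.values[:, :, z]
        new_pts: list[tuple[int, tuple[int, int]]] = []
        flags: list[bool] = []
        for (ix, iy) in current:
            i0, i1 = max(0, ix - window), min(c.shape[0], ix + window + 1)
            j0, j1 = max(0, iy - window), min(c.shape[1], iy + window + 1)
            patch = c[i0:i1, j0:j1]
            k = int(np.argmin(patch))  # row-major argmin == lexicographic tie-break
            pi, pj = i0 + k // patch.shape[1], j0 + k % patch.shape[1]
            if mask is not None and not mask.values[pi, pj, z]:
                new_pts.append((z, (ix, iy)))
                flags.append(False)
            else:
                new_pts.append((z, (pi, pj)))
                flags.append(True)
        out.append(SeedSet(points=new_pts, closed=seeds.closed, snapped=flags))
        current = [p for _, p in new_pts]
    return out


def trace_contour(
    cost: CostField, seeds: SeedSet
) -> tuple[int, list[tuple[int, int]]]:
    """Connect consecutive seeds (closing the loop) with shortest paths."""
    slices = {s for s, _ in seeds.points}
    if len(slices) != 1:
        raise VolumeError("a contour must live on a single slice")
    z = slices.pop()
    pts = [p for _, p in seeds.points]
    if seeds.closed:
        pairs = list(zip(pts, pts[1:] + pts[:1]))
    else:
        pairs = list(zip(pts[:-1], pts[1:]))
    contour: list[tuple[int, int]] = []
    for a, b in pairs:
        seg = shortest_path(cost, z, a, b)
        contour.extend(seg[:-1] if seeds.closed or b != pts[-1] else seg)
    return z, contour


def _clean_ring(verts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates and zero-area backtrack spikes (a, b, a)
    that naturally occur where traced path segments join; genuine
    self-crossings are left for the validity check."""
    pts = [tuple(v) for v in verts]
    for _ in range(len(pts)):
        n = len(pts)
        if n < 3:
            break
        out = []
        skip = False
        for i in range(n):
            if skip:
                skip = False
                continue
            prev = out[-1] if out else pts[(i - 1) % n]
            if pts[i] == prev:
                continue
            if pts[(i + 1) % n] == prev:  # spike prev -> pts[i] -> prev
                skip = True
                continue
            out.append(pts[i])
        if len(out) == len(pts):
            break
        pts = out
    return np.asarray(pts, dtype=float)


def apply_refinement(
    if_voi: BinaryMask,
    slice_index: int,
    contour: np.ndarray | list[tuple[int, int]],
) -> BinaryMask:
    """Replace one slice of the IF mask by the filled contour polygon
    (even-odd fill; boundary voxels inside). All other slices are returned
    bit-identical. Self-intersecting contours are rejected."""
    from shapely.geometry import Polygon
    from skimage import draw

    verts = np.asarray(contour, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ContourError("contour needs at least 3 vertices")
    verts = _clean_ring(verts)
    if verts.shape[0] < 3:
        raise ContourError("contour degenerates to fewer than 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ContourError("self-intersecting contour")
    nx, ny, _ = if_voi.shape
    filled = np.zeros((nx, ny), dtype=bool)
    rr, cc = draw.polygon(verts[:, 0], verts[:, 1], shape=(nx, ny))
    filled[rr, cc] = True
    iverts = np.rint(verts).astype(int)
    ring = np.vstack([iverts, iverts[:1]])
    for p, q in zip(ring[:-1], ring[1:]):
        rr, cc = draw.line(p[0], p[1], q[0], q[1])
        keep = (rr >= 0) & (rr < nx) & (cc >= 0) & (cc < ny)
        filled[rr[keep], cc[keep]] = True
    out = if_voi.values.copy()
    out[:, :, slice_index] = filled
    return BinaryMask.like(if_voi, out)
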