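"""Muscle-envelope extraction with a contractive morphological geodesic
active contour.

The front is a binary region initialized at the thigh boundary that shrinks
inward under three discrete operators per iteration: a balloon erosion gated
by the edge map, an advection step that removes boundary voxels where the
edge-map gradient points outward, and a sup-inf/inf-sup curvature smoothing.
The scheme is unconditionally stable (no time step) and, by construction,
strictly contractive: the enclosed region never grows, so it stops on the
first closed edge ridge it meets. Evolution steps act in-plane because the
slice spacing (3 mm) is much coarser than the in-plane spacing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, Volume3D, VolumeError
from .cluster import MembershipMap


class LevelSetCollapseError(VolumeError):
    """The evolving front vanished before converging."""

    def __init__(self, message: str, info: dict | None = None):
        super().__init__(message)
        self.info = info or {}


@dataclasses.dataclass
class LevelSetParams:
    """Parameters of the discrete geodesic-active-contour scheme.

    ``threshold`` gates the balloon erosion (the front keeps shrinking while
    the edge map exceeds it); ``smoothing`` is the number of curvature
    passes per iteration. Convergence is declared when fewer than
    ``conv_fraction`` of the voxels change over ``conv_window`` iterations.
    The morphological scheme has no CFL time-step constraint.
    """

    balloon: float = -1.0  # negative = shrink (the only supported direction)
    threshold: float = 0.35
    smoothing: int = 1
    max_iter: int = 200
    conv_fraction: float = 1e-4
    conv_window: int = 5
    polish_iter: int = 50  # advection-only settling onto the edge minimum
    edge_sigma_mm: float = 1.0
    edge_floor: float = 0.1
    edge_percentile: float = 90.0

    def __post_init__(self) -> None:
        if self.balloon >= 0:
            raise ValueError("only contractive evolution (balloon < 0) is supported")
        if not (0 < self.edge_floor < 1):
            raise ValueError("edge_floor must lie in (0, 1)")


# four 3-long line segments (in-plane) for the curvature operators
_LINES = [
    np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], dtype=bool),
    np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=bool),
    np.eye(3, dtype=bool),
    np.fliplr(np.eye(3, dtype=bool)),
]
_LINES = [l[:, :, None] for l in _LINES]
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)[:, :, None]


def _sup_inf(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    for se in _LINES:
        out |= ndimage.binary_erosion(u, structure=se, border_value=0)
    return out


def _inf_sup(u: np.ndarray) -> np.ndarray:
    out = np.ones_like(u)
    for se in _LINES:
        out &= ndimage.binary_dilation(u, structure=se, border_value=0)
    return out


def edge_map(
    members: MembershipMap,
    sigma_mm: float = 1.0,
    floor: float = 0.1,
    percentile: float = 90.0,
) -> Volume3D:
    """Edge-stopping map from the muscle-membership field.

    ``g = exp(-ln(1/floor) * G / G_p)`` with G the gradient magnitude of the
    Gaussian-smoothed muscle membership (derivatives in mm) and G_p its
    ``percentile``-th percentile — so g equals ``floor`` at that gradient
    level, is 1 in homogeneous regions and strictly positive everywhere.
    """
    mask = members.mask
    spacing = np.asarray(mask.spacing)
    muscle = members.memberships[2].astype(float)
    sm = ndimage.gaussian_filter(muscle, sigma=sigma_mm / spacing)
    grads = np.gradient(sm, *spacing)
    G = np.sqrt(sum(g * g for g in grads))
    pos = G[G > 1e-12]
    if pos.size == 0:
        return Volume3D(np.ones_like(G), mask.spacing, mask.origin)
    g_ref = np.percentile(pos, percentile)
    g = np.exp(-np.log(1.0 / floor) * G / max(g_ref, 1e-12))
    return Volume3D(g, mask.spacing, mask.origin)


def morph_gac(
    g: np.ndarray,
    init: np.ndarray,
    params: LevelSetParams,
    domain: np.ndarray | None = None,
    freeze: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the contractive morphological GAC.

    ``freeze`` voxels (if given) are clamped inside the region, so the front
    can never cross them; ``domain`` bounds the evolution. Returns the
    converged region and an info dict (iterations, converged, collapsed,
    per-iteration enclosed-voxel counts).
    """
    u = np.asarray(init, dtype=bool).copy()
    if domain is not None:
        u &= domain
    g = np.asarray(g, dtype=float)
    gx, gy = np.gradient(g, axis=0), np.gradient(g, axis=1)
    balloon_gate = g > params.threshold
    history: list[int] = []
    changes: list[int] = []
    converged = False
    total = u.size
    for it in range(1, params.max_iter + 1):
        prev = u
        nxt = u.copy()
        er = ndimage.binary_erosion(u, structure=_CROSS, border_value=0)
        nxt[balloon_gate] = er[balloon_gate]
        uf = prev.astype(float)
        aux = gx * np.gradient(uf, axis=0) + gy * np.gradient(uf, axis=1)
        nxt[aux < 0] = False
        for _ in range(params.smoothing):
            nxt = _sup_inf(_inf_sup(nxt)) if it % 2 else _inf_sup(_sup_inf(nxt))
        nxt &= prev  # strict contraction
        if freeze is not None:
            nxt |= freeze
        if domain is not None:
            nxt &= domain
        changed = int((nxt ^ prev).sum())
        u = nxt
        history.append(int(u.sum()))
        changes.append(changed)
        if len(changes) >= params.conv_window and (
            sum(changes[-params.conv_window:]) < params.conv_fraction * total
        ):
            converged = True
            break
        if not u.any():
            break
    # advection-only polish: slide the boundary onto the edge-map minimum
    # (the curvature operator can hold the front a voxel or two outside it);
    # each step only removes voxels, so contraction is preserved
    for _ in range(params.polish_iter):
        uf = u.astype(float)
        aux = gx * np.gradient(uf, axis=0) + gy * np.gradient(uf, axis=1)
        nxt = u & ~(aux < 0)
        if freeze is not None:
            nxt |= freeze
        if domain is not None:
            nxt &= domain
        if np.array_equal(nxt, u):
            break
        history.append(int(nxt.sum()))
        u = nxt
    info = {
        "iterations": it,
        "converged": converged,
        "collapsed": not u.any(),
        "enclosed_voxels": history,
    }
    return u, info


def muscle_envelope(
    members: MembershipMap,
    thigh: BinaryMask,
    params: LevelSetParams | None = None,
) -> BinaryMask:
    """Tight muscle envelope: the GAC front shrinks from the thigh boundary
    and stops on the muscle-membership edge; small muscle-labelled islands
    in SAT (veins) are pinched off and discarded with the non-largest
    components."""
    params = params or LevelSetParams()
    members.mask.require_same_grid(thigh)
    g = edge_map(
        members,
        sigma_mm=params.edge_sigma_mm,
        floor=params.edge_floor,
        percentile=params.edge_percentile,
    )
    u, info = morph_gac(g.values, thigh.values, params, domain=thigh.values)
    if info["collapsed"]:
        raise LevelSetCollapseError("muscle envelope collapsed to the empty set", info)
    lab, n = ndimage.label(u)
    if n == 0:
        raise LevelSetCollapseError("muscle envelope collapsed to the empty set", info)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    u = lab == (1 + int(np.argmax(sizes)))
    for z in range(u.shape[2]):
        u[:, :, z] = ndimage.binary_fill_holes(u[:, :, z])
    return BinaryMask.like(thigh, u)
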