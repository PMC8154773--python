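"""Shared fixtures: a small phantom (fast unit-test grid) and its
segmentation chain, computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import flseg
from flseg import cluster, envelope, fascia, preprocess


SMALL = dict(
    grid_shape=(104, 104, 8),
    thigh_radius_mm=21.0,
    femur_radius_mm=4.5,
    ff_grid_shape=(72, 72, 10),
)


@pytest.fixture(scope="session")
def small_spec() -> flseg.PhantomSpec:
    return flseg.PhantomSpec(**SMALL)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return flseg.make_phantom(small_spec)


@dataclasses.dataclass
class SegChain:
    t1w: flseg.Volume3D
    ff: flseg.Volume3D
    truth: flseg.PhantomTruth
    fg: flseg.BinaryMask
    t1c: flseg.Volume3D
    members: cluster.MembershipMap
    labels: cluster.TissueLabelMap
    thigh: flseg.BinaryMask
    femur: flseg.BinaryMask
    me: flseg.BinaryMask
    weights: flseg.WeightMap
    surf: fascia.FasciaSurface


@pytest.fixture(scope="session")
def seg(small_phantom) -> SegChain:
    """The full segmentation chain on the small phantom (shared; stages must
    not mutate it)."""
    t1w, ff, truth = small_phantom
    fg = preprocess.foreground_mask(t1w)
    t1c, _ = preprocess.correct_bias(t1w, fg)
    full = flseg.BinaryMask.like(t1c, np.ones(t1c.shape, dtype=bool))
    members = cluster.fcm(t1c, full)
    labels = cluster.harden(members)
    thigh = cluster.thigh_surface(labels, t1c)
    femur = cluster.segment_femur(labels, thigh)
    me = envelope.muscle_envelope(members, thigh)
    eigs = [fascia.hessian_eigen(t1c, s) for s in (1.0, 1.5, 2.5)]
    fibrous = flseg.BinaryMask.like(t1c, labels.tissue("fibrous"))
    weights = fascia.plate_weight(eigs, fibrous, me)
    surf = fascia.fl_surface(me, weights, thigh)
    return SegChain(t1w, ff, truth, fg, t1c, members, labels, thigh, femur, me, weights, surf)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
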