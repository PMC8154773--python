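"""End-to-end pipeline: bias correction -> clustering -> muscle envelope ->
fascia surface -> (optional scripted livewire refinement) -> quantification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import cluster as _cluster
from . import envelope as _envelope
from . import fascia as _fascia
from . import livewire as _livewire
from . import preprocess as _preprocess
from . import quantify as _quantify
from .envelope import LevelSetParams
from .volio import BinaryMask, RigidTransform, Volume3D, read_volume, resample, write_volume


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults."""

    # bias correction
    bias_order: int = 3
    bias_tol: float = 1e-3
    bias_max_iter: int = 20
    # fuzzy c-means
    fcm_clusters: int = 4
    fcm_m: float = 2.0
    fcm_tol: float = 1e-4
    fcm_max_iter: int = 200
    # thigh / femur morphology
    skin_thickness_vox: int = 2
    closing_radius: int = 2
    # level sets
    me_level_set: LevelSetParams = dataclasses.field(default_factory=LevelSetParams)
    fl_level_set: LevelSetParams = dataclasses.field(
        default_factory=lambda: LevelSetParams(threshold=0.35)
    )
    # plate filter
    frangi_scales_mm: tuple[float, ...] = (1.0, 1.5, 2.5)
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_c: float | None = None
    # livewire refinement
    livewire_w_edge: float = 0.6
    livewire_w_fascia: float = 0.4
    livewire_window: int = 3
    livewire_propagate_slices: int = 10
    # quantification
    hist_bin_width: float = 10.0
    hist_smooth_window: int = 5
    trim_n: int = 3
    reg_bins: int = 32
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["me_level_set"] = dataclasses.asdict(self.me_level_set)
        d["fl_level_set"] = dataclasses.asdict(self.fl_level_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("me_level_set", "fl_level_set"):
            if key in d and isinstance(d[key], dict):
                ls_known = {f.name for f in dataclasses.fields(LevelSetParams)}
                ls_unknown = set(d[key]) - ls_known
                if ls_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(ls_unknown)}")
                d[key] = LevelSetParams(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class PipelineResult:
    report: _quantify.QuantReport
    masks: dict[str, BinaryMask]
    members: _cluster.MembershipMap
    labels: _cluster.TissueLabelMap
    weights: object
    contours: dict
    transform: RigidTransform | None
    manifest: dict


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    t1w: Volume3D | str,
    ff: Volume3D | str | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    refine_seeds: dict[int, list[tuple[int, int]]] | None = None,
) -> PipelineResult:
    """Run the full segmentation + quantification chain.

    ``refine_seeds`` optionally maps a slice index to an ordered list of
    (ix, iy) seed points; the traced livewire contour replaces the IF
    boundary on that slice and is propagated to the following slices.
    Without an FF volume the FF-dependent report fields stay ``None``.
    """
    cfg = config or PipelineConfig()
    if isinstance(t1w, (str, Path)):
        t1w = read_volume(t1w)
    if isinstance(ff, (str, Path)):
        ff = read_volume(ff)
    warnings_out: list[str] = []

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, e) from e

    fg = stage("foreground", _preprocess.foreground_mask, t1w)
    t1c, bias = stage(
        "bias_correction",
        _preprocess.correct_bias,
        t1w,
        fg,
        order=cfg.bias_order,
        tol=cfg.bias_tol,
        max_iter=cfg.bias_max_iter,
    )
    full = BinaryMask.like(t1c, np.ones(t1c.shape, dtype=bool))
    members = stage(
        "fcm",
        _cluster.fcm,
        t1c,
        full,
        k=cfg.fcm_clusters,
        m=cfg.fcm_m,
        tol=cfg.fcm_tol,
        max_iter=cfg.fcm_max_iter,
        seed=cfg.seed,
    )
    labels = stage("harden", _cluster.harden, members)
    thigh = stage(
        "thigh_surface",
        _cluster.thigh_surface,
        labels,
        t1c,
        skin_thickness_vox=cfg.skin_thickness_vox,
        closing_radius=cfg.closing_radius,
    )
    femur = stage("femur", _cluster.segment_femur, labels, thigh)
    me = stage("muscle_envelope", _envelope.muscle_envelope, members, thigh, cfg.me_level_set)
    eigs = [
        stage("hessian", _fascia.hessian_eigen, t1c, s) for s in cfg.frangi_scales_mm
    ]
    fibrous = BinaryMask.like(t1c, labels.tissue("fibrous"))
    weights = stage(
        "plate_weight",
        _fascia.plate_weight,
        eigs,
        fibrous,
        me,
        alpha=cfg.frangi_alpha,
        beta=cfg.frangi_beta,
        c=cfg.frangi_c,
    )
    surf = stage("fl_surface", _fascia.fl_surface, me, weights, thigh, cfg.fl_level_set)
    if_voi = surf.if_voi
    if surf.fallback:
        warnings_out.append("fascia front collapsed onto the muscle envelope; IF = ME")

    if refine_seeds:
        cost = _livewire.cost_map(
            t1c, weights, w_edge=cfg.livewire_w_edge, w_fascia=cfg.livewire_w_fascia
        )
        for z0, pts in sorted(refine_seeds.items()):
            seeds = _livewire.SeedSet(points=[(z0, tuple(p)) for p in pts])
            z, contour = _livewire.trace_contour(cost, seeds)
            if_voi = _livewire.apply_refinement(if_voi, z, contour)
            for nxt in _livewire.propagate_seeds(
                seeds, cost, n_slices=cfg.livewire_propagate_slices,
                window=cfg.livewire_window, mask=thigh,
            ):
                z, contour = _livewire.trace_contour(cost, nxt)
                if_voi = _livewire.apply_refinement(if_voi, z, contour)

    if_trim = stage("trim", _quantify.trim_slices, if_voi, cfg.trim_n)
    me_trim = _quantify.trim_slices(me, cfg.trim_n)
    femur_trim = _quantify.trim_slices(femur, cfg.trim_n)
    imat_fl = _quantify.imat_volume(labels, if_trim, femur_trim)
    imat_me = _quantify.imat_volume(labels, me_trim, femur_trim)
    vol_total = _quantify.region_volume(if_trim, femur_trim)
    slices_analyzed = t1w.shape[2] - 2 * cfg.trim_n

    transform = None
    ff_mt_val = None
    thr_val = None
    thr_fallback = False
    if ff is not None:
        ff_mask = stage("ff_mask", _quantify.ff_thigh_mask, ff)
        # register over the full body cross-section (skin included): the FF
        # mask keeps the skin, and an asymmetric boundary band between the
        # two masks measurably biases the recovered rotations
        transform = stage(
            "registration",
            _quantify.register_rigid,
            ff,
            ff_mask,
            t1c,
            fg,
            bins=cfg.reg_bins,
        )
        if_ff = resample(if_voi, transform, ff)
        femur_ff = resample(femur, transform, ff)
        if_ff_trim = _quantify.trim_slices(if_ff, cfg.trim_n)
        thr = stage(
            "mt_threshold",
            _quantify.mt_threshold,
            ff,
            if_ff_trim,
            bin_width=cfg.hist_bin_width,
            smooth_window=cfg.hist_smooth_window,
        )
        thr_val, thr_fallback = thr.value, thr.fallback
        if thr.fallback:
            warnings_out.append("unimodal FF histogram; fallback threshold 500 used")
        mt = _quantify.muscle_tissue_mask(ff, if_ff_trim, thr.value, femur_ff)
        ff_mt_val = stage("ff_mt", _quantify.ff_mt, ff, mt)

    report = _quantify.QuantReport(
        volume_total_cm3=vol_total,
        imat_fl_cm3=imat_fl,
        imat_me_cm3=imat_me,
        slices_analyzed=slices_analyzed,
        ff_mt_pct=ff_mt_val,
        mt_threshold=thr_val,
        mt_threshold_fallback=thr_fallback,
        warnings=tuple(warnings_out),
    )
    masks = {
        "thigh": thigh,
        "femur": femur,
        "me": me,
        "if_voi": if_voi,
        "fibrous": fibrous,
    }
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "checksums": {
            "t1w_corrected": _checksum(t1c.values),
            **{k: _checksum(v.values) for k, v in masks.items()},
            "weights": _checksum(weights.values),
        },
        "report": report.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(t1c, out / "t1w_bc.nii.gz")
        for name, mask in masks.items():
            write_volume(mask, out / f"{name}.nii.gz")
        write_volume(Volume3D(weights.values, weights.spacing, weights.origin),
                     out / "weights.nii.gz")
        contours_json = {
            str(z): [c.tolist() for c in cs] for z, cs in surf.contours.items()
        }
        (out / "fl_contours.json").write_text(json.dumps(contours_json))
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        report=report,
        masks=masks,
        members=members,
        labels=labels,
        weights=weights,
        contours=surf.contours,
        transform=transform,
        manifest=manifest,
    )
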