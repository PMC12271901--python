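"""Paired-run orchestration: simulate, track, reconstruct, register, evaluate.

A run executes two arms on the *identical* phantom, bolus, motion trace and
noise streams -- one with prospective navigator tracking (the fastNAV-style
arm) and one without (the reference arm) -- mirroring a paired two-protocol
study design.  Each arm is acquired, TGRAPPA-reconstructed, registered
in-plane, temporally filtered, and scored with avDICE/avCOM on ground-truth
LV masks, before and after registration.  Everything is reproducible from
the (config, seed) pair recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import importlib.metadata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .fastnav import CrossCorrelationTracker, TrackingConfig
from .metrics import MaskSeries, analysis_window_start, regional_summary
from .moco import RegistrationConfig, register_series, temporal_filter, warp_mask
from .phantom import (BolusModel, BreathEvent, MotionConfig, PhantomSpec,
                      make_motion_trace, make_phantom)
from .recon import ImageSeries, reconstruct_series, series_nrmse
from .sequence import Protocol, acquire_series

__all__ = ["ReconOptions", "RunConfig", "ArmResult", "RunResult",
           "run_experiment", "comparison_table", "deep_breath_dynamics"]


@dataclass(frozen=True)
class ReconOptions:
    kernel_pe: int = 4
    kernel_ro: int = 5
    reg: float = 1e-4
    fit_stride: int = 2


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    rr_s: float = 1.0
    noise_sigma: float = 0.0005
    navigator_noise: float = 0.02
    com_reference: str = "first"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    bolus: BolusModel = field(default_factory=BolusModel)
    motion: MotionConfig = field(default_factory=MotionConfig)
    protocol: Protocol = field(default_factory=Protocol)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    recon: ReconOptions = field(default_factory=ReconOptions)
    moco: RegistrationConfig = field(default_factory=RegistrationConfig)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        builders = dict(
            phantom=_build_phantom_spec, bolus=_build(BolusModel),
            motion=_build_motion, protocol=_build(Protocol),
            tracking=_build(TrackingConfig), recon=_build(ReconOptions),
            moco=_build(RegistrationConfig),
        )
        kwargs = {}
        for key, builder in builders.items():
            if key in d:
                kwargs[key] = builder(d.pop(key))
        kwargs.update(d)
        return RunConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as f:
            return RunConfig.from_dict(yaml.safe_load(f) or {})

    @staticmethod
    def named(name: str) -> "RunConfig":
        """A config shipped with the package (``default`` or ``demo``)."""
        path = Path(__file__).parent / "configs" / f"{name}.yaml"
        if not path.exists():
            raise FileNotFoundError(f"no packaged config named {name!r}")
        return RunConfig.from_yaml(path)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = clean(self)
        d["phantom"].pop("tissues", None)  # tissue table is code-defined
        return d

    def with_overrides(self, overrides: dict) -> "RunConfig":
        d = self.to_dict()
        for dotted, value in overrides.items():
            node = d
            *parents, leaf = dotted.split(".")
            for p in parents:
                node = node.setdefault(p, {})
            node[leaf] = value
        return RunConfig.from_dict(d)


def _build(cls):
    def make(d):
        if isinstance(d, cls):
            return d
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name in d:
                v = d[f_.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[f_.name] = v
        return cls(**kwargs)
    return make


def _build_phantom_spec(d):
    if isinstance(d, PhantomSpec):
        return d
    return _build(PhantomSpec)(d)


def _build_motion(d):
    if isinstance(d, MotionConfig):
        return d
    d = dict(d)
    if "events" in d:
        d["events"] = tuple(BreathEvent(**ev) if isinstance(ev, dict) else ev
                            for ev in d["events"])
    return _build(MotionConfig)(d)


@dataclass
class ArmResult:
    name: str
    acquisition: object
    raw: ImageSeries
    registered: ImageSeries
    filtered: ImageSeries
    masks: MaskSeries
    masks_registered: MaskSeries
    metrics_pre: pd.DataFrame
    metrics_post: pd.DataFrame
    nrmse: pd.DataFrame


@dataclass
class RunResult:
    config: RunConfig
    arms: dict[str, ArmResult]
    comparison: pd.DataFrame
    manifest: dict
    out_dir: Path | None = None


def deep_breath_dynamics(motion: MotionConfig, rr_s: float, n_dynamics: int):
    """Dynamics whose heartbeat overlaps a deep-breath event."""
    dyns = set()
    for ev in motion.events:
        lo = int(np.floor(ev.onset_s / rr_s))
        hi = int(np.ceil((ev.onset_s + ev.duration_s) / rr_s))
        dyns.update(range(max(0, lo), min(n_dynamics, hi)))
    return sorted(dyns)


def _run_arm(name: str, tracking: bool, cfg: RunConfig, phantom, window) -> ArmResult:
    tracker = None
    if tracking:
        tracker = CrossCorrelationTracker(phantom, cfg.tracking,
                                          noise_sigma=cfg.navigator_noise,
                                          seed=cfg.seed)
    acq = acquire_series(phantom, cfg.protocol, tracking=tracking, tracker=tracker,
                         noise_sigma=cfg.noise_sigma, seed=cfg.seed)
    raw = reconstruct_series(acq.shots, cfg.protocol,
                             kernel_pe=cfg.recon.kernel_pe,
                             kernel_ro=cfg.recon.kernel_ro,
                             reg=cfg.recon.reg, fit_stride=cfg.recon.fit_stride)
    px = (cfg.phantom.voxel_size[0], cfg.phantom.voxel_size[1])
    raw.pixel_mm = px
    err = series_nrmse(raw, acq.truth)

    masks = MaskSeries(acq.gt_masks, pixel_mm=px, window=window)
    pre = regional_summary(masks, method=f"{name}/pre", com_reference=cfg.com_reference)

    rois = acq.gt_masks.any(axis=1)
    # "peak" = peak myocardial enhancement; with the bolus model known this
    # is the analysis-window start, which also anchors the metrics.
    ref = window[0] if cfg.moco.reference == "peak" else cfg.moco.reference
    moco_cfg = dataclasses.replace(cfg.moco, pixel_mm=px, reference=ref)
    registered, fields = register_series(raw, moco_cfg, rois=rois)
    warped = np.empty_like(acq.gt_masks)
    for s in range(masks.n_slices):
        for d in range(masks.n_dynamics):
            warped[s, d] = warp_mask(acq.gt_masks[s, d], fields[s][d])
    masks_reg = MaskSeries(warped, pixel_mm=px, window=window)
    post = regional_summary(masks_reg, method=f"{name}/post", com_reference=cfg.com_reference)

    filtered = temporal_filter(registered)
    return ArmResult(name=name, acquisition=acq, raw=raw, registered=registered,
                     filtered=filtered, masks=masks, masks_registered=masks_reg,
                     metrics_pre=pre, metrics_post=post, nrmse=err)


def comparison_table(arms: dict[str, ArmResult]) -> pd.DataFrame:
    """Four-row (arm x pre/post registration) global avDICE/avCOM table."""
    rows = []
    for name, arm in arms.items():
        for stage, table in (("pre", arm.metrics_pre), ("post", arm.metrics_post)):
            g = table[table.scope == "global"].iloc[0]
            rows.append(dict(arm=name, stage=stage,
                             avdice=g.avdice, avcom_mm=g.avcom_mm))
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, out_dir=None, save_kspace: bool = False,
                   arms: tuple[str, ...] = ("tracked", "untracked")) -> RunResult:
    """Execute the paired tracked/untracked experiment.

    Both arms share the phantom, motion trace, enhancement and per-shot
    noise seeds; only the tracking flag differs.  If ``out_dir`` is given,
    image series (NIfTI), tracking logs, metric tables (CSV) and a checksum
    manifest (JSON) are written there.
    """
    cfg = config
    cfg.protocol.validate()
    duration = cfg.protocol.n_dynamics * cfg.rr_s + 5.0
    motion = make_motion_trace(cfg.motion, duration, seed=cfg.seed)
    phantom = make_phantom(cfg.phantom, bolus=cfg.bolus, motion=motion, rr_s=cfg.rr_s)
    start = analysis_window_start(cfg.bolus, cfg.rr_s, cfg.protocol.n_dynamics)
    window = (start, cfg.protocol.n_dynamics)

    manifest = dict(
        created=datetime.datetime.now().isoformat(timespec="seconds"),
        package_version=importlib.metadata.version("smsperf"),
        seed=cfg.seed,
        config=cfg.to_dict(),
        analysis_window=list(window),
        outputs={},
    )
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        with open(out_path / "config.yaml", "w") as f:
            yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)
        sio.write_manifest(manifest, out_path)  # written before any output

    results: dict[str, ArmResult] = {}
    for name in arms:
        results[name] = _run_arm(name, tracking=(name == "tracked"), cfg=cfg,
                                 phantom=phantom, window=window)

    comparison = comparison_table(results)

    if out_path is not None:
        outputs = {}
        sio.save_motion_csv(motion, out_path / "motion.csv")
        outputs["motion"] = "motion.csv"
        comparison.to_csv(out_path / "comparison.csv", index=False)
        outputs["comparison"] = "comparison.csv"
        for name, arm in results.items():
            adir = out_path / name
            adir.mkdir(exist_ok=True)
            sio.save_series_nifti(arm.raw, adir / "images_raw.nii.gz")
            sio.save_series_nifti(arm.registered, adir / "images_registered.nii.gz")
            sio.save_series_nifti(arm.filtered, adir / "images_filtered.nii.gz")
            sio.save_masks_nifti(arm.masks.masks, adir / "masks.nii.gz",
                                 pixel_mm=arm.masks.pixel_mm)
            arm.acquisition.tracking_log.to_csv(adir / "tracking.csv", index=False)
            arm.nrmse.to_csv(adir / "nrmse.csv", index=False)
            pd.concat([arm.metrics_pre, arm.metrics_post]).to_csv(
                adir / "metrics.csv", index=False)
            if save_kspace:
                sio.save_shots_h5(arm.acquisition.shots, cfg.protocol,
                                  adir / "kspace.h5")
            outputs[name] = sorted(p.name for p in adir.iterdir())
        for rel in ["comparison.csv", "motion.csv", "config.yaml"]:
            manifest["outputs"][rel] = sio.sha256_of(out_path / rel)
        for name in results:
            for p in sorted((out_path / name).iterdir()):
                manifest["outputs"][f"{name}/{p.name}"] = sio.sha256_of(p)
        sio.write_manifest(manifest, out_path)

    return RunResult(config=cfg, arms=results, comparison=comparison,
                     manifest=manifest, out_dir=out_path)
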