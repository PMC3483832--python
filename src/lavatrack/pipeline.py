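"""Full-study orchestration: seven registrations plus all tracking outputs.

A study comprises eight scans (four phases x FRC/TLC).  The pipeline runs
three inter-phase registrations (each post-lavage TLC onto the baseline
TLC) and four intra-phase registrations (each phase's FRC onto its TLC),
then derives, on the baseline lattice: tissue-volume series for the whole
lung and the lavage region, ventilation (reciprocal-Jacobian) maps and
their rank (CDF) transforms, rank-change summaries, slab profiles, and
landmark errors.  All outputs are deterministic given the configuration
and inputs; a manifest records the configuration hash and per-stage wall
times.

Two small robustness choices: the whole-lung tracking region is the lung
mask eroded by one voxel (boundary voxels mix lung and chest-wall
intensities under interpolation, which would bias the tissue integral
one-sidedly), and fluid recovery is additionally reported over the lavage
region dilated by two voxels (a material region that contains the
deposited fluid with a margin for registration uncertainty).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .bspline_transform import BSplineTransform, JacobianMap
from .image_model import (
    BinaryMask3D,
    LandmarkSet,
    read_mask,
    read_volume,
    write_volume,
)
from .mixture_model import TissueVolumeSeries
from .registration import RegistrationConfig, register
from .synthetic_data import PhantomSpec, generate_phantom_study
from .tracking_analysis import (
    PHASES,
    POST_PHASES,
    PhaseScans,
    PhaseStudy,
    pull_map_to_baseline,
    rank_change,
    rank_map,
    slab_profile,
    ventilation_map,
)

log = logging.getLogger("lavatrack")

__all__ = ["StudyConfig", "StudyReport", "run_full_study", "eroded", "dilated"]


def eroded(mask: BinaryMask3D, voxels: int) -> BinaryMask3D:
    if voxels <= 0:
        return mask
    return BinaryMask3D(
        ndimage.binary_erosion(mask.values, iterations=voxels),
        mask.spacing,
        mask.origin,
    )


def dilated(mask: BinaryMask3D, voxels: int) -> BinaryMask3D:
    if voxels <= 0:
        return mask
    return BinaryMask3D(
        ndimage.binary_dilation(mask.values, iterations=voxels),
        mask.spacing,
        mask.origin,
    )


@dataclass
class StudyConfig:
    """Inputs, registration settings and output layout for one study run."""

    out_dir: Path
    phantom: PhantomSpec | None = None
    scan_paths: dict | None = None  # {phase: {"tlc":..., "frc":..., "tlc_mask":..., ...}}
    lavage_mask_path: str | None = None
    rtvp: RegistrationConfig = field(default_factory=RegistrationConfig.rtvp)
    rivp: RegistrationConfig = field(default_factory=RegistrationConfig.rivp_defaults)
    seed: int = 17
    lung_erosion_voxels: int = 1
    lavage_dilation_voxels: int = 2
    n_slabs: int = 30
    slab_axes: tuple[int, ...] = (1, 2)
    save_transforms: bool = True
    save_maps: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if (self.phantom is None) == (self.scan_paths is None):
            raise ValueError("configure exactly one of phantom or scan_paths")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kw = dict(raw)
        if "phantom" in kw and kw["phantom"] is not None:
            kw["phantom"] = PhantomSpec(**kw["phantom"])
        for key in ("rtvp", "rivp"):
            if key in kw and isinstance(kw[key], dict):
                factory = (
                    RegistrationConfig.rtvp
                    if key == "rtvp"
                    else RegistrationConfig.rivp_defaults
                )
                kw[key] = factory(**kw[key])
        if "slab_axes" in kw:
            kw["slab_axes"] = tuple(kw["slab_axes"])
        return cls(**kw)

    def digest(self) -> str:
        blob = repr(
            (
                self.phantom,
                self.scan_paths,
                self.lavage_mask_path,
                self.rtvp,
                self.rivp,
                self.seed,
                self.lung_erosion_voxels,
                self.lavage_dilation_voxels,
                self.n_slabs,
                self.slab_axes,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyReport:
    manifest: dict
    tissue_series: dict[str, TissueVolumeSeries]
    rank_changes: list
    slab_profiles: dict
    landmark_errors: dict
    rivp_transforms: dict[str, BSplineTransform]
    rtvp_transforms: dict[str, BSplineTransform]


def _load_study(cfg: StudyConfig) -> PhaseStudy:
    if cfg.phantom is not None:
        spec = replace(cfg.phantom, seed=cfg.seed)
        return generate_phantom_study(spec)
    scans = {}
    for phase in PHASES:
        p = cfg.scan_paths[phase]
        scans[phase] = PhaseScans(
            tlc=read_volume(p["tlc"]),
            frc=read_volume(p["frc"]),
            tlc_mask=read_mask(p["tlc_mask"]),
            frc_mask=read_mask(p["frc_mask"]),
            tlc_landmarks=(
                LandmarkSet.read_csv(p["tlc_landmarks"]) if "tlc_landmarks" in p else None
            ),
            frc_landmarks=(
                LandmarkSet.read_csv(p["frc_landmarks"]) if "frc_landmarks" in p else None
            ),
        )
    lavage = read_mask(cfg.lavage_mask_path) if cfg.lavage_mask_path else None
    return PhaseStudy(scans=scans, lavage_mask=lavage)


def run_full_study(cfg: StudyConfig) -> StudyReport:
    """Execute the seven registrations and every tracking analysis.

    Results are written under ``cfg.out_dir`` (CSV/JSON, plus transforms and
    optional maps); the returned report holds the in-memory objects.  A
    stage failure is recorded in the manifest with the stage flagged, and
    later stages that do not depend on it still run.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lavatrack",
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "stages": {},
        "failed_stages": [],
        "outputs": [],
    }

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 2),
                    "ok": exc is None,
                }
                if exc is not None:
                    manifest["failed_stages"].append(name)
                    log.error("stage %s failed: %s", name, exc)
                    return True  # continue with remaining stages
                log.info("stage %s: done", name)
                return False

        return _Stage()

    study: PhaseStudy | None = None
    with stage("load_inputs"):
        study = _load_study(cfg)
    if study is None:
        _write_manifest(manifest, out)
        return StudyReport(manifest, {}, [], {}, {}, {}, {})

    base = study.baseline
    cache: dict = {}
    rivp_transforms: dict[str, BSplineTransform] = {}
    rtvp_transforms: dict[str, BSplineTransform] = {}
    landmark_errors: dict[str, dict] = {}

    for phase in POST_PHASES:
        with stage(f"rivp_{phase}"):
            scans = study.scans[phase]
            lms = None
            if base.tlc_landmarks is not None and scans.tlc_landmarks is not None:
                lms = (base.tlc_landmarks, scans.tlc_landmarks)
            res = register(
                scans.tlc, base.tlc, scans.tlc_mask, base.tlc_mask, cfg.rivp,
                landmarks=lms, feature_cache=cache,
            )
            rivp_transforms[phase] = res.transform
            landmark_errors[f"rivp_{phase}"] = _landmark_entry(res)
            if cfg.save_transforms:
                path = out / f"rivp_{phase}.lvt"
                res.transform.save(path)
                manifest["outputs"].append(path.name)

    for phase in PHASES:
        with stage(f"rtvp_{phase}"):
            scans = study.scans[phase]
            lms = None
            if scans.tlc_landmarks is not None and scans.frc_landmarks is not None:
                lms = (scans.tlc_landmarks, scans.frc_landmarks)
            res = register(
                scans.frc, scans.tlc, scans.frc_mask, scans.tlc_mask, cfg.rtvp,
                landmarks=lms, feature_cache=cache,
            )
            rtvp_transforms[phase] = res.transform
            landmark_errors[f"rtvp_{phase}"] = _landmark_entry(res)
            if cfg.save_transforms:
                path = out / f"rtvp_{phase}.lvt"
                res.transform.save(path)
                manifest["outputs"].append(path.name)

    # ---- tissue volume tracking -------------------------------------------
    tissue_series: dict[str, TissueVolumeSeries] = {}
    with stage("tissue_tracking"):
        from .tracking_analysis import track_tissue_volume

        regions = {"whole_lung": eroded(base.tlc_mask, cfg.lung_erosion_voxels)}
        if study.lavage_mask is not None:
            regions["lavage"] = study.lavage_mask.intersection(base.tlc_mask)
            regions["lavage_dilated"] = dilated(
                study.lavage_mask, cfg.lavage_dilation_voxels
            ).intersection(base.tlc_mask)
        for name, region in regions.items():
            tissue_series[name] = track_tissue_volume(
                study, rivp_transforms, region, region=name
            )
        df = pd.concat([s.to_frame() for s in tissue_series.values()])
        path = out / "tissue_volume_series.csv"
        df.to_csv(path, index=False)
        manifest["outputs"].append(path.name)

    # ---- ventilation, rank maps, rank change ------------------------------
    rank_changes: list = []
    slabs: dict = {}
    with stage("function_analysis"):
        vent_on_base: dict[str, JacobianMap] = {}
        for phase in PHASES:
            vent = ventilation_map(rtvp_transforms[phase], study.scans[phase].tlc, label=phase)
            if phase != "base":
                vent = pull_map_to_baseline(vent, rivp_transforms[phase], base.tlc)
            vent_on_base[phase] = vent
            if cfg.save_maps:
                path = out / f"ventilation_{phase}.nii.gz"
                write_volume(vent.volume, path)
                manifest["outputs"].append(path.name)
        ranks = {
            phase: rank_map(vent_on_base[phase], base.tlc_mask, phase=phase)
            for phase in PHASES
        }
        if study.lavage_mask is not None:
            for phase in POST_PHASES:
                rank_changes.append(
                    rank_change(
                        ranks["base"], ranks[phase],
                        study.lavage_mask, study.nonlavage_mask, phase=phase,
                    )
                )
            path = out / "rank_change.json"
            path.write_text(
                json.dumps(
                    [
                        {
                            "phase": rc.phase,
                            "mean_rc_lavage": rc.mean_rc_lavage,
                            "mean_rc_nonlavage": rc.mean_rc_nonlavage,
                        }
                        for rc in rank_changes
                    ],
                    indent=2,
                )
            )
            manifest["outputs"].append(path.name)
        rows = []
        for axis in cfg.slab_axes:
            for phase in PHASES:
                prof = slab_profile(
                    vent_on_base[phase], base.tlc_mask, axis, cfg.n_slabs
                )
                slabs[(axis, phase)] = prof
                for i, v in enumerate(prof):
                    rows.append(
                        {"axis": axis, "phase": phase, "slab": i, "mean_jacobian": v}
                    )
        path = out / "slab_profiles.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest["outputs"].append(path.name)

    with stage("landmark_report"):
        path = out / "landmark_errors.json"
        path.write_text(json.dumps(landmark_errors, indent=2))
        manifest["outputs"].append(path.name)

    _write_manifest(manifest, out)
    return StudyReport(
        manifest=manifest,
        tissue_series=tissue_series,
        rank_changes=rank_changes,
        slab_profiles=slabs,
        landmark_errors=landmark_errors,
        rivp_transforms=rivp_transforms,
        rtvp_transforms=rtvp_transforms,
    )


def _landmark_entry(res) -> dict:
    if res.landmark_error_after_mm is None:
        return {"available": False}
    return {
        "available": True,
        "mean_before_mm": res.mean_landmark_error_before,
        "mean_after_mm": res.mean_landmark_error_after,
        "min_jacobian": res.min_jacobian,
        "convergence_failure": res.convergence_failure,
    }


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
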