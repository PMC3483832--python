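"""Longitudinal tissue-volume tracking and Jacobian ventilation analysis.

All regional quantities are tracked in a Lagrangian reference frame: regions
and landmarks are defined on the baseline TLC lattice, and post-lavage
quantities are carried to it through the inter-phase transforms.  The
Jacobian determinant of the intra-phase (FRC-to-TLC) transform serves as a
regional ventilation surrogate; because the transform is estimated on the
TLC lattice and maps into the FRC image, its determinant is the FRC/TLC
volume ratio, so the reported ventilation map is the reciprocal 1/J and
local inspiratory expansion corresponds to values greater than one.

To compare ventilation across phases with different breathing efforts, each
phase's map is reduced to its empirical CDF ("rank") within the lung: a
voxel's rank is the fraction of lung voxels with a Jacobian less than or
equal to its own.  Rank is invariant under any strictly increasing
rescaling of the map, which removes global effort differences; the rank
change RC_i = Rank_i - Rank_0 then isolates regional function change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .bspline_transform import JacobianMap
from .image_model import (
    BinaryMask3D,
    DegenerateInputError,
    LandmarkSet,
    ScalarVolume3D,
    resample_through_transform,
)
from .mixture_model import (
    DEFAULT_MIXTURE,
    MixtureConstants,
    TissueVolumeSeries,
    regional_tissue_volume,
    tissue_volume_series,
    warped_regional_tissue_volume,
)

__all__ = [
    "PHASES",
    "POST_PHASES",
    "PhaseScans",
    "PhaseStudy",
    "BalRecord",
    "RankMap",
    "RankChangeSummary",
    "RegressionResult",
    "LandmarkErrorSummary",
    "unretrieved_bal",
    "track_tissue_volume",
    "ventilation_map",
    "pull_map_to_baseline",
    "rank_map",
    "rank_change",
    "slab_profile",
    "landmark_error",
    "regress_tvc_vs_bal",
    "load_bal_study",
    "load_whole_lung_tvcr",
]

PHASES = ("base", "post0", "post4", "post24")
POST_PHASES = PHASES[1:]


@dataclass
class PhaseScans:
    """One phase's FRC/TLC scan pair with lung masks and landmarks."""

    tlc: ScalarVolume3D
    frc: ScalarVolume3D
    tlc_mask: BinaryMask3D
    frc_mask: BinaryMask3D
    tlc_landmarks: LandmarkSet | None = None
    frc_landmarks: LandmarkSet | None = None


@dataclass
class PhaseStudy:
    """The eight-scan bundle: four phases, FRC and TLC each.

    The baseline TLC lattice is the reference frame; the lavage-region mask
    (when present) lives on it.  ``truth`` holds generator ground truth for
    synthetic studies (analytic warps, fluid volumes, noise-free images).
    """

    scans: dict[str, PhaseScans]
    lavage_mask: BinaryMask3D | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [p for p in PHASES if p not in self.scans]
        if missing:
            raise ValueError(f"study is missing phases: {missing}")

    @property
    def baseline(self) -> PhaseScans:
        return self.scans["base"]

    @property
    def nonlavage_mask(self) -> BinaryMask3D:
        if self.lavage_mask is None:
            raise ValueError("study has no lavage-region mask")
        return self.baseline.tlc_mask.difference(self.lavage_mask)


@dataclass(frozen=True)
class BalRecord:
    """Instilled, retrieved and unretrieved lavage fluid volumes, mL."""

    v_total: float
    v_retrieved: float

    def __post_init__(self):
        if self.v_total < 0 or self.v_retrieved < 0:
            raise ValueError("volumes must be nonnegative")
        if self.v_retrieved > self.v_total:
            raise ValueError("retrieved volume exceeds instilled volume")

    @property
    def v_bal(self) -> float:
        return self.v_total - self.v_retrieved


def unretrieved_bal(total_ml: float, retrieved_ml: float) -> BalRecord:
    """Unretrieved lavage fluid: volume delivered minus volume retrieved."""
    return BalRecord(float(total_ml), float(retrieved_ml))


def track_tissue_volume(
    study: PhaseStudy,
    transforms: dict[str, object],
    region_on_base: BinaryMask3D,
    region: str = "region",
    c: MixtureConstants = DEFAULT_MIXTURE,
) -> TissueVolumeSeries:
    """Tissue volume of a baseline region tracked across the four phases.

    ``transforms`` maps each post phase to its inter-phase transform (defined
    on the baseline TLC lattice, into that phase's TLC image).  TV_0 is the
    direct mixture integral on baseline; TV_i integrates through h_i with
    Jacobian volume scaling.
    """
    base = study.baseline
    if not base.tlc.same_geometry(region_on_base):
        raise ValueError("region must live on the baseline TLC lattice")
    if not np.all(base.tlc_mask.values[region_on_base.values]):
        raise ValueError("region extends outside the baseline lung mask")
    tv = [regional_tissue_volume(base.tlc, region_on_base, c)]
    for phase in POST_PHASES:
        tv.append(
            warped_regional_tissue_volume(
                study.scans[phase].tlc, transforms[phase], region_on_base, c
            )
        )
    return tissue_volume_series(*tv, region=region)


def ventilation_map(intra_transform, geometry, label: str = "") -> JacobianMap:
    """Ventilation surrogate on the TLC lattice: reciprocal Jacobian 1/J(h).

    ``intra_transform`` maps the TLC lattice into the FRC image, so J(h) is
    the FRC/TLC volume ratio; 1/J makes inspiratory expansion > 1.
    """
    jac = intra_transform.jacobian_map(geometry, label=label)
    return JacobianMap(jac.volume.with_values(1.0 / jac.values), label=label)


def pull_map_to_baseline(
    map_on_post: JacobianMap, inter_transform, base_geometry
) -> JacobianMap:
    """Resample a post-phase map onto the baseline lattice through h_i."""
    vol = resample_through_transform(
        map_on_post.volume, inter_transform, base_geometry, fill=1.0
    )
    return JacobianMap(vol, label=map_on_post.label)


@dataclass(frozen=True)
class RankMap:
    """Empirical-CDF-transformed Jacobian map on a lung mask.

    Values inside the mask lie in (0, 1] with the "<=" tie convention (a
    constant field ranks 1.0 everywhere); voxels outside the mask are 0.
    """

    volume: ScalarVolume3D
    mask: BinaryMask3D
    phase: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


def rank_map(jac: JacobianMap, mask: BinaryMask3D, phase: str = "") -> RankMap:
    """Rank (empirical CDF) of each masked voxel's Jacobian within the mask."""
    mask.require_nonempty("lung mask")
    vals = jac.values[mask.values]
    ranks = stats.rankdata(vals, method="max") / vals.size
    out = np.zeros(mask.shape)
    out[mask.values] = ranks
    return RankMap(
        ScalarVolume3D(out, mask.spacing, mask.origin), mask=mask, phase=phase
    )


@dataclass(frozen=True)
class RankChangeSummary:
    """Mean voxel-wise rank change per region for one post phase."""

    phase: str
    mean_rc_lavage: float
    mean_rc_nonlavage: float


def rank_change(
    rank_base: RankMap,
    rank_post: RankMap,
    lavage_mask: BinaryMask3D,
    nonlavage_mask: BinaryMask3D,
    phase: str = "",
) -> RankChangeSummary:
    """Voxel-wise rank difference averaged within lavage / non-lavage regions."""
    for m in (rank_post.volume, lavage_mask, nonlavage_mask):
        if not rank_base.volume.same_geometry(m):
            raise ValueError("all maps must live on the baseline lattice")
    rc = rank_post.values - rank_base.values
    return RankChangeSummary(
        phase=phase or rank_post.phase,
        mean_rc_lavage=float(rc[lavage_mask.values].mean()),
        mean_rc_nonlavage=float(rc[nonlavage_mask.values].mean()),
    )


def slab_profile(
    jac: JacobianMap, mask: BinaryMask3D, axis: int, n_slabs: int = 30
) -> np.ndarray:
    """Mean Jacobian in equal-thickness slabs along one axis of the lung box.

    The mask bounding box along ``axis`` is split into ``n_slabs`` slabs;
    each entry is the mean over masked voxels in that slab, NaN where a slab
    contains none.
    """
    if n_slabs < 1:
        raise DegenerateInputError("n_slabs must be at least 1")
    mask.require_nonempty("lung mask")
    idx = np.nonzero(mask.values)
    lo, hi = idx[axis].min(), idx[axis].max() + 1
    edges = np.linspace(lo, hi, n_slabs + 1)
    which = np.clip(np.searchsorted(edges, idx[axis], side="right") - 1, 0, n_slabs - 1)
    vals = jac.values[idx]
    out = np.full(n_slabs, np.nan)
    for s in range(n_slabs):
        sel = which == s
        if sel.any():
            out[s] = vals[sel].mean()
    return out


@dataclass(frozen=True)
class LandmarkErrorSummary:
    labels: tuple[str, ...]
    distances_mm: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances_mm.mean())

    @property
    def sd(self) -> float:
        return float(self.distances_mm.std(ddof=1)) if len(self.distances_mm) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "error_mm": self.distances_mm})


def landmark_error(predicted: LandmarkSet, truth: LandmarkSet) -> LandmarkErrorSummary:
    """Euclidean distance (mm) between predicted and true landmark positions."""
    if set(predicted.labels) != set(truth.labels):
        raise ValueError("landmark sets carry different labels")
    order = {lab: i for i, lab in enumerate(truth.labels)}
    t = truth.points[[order[lab] for lab in predicted.labels]]
    d = np.linalg.norm(predicted.points - t, axis=1)
    return LandmarkErrorSummary(labels=predicted.labels, distances_mm=d)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def regress_tvc_vs_bal(records) -> RegressionResult:
    """Ordinary least squares of TVC_1 on the unretrieved fluid volume V_BAL.

    ``records`` is an iterable of (V_BAL, TVC_1) pairs in mL; R^2 is the
    squared Pearson correlation of the fit.
    """
    arr = np.asarray(list(records), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise DegenerateInputError("need at least two (V_BAL, TVC1) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateInputError("V_BAL is constant; regression is degenerate")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# packaged reference measurements (six-subject lavage study)
# ---------------------------------------------------------------------------


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("lavatrack.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_bal_study() -> pd.DataFrame:
    """Per-subject instilled/retrieved fluid volumes and whole-lung TVC_1 (mL)
    from the reference six-subject lavage study."""
    return _load_csv("bal_study.csv")


def load_whole_lung_tvcr() -> pd.DataFrame:
    """Per-subject whole-lung tissue volume change ratios (percent, integers
    as reported) across the three post-lavage phases."""
    return _load_csv("whole_lung_tvcr.csv")
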