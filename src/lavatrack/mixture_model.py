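"""Air/tissue decomposition of CT Hounsfield values.

The lung parenchyma is modelled as a two-compartment mixture of air and
tissue/blood.  With fixed anchors HU_air and HU_tissue, the tissue fraction
of a voxel is linear in its HU value,

    beta(I) = (I - HU_air) / (HU_tissue - HU_air),

and the air fraction is alpha(I) = 1 - beta(I).  Both are clamped to [0, 1]
for HU outside the model range (bone, contrast, noise), where the
two-compartment extrapolation would be nonphysical.  Regional tissue volume
is the voxel-centre Riemann sum of v(x) * beta(I(x)) over a region, and the
warped variant integrates the same quantity through a transformation h with
local volume scaling by its Jacobian determinant:

    TV = sum_R v(x) * J(h(x)) * beta(I(h(x))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_model import (
    BinaryMask3D,
    DegenerateInputError,
    ScalarVolume3D,
    sample_at_world,
)

__all__ = [
    "MixtureConstants",
    "DEFAULT_MIXTURE",
    "TissueVolumeSeries",
    "tissue_fraction",
    "air_fraction",
    "regional_tissue_volume",
    "regional_air_volume",
    "warped_regional_tissue_volume",
    "tissue_volume_series",
]


@dataclass(frozen=True)
class MixtureConstants:
    """HU anchors of the air/tissue mixture model."""

    hu_air: float = -1000.0
    hu_tissue: float = 55.0

    def __post_init__(self):
        if not self.hu_tissue > self.hu_air:
            raise ValueError("hu_tissue must exceed hu_air")

    @property
    def span(self) -> float:
        return self.hu_tissue - self.hu_air


DEFAULT_MIXTURE = MixtureConstants()


def tissue_fraction(hu, c: MixtureConstants = DEFAULT_MIXTURE):
    """Tissue (non-air) volume fraction beta(I), clamped to [0, 1]."""
    beta = (np.asarray(hu, dtype=np.float64) - c.hu_air) / c.span
    return np.clip(beta, 0.0, 1.0)


def air_fraction(hu, c: MixtureConstants = DEFAULT_MIXTURE):
    """Air volume fraction alpha(I), clamped to [0, 1]."""
    alpha = (c.hu_tissue - np.asarray(hu, dtype=np.float64)) / c.span
    return np.clip(alpha, 0.0, 1.0)


def hu_from_tissue_fraction(beta, c: MixtureConstants = DEFAULT_MIXTURE):
    """Inverse of :func:`tissue_fraction` on the model range."""
    return c.hu_air + np.asarray(beta, dtype=np.float64) * c.span


def regional_tissue_volume(
    vol: ScalarVolume3D,
    region: BinaryMask3D,
    c: MixtureConstants = DEFAULT_MIXTURE,
) -> float:
    """Tissue volume (mm^3) inside a region: sum of v(x) * beta(I(x))."""
    if not vol.same_geometry(region):
        raise ValueError("region must live on the volume's lattice")
    region.require_nonempty("integration region")
    beta = tissue_fraction(vol.values[region.values], c)
    return float(vol.voxel_volume * beta.sum())


def regional_air_volume(
    vol: ScalarVolume3D,
    region: BinaryMask3D,
    c: MixtureConstants = DEFAULT_MIXTURE,
) -> float:
    """Air volume (mm^3) inside a region: sum of v(x) * alpha(I(x))."""
    if not vol.same_geometry(region):
        raise ValueError("region must live on the volume's lattice")
    region.require_nonempty("integration region")
    alpha = air_fraction(vol.values[region.values], c)
    return float(vol.voxel_volume * alpha.sum())


def warped_regional_tissue_volume(
    template_vol: ScalarVolume3D,
    transform,
    region_on_target: BinaryMask3D,
    c: MixtureConstants = DEFAULT_MIXTURE,
) -> float:
    """Tissue volume of a reference region integrated through a transform.

    The region lives on the reference (baseline) lattice; ``transform`` maps
    reference world points into the template (post-phase) image.  Each voxel
    contributes v(x) * J(h(x)) * beta(I(h(x))).  Non-positive Jacobian values
    inside the region indicate an injectivity violation and raise a
    RuntimeWarning (the sum is still returned).
    """
    region_on_target.require_nonempty("integration region")
    pts = region_on_target.lattice_points()[region_on_target.values]
    mapped = transform.map_points(pts)
    jac = transform.jacobian_at(pts)
    n_bad = int((jac <= 0).sum())
    if n_bad:
        warnings.warn(
            f"transform is non-injective at {n_bad} region voxels (J <= 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    hu = sample_at_world(template_vol, mapped, fill=c.hu_air)
    beta = tissue_fraction(hu, c)
    return float(region_on_target.voxel_volume * np.sum(jac * beta))


@dataclass(frozen=True)
class TissueVolumeSeries:
    """Regional tissue volume tracked across the four study phases.

    TV_i are absolute tissue volumes (mm^3) at baseline and the three
    post-lavage phases; TVC_i = TV_i - TV_0 (mm^3) and
    TVCR_i = 100 * TVC_i / TV_0 (percent).
    """

    region: str
    tv: tuple[float, float, float, float]

    def __post_init__(self):
        tv = tuple(float(v) for v in self.tv)
        if len(tv) != 4:
            raise ValueError("expected four tissue volumes (TV0..TV3)")
        object.__setattr__(self, "tv", tv)

    @property
    def tvc(self) -> tuple[float, float, float]:
        return tuple(v - self.tv[0] for v in self.tv[1:])  # type: ignore[return-value]

    @property
    def tvcr_percent(self) -> tuple[float, float, float]:
        return tuple(100.0 * c / self.tv[0] for c in self.tvc)  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        row = {"region": self.region}
        for i, v in enumerate(self.tv):
            row[f"TV{i}"] = v
        for i, v in enumerate(self.tvc, start=1):
            row[f"TVC{i}"] = v
        for i, v in enumerate(self.tvcr_percent, start=1):
            row[f"TVCR{i}"] = v
        return pd.DataFrame([row])


def tissue_volume_series(
    tv0: float, tv1: float, tv2: float, tv3: float, region: str = "region"
) -> TissueVolumeSeries:
    """Build a :class:`TissueVolumeSeries`; requires a positive baseline volume."""
    if not tv0 > 0:
        raise DegenerateInputError("baseline tissue volume TV0 must be positive")
    return TissueVolumeSeries(region=region, tv=(tv0, tv1, tv2, tv3))
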