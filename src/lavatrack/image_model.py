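"""Volume, mask and landmark containers with file I/O and resampling.

Volumes are axis-aligned 3D scalar lattices in Hounsfield units (HU).
The world coordinate of voxel index ``(i1, i2, i3)`` (0-based) is
``origin + index * spacing`` in millimetres; array axis ``k`` of
``values`` corresponds to ``spacing[k]``.  Oblique orientation matrices
are rejected rather than silently handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ScalarVolume3D",
    "BinaryMask3D",
    "LandmarkSet",
    "FormatError",
    "DegenerateInputError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "downsample_by_two",
    "downsample_mask_by_two",
    "histogram_match",
    "resample_through_transform",
    "sample_at_world",
]

AIR_HU = -1000.0  # out-of-bounds fill: pure air, the background of chest CT


class FormatError(ValueError):
    """Unreadable, ambiguous or invariant-violating file header."""


class DegenerateInputError(ValueError):
    """Input violates a precondition (empty mask, too-small lattice, ...)."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class ScalarVolume3D:
    """HU-valued scalar field on a regular axis-aligned lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if values.ndim != 3:
            raise FormatError(f"expected a 3D array, got ndim={values.ndim}")
        if any(n < 1 for n in values.shape):
            raise FormatError(f"empty lattice: {values.shape}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3 (the v(x) of the mixture model)."""
        s = self.spacing
        return s[0] * s[1] * s[2]

    @property
    def geometry(self) -> tuple[tuple[int, int, int], tuple[float, float, float], tuple[float, float, float]]:
        return self.shape, self.spacing, self.origin

    def same_geometry(self, other: "ScalarVolume3D | BinaryMask3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-coordinate bounds spanned by the voxel centres, mm."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def lattice_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n1, n2, n3, 3)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) index coordinates of world points."""
        pts = np.asarray(points, dtype=np.float64)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=np.float64) * np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "ScalarVolume3D":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass(frozen=True)
class BinaryMask3D:
    """Voxel membership flags on a lattice geometrically identical to a volume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values).astype(bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if values.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    # geometry helpers shared with ScalarVolume3D
    shape = ScalarVolume3D.shape
    voxel_volume = ScalarVolume3D.voxel_volume
    geometry = ScalarVolume3D.geometry
    same_geometry = ScalarVolume3D.same_geometry
    bounds = ScalarVolume3D.bounds
    lattice_points = ScalarVolume3D.lattice_points
    world_to_index = ScalarVolume3D.world_to_index
    index_to_world = ScalarVolume3D.index_to_world

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if self.count == 0:
            raise DegenerateInputError(f"{what} is empty")

    def union(self, other: "BinaryMask3D") -> "BinaryMask3D":
        return replace(self, values=self.values | other.values)

    def intersection(self, other: "BinaryMask3D") -> "BinaryMask3D":
        return replace(self, values=self.values & other.values)

    def difference(self, other: "BinaryMask3D") -> "BinaryMask3D":
        return replace(self, values=self.values & ~other.values)


@dataclass(frozen=True)
class LandmarkSet:
    """Labelled 3D points in world millimetres."""

    labels: tuple[str, ...]
    points: np.ndarray  # (n, 3) world mm

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(labels) != len(points):
            raise ValueError("labels and points differ in length")
        if len(set(labels)) != len(labels):
            raise ValueError("landmark labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", points)

    def __len__(self) -> int:
        return len(self.labels)

    def transformed(self, func) -> "LandmarkSet":
        """Map every point through ``func`` (an (n,3)->(n,3) callable)."""
        return LandmarkSet(self.labels, np.asarray(func(self.points)))

    @classmethod
    def read_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        expected = ["label", "x_mm", "y_mm", "z_mm"]
        if list(df.columns[:4]) != expected:
            raise FormatError(f"landmark CSV must have columns {expected}")
        return cls(tuple(df["label"].astype(str)), df[["x_mm", "y_mm", "z_mm"]].to_numpy())

    def write_csv(self, path) -> None:
        df = pd.DataFrame(self.points, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {path.name!r}; "
            f"expected one of {_SUPPORTED_SUFFIXES}"
        )


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D image, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError("oblique/non-identity direction matrices are not supported")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive spacing in header: {spacing}")
    # SimpleITK arrays are indexed [z, y, x]; transpose so axis k matches spacing[k]
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(spacing), tuple(img.GetOrigin())


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def read_volume(path) -> ScalarVolume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) HU volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable/ambiguous header
        raise FormatError(f"could not read {path}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    if any(n < 2 for n in arr.shape):
        raise FormatError(f"lattice dimensions must be >= 2, got {arr.shape}")
    return ScalarVolume3D(arr.astype(np.float64), spacing, origin)


def write_volume(vol: ScalarVolume3D, path) -> None:
    path = Path(path)
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(vol.values, vol.spacing, vol.origin), str(path))


def read_mask(path) -> BinaryMask3D:
    vol = read_volume(path)
    return BinaryMask3D(vol.values > 0.5, vol.spacing, vol.origin)


def write_mask(mask: BinaryMask3D, path) -> None:
    path = Path(path)
    _check_suffix(path)
    sitk.WriteImage(_to_sitk(mask.values.astype(np.uint8), mask.spacing, mask.origin), str(path))


# ---------------------------------------------------------------------------
# resampling and intensity normalisation
# ---------------------------------------------------------------------------


def downsample_by_two(vol: ScalarVolume3D) -> ScalarVolume3D:
    """Halve each dimension by 2x2x2 block averaging; spacing doubles.

    Trailing slices of odd dimensions are dropped (floor halving).  The new
    origin sits at the centre of each contributing block, half the old
    spacing beyond the old origin.
    """
    if any(n < 2 for n in vol.shape):
        raise DegenerateInputError(f"cannot halve dimensions {vol.shape}")
    n = [d // 2 for d in vol.shape]
    v = vol.values[: 2 * n[0], : 2 * n[1], : 2 * n[2]]
    blocks = v.reshape(n[0], 2, n[1], 2, n[2], 2)
    out = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(2 * s for s in vol.spacing)
    origin = tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing))
    return ScalarVolume3D(out, spacing, origin)


def downsample_mask_by_two(mask: BinaryMask3D) -> BinaryMask3D:
    """Majority-vote halving of a mask (block mean >= 0.5)."""
    vol = ScalarVolume3D(mask.values.astype(np.float64), mask.spacing, mask.origin)
    half = downsample_by_two(vol)
    return BinaryMask3D(half.values >= 0.5, half.spacing, half.origin)


def histogram_match(
    template: ScalarVolume3D,
    target: ScalarVolume3D,
    template_mask: BinaryMask3D,
    target_mask: BinaryMask3D,
    n_quantiles: int = 128,
) -> ScalarVolume3D:
    """Monotone remapping of template intensities onto the target's masked histogram.

    Quantile landmarks of the masked template intensities are mapped onto the
    corresponding masked target quantiles with a piecewise-linear, monotone
    non-decreasing transfer function.  Voxels outside ``template_mask`` are
    left unchanged.  The result depends only on masked intensities and is
    invariant to voxel ordering.
    """
    template_mask.require_nonempty("template mask")
    target_mask.require_nonempty("target mask")
    q = np.linspace(0.0, 1.0, n_quantiles)
    src = np.quantile(template.values[template_mask.values], q)
    dst = np.quantile(target.values[target_mask.values], q)
    # enforce monotone non-decreasing knots (quantiles already are, up to ties)
    src = np.maximum.accumulate(src)
    dst = np.maximum.accumulate(dst)
    out = template.values.copy()
    inside = template_mask.values
    out[inside] = np.interp(template.values[inside], src, dst)
    return template.with_values(out)


def sample_at_world(
    vol: ScalarVolume3D, points: np.ndarray, fill: float = AIR_HU
) -> np.ndarray:
    """Trilinear interpolation of ``vol`` at world points; out-of-bounds -> fill."""
    idx = vol.world_to_index(np.asarray(points, dtype=np.float64))
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        vol.values, coords, order=1, mode="constant", cval=fill, prefilter=False
    )


def resample_through_transform(
    template: ScalarVolume3D,
    transform,
    target_geometry: "ScalarVolume3D | BinaryMask3D",
    fill: float = AIR_HU,
) -> ScalarVolume3D:
    """Pull the template image back onto the target lattice through ``transform``.

    ``transform`` maps target-lattice world points x to template world points
    h(x); the output voxel value at x is the trilinear sample of the template
    at h(x).  Out-of-bounds samples take the fill value (-1000 HU, pure air).
    """
    ref = target_geometry
    pts = ref.lattice_points().reshape(-1, 3)
    mapped = transform.map_points(pts)
    vals = sample_at_world(template, mapped, fill=fill)
    shape = ref.shape
    return ScalarVolume3D(vals.reshape(shape), ref.spacing, ref.origin)
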