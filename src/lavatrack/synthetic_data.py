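"""Seedable 4-phase, two-inflation lung phantom studies with ground truth.

The phantom emulates the structure of a serial lavage CT study: an
ellipsoidal lung of air/tissue-mixture parenchyma inside a soft-tissue
body, a bright three-level bifurcating vessel tree whose branch points
serve as landmarks, and a spherical lavage region whose non-air content is
raised by a known fluid volume that decays across the post phases.

All deformations are smooth analytic warps (a global anisotropic
contraction for inspiration-to-expiration, plus random Gaussian-bump
displacements), numerically invertible by fixed-point iteration.  Images
at deformed states are synthesised tissue-preservingly: the tissue volume
of every material element is conserved through the warp (intensity divided
by the local Jacobian, in mixture-fraction units), so the tissue-volume
similarity between a generated FRC/TLC pair is exactly zero at the
ground-truth transform up to interpolation and clamping.

Reduced post-lavage breathing effort is emulated by a global shrink factor
on the intra-phase displacement, and regionally suppressed function by a
Gaussian attenuation of the displacement centred on the lavage region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import BinaryMask3D, LandmarkSet, ScalarVolume3D
from .mixture_model import (
    DEFAULT_MIXTURE,
    MixtureConstants,
    hu_from_tissue_fraction,
    tissue_fraction,
)
from .tracking_analysis import PHASES, POST_PHASES, PhaseScans, PhaseStudy

__all__ = [
    "PhantomSpec",
    "AnalyticWarp",
    "generate_phantom_study",
    "apply_tissue_preserving_warp",
]

_CT_MIN, _CT_MAX = -1024.0, 3071.0


class AnalyticWarp:
    """y = x + m(x) * [ (A - I)(x - c) + sum_k a_k exp(-|x - b_k|^2 / 2 s_k^2) ].

    A smooth invertible warp: an affine part about centre ``c`` plus
    Gaussian-bump displacements, optionally attenuated by a global effort
    factor and a Gaussian suppression well (both folded into m(x)).  The
    Jacobian is evaluated by central differences of the analytic map and the
    inverse by fixed-point (Picard) iteration on the displacement.
    """

    def __init__(
        self,
        scale=(1.0, 1.0, 1.0),
        center=(0.0, 0.0, 0.0),
        bumps=(),  # iterable of (center(3,), sigma_mm, amplitude(3,))
        effort: float = 1.0,
        suppression: "tuple | None" = None,  # (center(3,), sigma_mm, strength)
        gradient: "tuple | None" = None,  # (axis, relative amplitude per mm)
    ):
        self.scale = np.asarray(scale, dtype=np.float64)
        self.center = np.asarray(center, dtype=np.float64)
        self.bumps = [
            (np.asarray(b, np.float64), float(s), np.asarray(a, np.float64))
            for b, s, a in bumps
        ]
        self.effort = float(effort)
        self.suppression = suppression
        self.gradient = gradient

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        u = (pts - self.center) * (self.scale - 1.0)
        for b, s, a in self.bumps:
            w = np.exp(-np.sum((pts - b) ** 2, axis=-1) / (2.0 * s**2))
            u = u + w[..., None] * a
        m = np.full(pts.shape[:-1] + (1,), self.effort)
        if self.gradient is not None:
            axis, rel = self.gradient
            m = m * (1.0 + rel * (pts[..., axis] - self.center[axis]))[..., None]
        if self.suppression is not None:
            c, s, k = self.suppression
            well = np.exp(
                -np.sum((pts - np.asarray(c)) ** 2, axis=-1) / (2.0 * float(s) ** 2)
            )
            m = m * (1.0 - float(k) * well[..., None])
        return u * m

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) + self.displacement(pts)

    def inverse_points(self, pts: np.ndarray, tol=1e-9, max_iter=200) -> np.ndarray:
        """Solve y = h(x) for x by Picard iteration (displacement contraction)."""
        y = np.asarray(pts, dtype=np.float64)
        x = y.copy()
        for _ in range(max_iter):
            x_new = y - self.displacement(x)
            if np.max(np.abs(x_new - x)) < tol:
                return x_new
            x = x_new
        return x

    def jacobian_at(self, pts: np.ndarray, step: float = 1e-3) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        d = np.empty(pts.shape[:-1] + (3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = step
            d[..., :, j] = (self.map_points(pts + e) - self.map_points(pts - e)) / (
                2.0 * step
            )
        return np.linalg.det(d)


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(pts - a - t[:, None] * ab, axis=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, deformation and fluid parameters of the phantom.

    Defaults give a desk-scale study: a 96^3 lattice at 2 mm spacing, a
    ~0.7 L ellipsoidal lung of -850 HU parenchyma at TLC, 0 HU vessels of
    1.5-4 mm radius, and 15 / 7.5 / 1.5 mL of lavage fluid at the three post
    phases (a resolution pattern of roughly 14% -> 7% -> 2% of the lavage
    region's baseline tissue volume scale).  The intra-phase contraction has
    Jacobian ~0.61, placing FRC parenchyma near -750 HU, with peak
    displacement just under 10 mm.
    """

    dims: tuple[int, int, int] = (96, 96, 96)
    texture_amp_beta: float = 0.03
    n_texture_blobs: int = 60
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_semiaxes_mm: tuple[float, float, float] = (50.0, 55.0, 60.0)
    body_margin_mm: float = 14.0
    parenchyma_hu_tlc: float = -850.0
    body_hu: float = 40.0
    vessel_hu: float = 0.0
    vessel_root_radius_mm: float = 4.0
    vessel_levels: int = 2  # splits after the root branches
    n_root_branches: int = 3
    lavage_offset_mm: tuple[float, float, float] = (14.0, 12.0, -10.0)
    lavage_radius_mm: float = 22.0
    fluid_volumes_ml: tuple[float, float, float] = (15.0, 7.5, 1.5)
    intra_scale: tuple[float, float, float] = (0.86, 0.85, 0.84)
    intra_bump_mm: float = 0.5
    inter_bump_mm: float = 2.0
    n_bumps: int = 3
    vent_gradient_per_mm: float = 0.004  # dorsoventral ventilation gradient
    vent_gradient_axis: int = 2
    efforts: tuple[float, float, float, float] = (1.0, 0.85, 0.95, 1.0)
    suppression: tuple[float, float, float, float] = (0.0, 0.35, 0.15, 0.0)
    noise_sd_hu: float = 0.0
    seed: int = 17

    def __post_init__(self):
        for hu in (self.parenchyma_hu_tlc, self.body_hu, self.vessel_hu):
            if not _CT_MIN <= hu <= _CT_MAX:
                raise ValueError(f"HU value {hu} outside the CT range")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be nonnegative")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.dims) - 1) * np.asarray(self.spacing_mm) / 2.0

    @property
    def lavage_center_mm(self) -> np.ndarray:
        return self.center_mm + np.asarray(self.lavage_offset_mm)


class _PhantomGeometry:
    """Analytic baseline-TLC evaluators: membership and HU at world points."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator,
                 c: MixtureConstants):
        self.spec = spec
        self.c = c
        self.center = spec.center_mm
        self.lung_ax = np.asarray(spec.lung_semiaxes_mm)
        self.body_ax = self.lung_ax + spec.body_margin_mm
        self.beta_par = float(tissue_fraction(spec.parenchyma_hu_tlc, c))
        self.beta_vessel = float(tissue_fraction(spec.vessel_hu, c))
        self.segments, self.junctions = self._grow_tree(rng)
        # material-attached parenchymal density heterogeneity: smooth random
        # Gaussian blobs in tissue-fraction units, carried with the tissue
        n = spec.n_texture_blobs
        self.tex_centers = self.center + rng.uniform(-0.85, 0.85, (n, 3)) * self.lung_ax
        self.tex_sigmas = rng.uniform(5.0, 14.0, n)
        self.tex_amps = rng.normal(0.0, spec.texture_amp_beta, n)

    def _grow_tree(self, rng):
        spec = self.spec
        segments = []  # (a, b, radius)
        junctions = []
        root = self.center.copy()
        lengths = (0.55, 0.42, 0.32)  # fraction of mean semi-axis per level
        mean_ax = float(self.lung_ax.mean())

        def inside_frac(p):
            return np.sum(((p - self.center) / self.lung_ax) ** 2)

        def grow(start, direction, level, radius):
            length = lengths[min(level, len(lengths) - 1)] * mean_ax
            end = start + direction * length
            # keep endpoints well inside the lung
            for _ in range(20):
                if inside_frac(end) < 0.70:
                    break
                end = start + (end - start) * 0.85
            segments.append((start, end, radius))
            if level < spec.vessel_levels:
                junctions.append(end)
                for _ in range(2):
                    d = direction + rng.normal(0.0, 0.45, 3)
                    d /= np.linalg.norm(d)
                    grow(end, d, level + 1, radius * 0.65)

        for _ in range(spec.n_root_branches):
            d = rng.normal(0.0, 1.0, 3)
            d /= np.linalg.norm(d)
            grow(root, d, 0, spec.vessel_root_radius_mm)
        return segments, np.asarray(junctions)

    def in_lung(self, pts: np.ndarray) -> np.ndarray:
        return np.sum(((pts - self.center) / self.lung_ax) ** 2, axis=-1) <= 1.0

    def in_body(self, pts: np.ndarray) -> np.ndarray:
        return np.sum(((pts - self.center) / self.body_ax) ** 2, axis=-1) <= 1.0

    def in_lavage(self, pts: np.ndarray) -> np.ndarray:
        d2 = np.sum((pts - self.spec.lavage_center_mm) ** 2, axis=-1)
        return d2 <= self.spec.lavage_radius_mm**2

    def in_vessel(self, pts: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pts), dtype=bool)
        for a, b, r in self.segments:
            hit |= _segment_distance(pts, a, b) <= r
        return hit

    def texture(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts))
        for ct, s, a in zip(self.tex_centers, self.tex_sigmas, self.tex_amps):
            out += a * np.exp(-np.sum((pts - ct) ** 2, axis=1) / (2.0 * s**2))
        return out

    def beta_parenchyma(self, pts: np.ndarray) -> np.ndarray:
        """Parenchymal tissue fraction with density heterogeneity, at world points."""
        return np.clip(self.beta_par + self.texture(pts), 0.02, 0.60)

    def beta_base(self, pts: np.ndarray) -> np.ndarray:
        """Baseline-TLC tissue fraction at arbitrary world points (lung only)."""
        beta = self.beta_parenchyma(pts)
        beta[self.in_vessel(pts)] = self.beta_vessel
        return beta

    def background_hu(self, pts: np.ndarray) -> np.ndarray:
        hu = np.full(len(pts), self.c.hu_air)
        hu[self.in_body(pts)] = self.spec.body_hu
        return hu


def apply_tissue_preserving_warp(
    vol: ScalarVolume3D, h_known, c: MixtureConstants = DEFAULT_MIXTURE
) -> ScalarVolume3D:
    """Warp an image so per-voxel tissue volume is conserved through h.

    The output on the input lattice satisfies
    beta(I_out(x)) = J(h(x)) * beta(I_in(h(x))) (clamped to the mixture
    range), i.e. the tissue-volume relation v1(h(x)) = v2(x) * J(h(x)) holds
    exactly up to interpolation.  ``h_known`` must be invertible on the
    domain (positive Jacobian).
    """
    from .image_model import sample_at_world

    pts = vol.lattice_points().reshape(-1, 3)
    mapped = h_known.map_points(pts)
    jac = h_known.jacobian_at(pts)
    if np.any(jac <= 0):
        raise ValueError("h_known is not invertible on the image domain")
    hu_in = sample_at_world(vol, mapped, fill=c.hu_air)
    beta = np.clip(jac * tissue_fraction(hu_in, c), 0.0, 1.0)
    out = hu_from_tissue_fraction(beta, c).reshape(vol.shape)
    return vol.with_values(out)


def generate_phantom_study(spec: PhantomSpec) -> PhaseStudy:
    """Build the eight-scan phantom study with attached ground truth.

    Identical seeds give bit-identical studies.  ``study.truth`` carries the
    analytic warps (``intra_warps`` mapping each phase's TLC lattice into its
    FRC image; ``inter_warps`` mapping the baseline TLC lattice into each
    post TLC image), the per-phase fluid volumes (mm^3), and noise-free
    copies of every image.
    """
    c = DEFAULT_MIXTURE
    rng = np.random.default_rng(spec.seed)
    geom = _PhantomGeometry(spec, rng, c)
    ref = ScalarVolume3D(
        np.zeros(spec.dims), spec.spacing_mm
    )  # lattice geometry carrier
    pts = ref.lattice_points().reshape(-1, 3)
    vox = ref.voxel_volume

    def make_bumps(amp):
        if amp == 0.0 or spec.n_bumps == 0:
            return ()
        centers = geom.center + rng.uniform(-0.5, 0.5, (spec.n_bumps, 3)) * geom.lung_ax
        sigmas = rng.uniform(18.0, 30.0, spec.n_bumps)
        amps = rng.normal(0.0, amp / np.sqrt(3.0), (spec.n_bumps, 3))
        return tuple((ct, s, a) for ct, s, a in zip(centers, sigmas, amps))

    # ground-truth warps -----------------------------------------------------
    inter_warps: dict[str, AnalyticWarp] = {}
    intra_warps: dict[str, AnalyticWarp] = {}
    lavage_centers: dict[str, np.ndarray] = {"base": spec.lavage_center_mm}
    for phase in POST_PHASES:
        w = AnalyticWarp(center=geom.center, bumps=make_bumps(spec.inter_bump_mm))
        inter_warps[phase] = w
        lavage_centers[phase] = w.map_points(spec.lavage_center_mm[None, :])[0]
    for i, phase in enumerate(PHASES):
        supp = None
        if spec.suppression[i] > 0:
            supp = (lavage_centers[phase], spec.lavage_radius_mm, spec.suppression[i])
        intra_warps[phase] = AnalyticWarp(
            scale=spec.intra_scale,
            center=geom.center,
            bumps=make_bumps(spec.intra_bump_mm),
            effort=spec.efforts[i],
            suppression=supp,
            gradient=(spec.vent_gradient_axis, spec.vent_gradient_per_mm),
        )

    # lavage fluid as a uniform tissue-fraction increment over the airspace
    # (non-vessel) voxels of the base lavage sphere
    in_lavage_base = geom.in_lavage(pts) & geom.in_lung(pts)
    n_deposit = int((in_lavage_base & ~geom.in_vessel(pts)).sum())
    fluid_mm3 = {
        phase: 1000.0 * v for phase, v in zip(POST_PHASES, spec.fluid_volumes_ml)
    }
    delta_beta = {phase: f / (vox * n_deposit) for phase, f in fluid_mm3.items()}
    beta_free = 1.0 - (geom.beta_par + max(delta_beta.values()))
    if beta_free < 0:
        raise ValueError("fluid volume exceeds the lavage region's air capacity")

    def synthesise(phase: str, inflation: str):
        """Image, lung mask and landmarks for one scan, noise-free.

        The scan's forward map from baseline material coordinates is
        xb -(w_phase)-> TLC coords -(c_phase)-> FRC coords; lattice points
        are pulled back through the inverse chain and the forward Jacobians
        multiply along it.
        """
        if inflation == "frc":
            x_tlc = intra_warps[phase].inverse_points(pts)
        else:
            x_tlc = pts
        if phase == "base":
            xb = x_tlc
            jac = np.ones(len(pts))
        else:
            xb = inter_warps[phase].inverse_points(x_tlc)
            jac = inter_warps[phase].jacobian_at(xb)
        if inflation == "frc":
            jac = jac * intra_warps[phase].jacobian_at(x_tlc)

        in_lung = geom.in_lung(xb)
        hu = geom.background_hu(xb)
        if in_lung.any():
            vessel = geom.in_vessel(xb[in_lung])
            beta = np.where(
                vessel, geom.beta_vessel, geom.beta_parenchyma(xb[in_lung])
            )
            if phase != "base":
                beta = beta + delta_beta[phase] * (
                    geom.in_lavage(xb[in_lung]) & ~vessel
                )
            beta = np.clip(beta / jac[in_lung], 0.0, 1.0)
            hu[in_lung] = hu_from_tissue_fraction(beta, c)
        img = ScalarVolume3D(hu.reshape(spec.dims), spec.spacing_mm)
        mask = BinaryMask3D(in_lung.reshape(spec.dims), spec.spacing_mm)

        lm = geom.junctions
        if phase != "base":
            lm = inter_warps[phase].map_points(lm)
        if inflation == "frc":
            lm = intra_warps[phase].map_points(lm)
        labels = tuple(f"bif{i:02d}" for i in range(len(lm)))
        return img, mask, LandmarkSet(labels, lm)

    scans: dict[str, PhaseScans] = {}
    noise_free: dict[str, dict[str, ScalarVolume3D]] = {}
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    for phase in PHASES:
        tlc, tlc_mask, tlc_lm = synthesise(phase, "tlc")
        frc, frc_mask, frc_lm = synthesise(phase, "frc")
        noise_free[phase] = {"tlc": tlc, "frc": frc}
        if spec.noise_sd_hu > 0:
            tlc = tlc.with_values(
                tlc.values + noise_rng.normal(0.0, spec.noise_sd_hu, tlc.shape)
            )
            frc = frc.with_values(
                frc.values + noise_rng.normal(0.0, spec.noise_sd_hu, frc.shape)
            )
        scans[phase] = PhaseScans(
            tlc=tlc, frc=frc, tlc_mask=tlc_mask, frc_mask=frc_mask,
            tlc_landmarks=tlc_lm, frc_landmarks=frc_lm,
        )

    lavage_mask = BinaryMask3D(in_lavage_base.reshape(spec.dims), spec.spacing_mm)

    # validate that the ground-truth warps are diffeomorphic on the lung
    lung_pts = pts[geom.in_lung(pts)][:: max(1, n_deposit // 2000)]
    for warp in list(inter_warps.values()) + list(intra_warps.values()):
        if np.any(warp.jacobian_at(lung_pts) <= 0):
            raise ValueError("ground-truth warp is not injective on the lung")

    return PhaseStudy(
        scans=scans,
        lavage_mask=lavage_mask,
        truth={
            "spec": spec,
            "inter_warps": inter_warps,
            "intra_warps": intra_warps,
            "fluid_mm3": fluid_mm3,
            "delta_beta": delta_beta,
            "noise_free": noise_free,
        },
    )
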