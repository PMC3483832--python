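"""Intra-phase (RTVP) and inter-phase (RIVP) deformable registration.

Both algorithms estimate a cubic B-spline transform h defined on the target
(fixed) image lattice, mapping into the template (moving) image, by
minimising a weighted cost

    RTVP:  C = C_SSTVD + chi * C_SSVMD + gamma * C_LAP
    RIVP:  C = C_SSD   + chi * C_SSVMD + gamma * C_LAP

where C_SSTVD penalises per-voxel tissue-volume mismatch between the two
inflation levels (with v1(h(x)) = v2(x) * J(h(x)) relating voxel volumes
through the Jacobian determinant), C_SSD is plain intensity mismatch after
histogram matching (valid between same-inflation scans whose tissue content
differs because of lavage fluid), C_SSVMD aligns Frangi vesselness maps,
and C_LAP is the squared component-wise Laplacian of the displacement.

Optimisation is bounded limited-memory quasi-Newton (L-BFGS-B) over a
coarse-to-fine image pyramid with an alternately refined control grid; the
coefficient box bounds are the Choi-Lee injectivity fraction of the grid
spacing, so every returned transform has a strictly positive Jacobian.
Gradients are analytic: chain rule through the B-spline basis, the exact
derivative of the trilinear interpolant, and the cofactor expansion of the
Jacobian determinant.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .bspline_transform import BSplineTransform, injectivity_bound
from .image_model import (
    AIR_HU,
    BinaryMask3D,
    ScalarVolume3D,
    downsample_by_two,
    downsample_mask_by_two,
    histogram_match,
)
from .mixture_model import DEFAULT_MIXTURE, MixtureConstants, tissue_fraction
from .vesselness import FrangiParams, VesselnessVolume, multiscale_vesselness

__all__ = [
    "RegistrationConfig",
    "CostBreakdown",
    "RegistrationResult",
    "cost_sstvd",
    "cost_ssvmd",
    "cost_ssd",
    "cost_laplacian",
    "total_cost",
    "compute_omega",
    "register",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Mode, cost weights, pyramid schedule and optimizer settings."""

    mode: str  # "rtvp" | "rivp"
    chi: float
    gamma_reg: float
    levels: tuple[int, ...] = (3, 2, 1, 0)  # downsample exponents, coarse -> fine
    finest_grid_mm: float = 8.0
    max_iter: int = 200
    tol: float = 1e-5
    memory: int = 10
    frangi: FrangiParams = field(default_factory=FrangiParams)
    mixture: MixtureConstants = field(default_factory=MixtureConstants)
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("rtvp", "rivp"):
            raise ValueError("mode must be 'rtvp' or 'rivp'")
        if self.chi < 0 or self.gamma_reg < 0:
            raise ValueError("weights must be nonnegative")
        levels = tuple(int(l) for l in self.levels)
        if any(b > a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must go coarse to fine (non-increasing)")
        object.__setattr__(self, "levels", levels)
        if self.finest_grid_mm <= 0:
            raise ValueError("finest grid spacing must be positive")

    @classmethod
    def rtvp(cls, **kw) -> "RegistrationConfig":
        """Tissue-volume-preserving intra-phase defaults (chi=1, gamma=0.01)."""
        kw.setdefault("chi", 1.0)
        kw.setdefault("gamma_reg", 0.01)
        return cls(mode="rtvp", **kw)

    @classmethod
    def rivp_defaults(cls, **kw) -> "RegistrationConfig":
        """Intensity-preserving inter-phase defaults (chi=2, gamma=10)."""
        kw.setdefault("chi", 2.0)
        kw.setdefault("gamma_reg", 10.0)
        return cls(mode="rivp", **kw)

    def grid_schedule(self) -> tuple[float, ...]:
        """Grid spacing per pyramid level: starts at 4x the finest spacing and
        halves alternately with the image levels, ending at the finest."""
        n = len(self.levels)
        return tuple(
            self.finest_grid_mm * 2 ** max(0, min(2, n - 2 - i)) for i in range(n)
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Total cost and its three components; total = sim + chi*ssvmd + gamma*lap."""

    similarity: float
    ssvmd: float
    laplacian: float
    chi: float
    gamma_reg: float

    @property
    def total(self) -> float:
        return self.similarity + self.chi * self.ssvmd + self.gamma_reg * self.laplacian


@dataclass
class LevelReport:
    downsample: int
    grid_spacing_mm: float
    n_parameters: int
    n_iterations: int
    initial_cost: float
    final_cost: float
    converged: bool
    history: list[float]
    wall_time_s: float

    @property
    def decreased(self) -> bool:
        return self.final_cost <= self.initial_cost + 1e-12


@dataclass
class RegistrationResult:
    transform: BSplineTransform
    breakdown: CostBreakdown
    levels: list[LevelReport]
    convergence_failure: bool
    min_jacobian: float = float("nan")
    landmark_error_before_mm: np.ndarray | None = None
    landmark_error_after_mm: np.ndarray | None = None

    @property
    def mean_landmark_error_before(self) -> float | None:
        e = self.landmark_error_before_mm
        return None if e is None else float(np.mean(e))

    @property
    def mean_landmark_error_after(self) -> float | None:
        e = self.landmark_error_after_mm
        return None if e is None else float(np.mean(e))


# ---------------------------------------------------------------------------
# trilinear sampling with exact interpolant gradient
# ---------------------------------------------------------------------------


def _trilinear(arr, idx, spacing, fill, want_grad=True):
    """Sample ``arr`` at continuous indices (n, 3); returns value and the exact
    gradient of the trilinear interpolant in world units (mm^-1)."""
    n = np.asarray(arr.shape)
    eps = 1e-9
    inb = np.all((idx >= -eps) & (idx <= n - 1 + eps), axis=1)
    ic = np.clip(np.floor(idx).astype(np.int64), 0, n - 2)
    f = idx - ic  # in [0, 1] on the last in-bounds plane
    i0, i1, i2 = ic[:, 0], ic[:, 1], ic[:, 2]
    f0, f1, f2 = f[:, 0], f[:, 1], f[:, 2]
    c = [
        [
            [arr[i0 + d0, i1 + d1, i2 + d2] for d2 in (0, 1)]
            for d1 in (0, 1)
        ]
        for d0 in (0, 1)
    ]
    # collapse axis 2
    b = [[c[d0][d1][0] * (1 - f2) + c[d0][d1][1] * f2 for d1 in (0, 1)] for d0 in (0, 1)]
    g2 = [[c[d0][d1][1] - c[d0][d1][0] for d1 in (0, 1)] for d0 in (0, 1)]
    # collapse axis 1
    e = [b[d0][0] * (1 - f1) + b[d0][1] * f1 for d0 in (0, 1)]
    g2e = [g2[d0][0] * (1 - f1) + g2[d0][1] * f1 for d0 in (0, 1)]
    g1 = [b[d0][1] - b[d0][0] for d0 in (0, 1)]
    # collapse axis 0
    val = e[0] * (1 - f0) + e[1] * f0
    val = np.where(inb, val, fill)
    if not want_grad:
        return val, None
    grad = np.empty((len(val), 3))
    grad[:, 0] = (e[1] - e[0]) / spacing[0]
    grad[:, 1] = (g1[0] * (1 - f0) + g1[1] * f0) / spacing[1]
    grad[:, 2] = (g2e[0] * (1 - f0) + g2e[1] * f0) / spacing[2]
    grad[~inb] = 0.0
    return val, grad


def _cofactors(d: np.ndarray) -> np.ndarray:
    """Cofactor matrices C with det(D) = sum_j D_ij C_ij, for (n, 3, 3) input."""
    c = np.empty_like(d)
    c[:, 0, 0] = d[:, 1, 1] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 1]
    c[:, 0, 1] = -(d[:, 1, 0] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 0])
    c[:, 0, 2] = d[:, 1, 0] * d[:, 2, 1] - d[:, 1, 1] * d[:, 2, 0]
    c[:, 1, 0] = -(d[:, 0, 1] * d[:, 2, 2] - d[:, 0, 2] * d[:, 2, 1])
    c[:, 1, 1] = d[:, 0, 0] * d[:, 2, 2] - d[:, 0, 2] * d[:, 2, 0]
    c[:, 1, 2] = -(d[:, 0, 0] * d[:, 2, 1] - d[:, 0, 1] * d[:, 2, 0])
    c[:, 2, 0] = d[:, 0, 1] * d[:, 1, 2] - d[:, 0, 2] * d[:, 1, 1]
    c[:, 2, 1] = -(d[:, 0, 0] * d[:, 1, 2] - d[:, 0, 2] * d[:, 1, 0])
    c[:, 2, 2] = d[:, 0, 0] * d[:, 1, 1] - d[:, 0, 1] * d[:, 1, 0]
    return c


def _forward(w, coeffs):
    return np.einsum("ip,jq,kr,pqrc->ijkc", w[0], w[1], w[2], coeffs, optimize=True)


def _adjoint(w, fld):
    return np.einsum("ip,jq,kr,ijkc->pqrc", w[0], w[1], w[2], fld, optimize=True)


# ---------------------------------------------------------------------------
# public cost operations (reference path: generic transforms, no gradients)
# ---------------------------------------------------------------------------


def compute_omega(
    template_mask: BinaryMask3D, target_mask: BinaryMask3D, transform
) -> BinaryMask3D:
    """Union of the target lung mask and the deformed template lung mask."""
    pts = target_mask.lattice_points().reshape(-1, 3)
    mapped = transform.map_points(pts)
    idx = np.moveaxis(
        (mapped - np.asarray(template_mask.origin)) / np.asarray(template_mask.spacing),
        -1,
        0,
    )
    warped = ndimage.map_coordinates(
        template_mask.values.astype(np.float64), idx, order=1, mode="constant",
        cval=0.0, prefilter=False,
    ).reshape(target_mask.shape)
    return BinaryMask3D(
        target_mask.values | (warped >= 0.5), target_mask.spacing, target_mask.origin
    )


def _sample_through(vol: ScalarVolume3D, transform, omega: BinaryMask3D, fill: float):
    pts = omega.lattice_points()[omega.values]
    mapped = transform.map_points(pts)
    idx = vol.world_to_index(mapped)
    val, _ = _trilinear(vol.values, idx, vol.spacing, fill, want_grad=False)
    return pts, val


def cost_sstvd(
    template: ScalarVolume3D,
    target: ScalarVolume3D,
    transform,
    omega: BinaryMask3D,
    c: MixtureConstants = DEFAULT_MIXTURE,
) -> float:
    """Sum of squared tissue volume difference over omega."""
    omega.require_nonempty("omega")
    pts, hu1 = _sample_through(template, transform, omega, fill=c.hu_air)
    jac = transform.jacobian_at(pts)
    v2 = target.voxel_volume
    tv2 = v2 * tissue_fraction(target.values[omega.values], c)
    tv1 = v2 * jac * tissue_fraction(hu1, c)
    return float(np.sum((tv2 - tv1) ** 2))


def cost_ssvmd(
    f_template: "VesselnessVolume | ScalarVolume3D",
    f_target: "VesselnessVolume | ScalarVolume3D",
    transform,
    omega: BinaryMask3D,
) -> float:
    """Sum of squared vesselness measure difference over omega."""
    omega.require_nonempty("omega")
    fv1 = f_template.volume if isinstance(f_template, VesselnessVolume) else f_template
    fv2 = f_target.volume if isinstance(f_target, VesselnessVolume) else f_target
    _, f1 = _sample_through(fv1, transform, omega, fill=0.0)
    f2 = fv2.values[omega.values]
    return float(np.sum((f2 - f1) ** 2))


def cost_ssd(
    template: ScalarVolume3D,
    target: ScalarVolume3D,
    transform,
    omega: BinaryMask3D,
) -> float:
    """Sum of squared intensity difference over omega (template assumed
    histogram-matched to the target beforehand)."""
    omega.require_nonempty("omega")
    _, i1 = _sample_through(template, transform, omega, fill=AIR_HU)
    i2 = target.values[omega.values]
    return float(np.sum((i2 - i1) ** 2))


def cost_laplacian(transform: BSplineTransform, omega: BinaryMask3D) -> float:
    """Sum over omega of the squared component-wise Laplacian of u = h - id."""
    lap = np.zeros(tuple(omega.shape) + (3,))
    for a in range(3):
        derivs = [0, 0, 0]
        derivs[a] = 2
        lap += transform.displacement_on_lattice(omega, tuple(derivs))
    return float(np.sum(lap[omega.values] ** 2))


def total_cost(
    template: ScalarVolume3D,
    target: ScalarVolume3D,
    transform: BSplineTransform,
    cfg: RegistrationConfig,
    omega: BinaryMask3D,
    f_template: "VesselnessVolume | None" = None,
    f_target: "VesselnessVolume | None" = None,
) -> CostBreakdown:
    """Cost breakdown for the mode's total cost at a given transform.

    Vesselness volumes are computed on the fly (within omega) when not
    supplied.  For RIVP the template is expected to be histogram-matched
    already, as in the registration pipeline.
    """
    if f_template is None:
        f_template = multiscale_vesselness(template, cfg.frangi)
    if f_target is None:
        f_target = multiscale_vesselness(target, cfg.frangi)
    if cfg.mode == "rtvp":
        sim = cost_sstvd(template, target, transform, omega, cfg.mixture)
    else:
        sim = cost_ssd(template, target, transform, omega)
    vess = cost_ssvmd(f_template, f_target, transform, omega)
    lap = cost_laplacian(transform, omega)
    return CostBreakdown(sim, vess, lap, cfg.chi, cfg.gamma_reg)


# ---------------------------------------------------------------------------
# optimisation engine
# ---------------------------------------------------------------------------


class _LevelProblem:
    """Cost + analytic gradient for one pyramid level, vectorised over omega."""

    def __init__(
        self,
        template: ScalarVolume3D,
        target: ScalarVolume3D,
        omega: BinaryMask3D,
        f_template: np.ndarray,
        f_target: np.ndarray,
        transform: BSplineTransform,
        cfg: RegistrationConfig,
    ):
        self.cfg = cfg
        self.mode = cfg.mode
        self.shape = target.shape
        self.coeff_shape = transform.coeffs.shape
        self.grid_template = transform
        self.mask = omega.values
        self.pts = target.lattice_points()[self.mask]
        self.template = template
        # similarity residuals are kept on the dimensionless tissue-fraction
        # scale (per unit voxel volume for SSTVD; HU divided by the air-tissue
        # span for SSD) so the chi / gamma weights are unit-free and levels of
        # the pyramid are comparable
        self.v2 = 1.0
        c = cfg.mixture
        if self.mode == "rtvp":
            self.tmpl_arr = tissue_fraction(template.values, c)  # beta volume
            self.tmpl_fill = 0.0
            self.target_term = tissue_fraction(target.values[self.mask], c)
        else:
            self.tmpl_arr = (template.values - c.hu_air) / c.span
            self.tmpl_fill = 0.0
            self.target_term = (target.values[self.mask] - c.hu_air) / c.span
        self.f1 = f_template
        self.f2m = f_target[self.mask]
        # per-axis basis weight matrices for value / first / second derivatives
        self.w = [
            [transform.lattice_weights(target, tuple(d * (a == b) for b in range(3)))[a]
             for d in (0, 1, 2)]
            for a in range(3)
        ]
        self.n_eval = 0

    def _w(self, derivs):
        return [self.w[a][derivs[a]] for a in range(3)]

    def cost_and_grad(self, x: np.ndarray):
        cfg = self.cfg
        coeffs = x.reshape(self.coeff_shape)
        mask = self.mask
        plain = self._w((0, 0, 0))

        u = _forward(plain, coeffs)
        h = self.pts + u[mask]
        idx = self.template.world_to_index(h)

        grad = np.zeros(self.coeff_shape)

        # similarity + vesselness share the plain backprojection pattern
        p_field = np.zeros(tuple(self.shape) + (3,))

        if self.mode == "rtvp":
            dw = [self._w(tuple(1 * (b == j) for b in range(3))) for j in range(3)]
            d = np.empty((len(h), 3, 3))
            du_fields = []
            for j in range(3):
                duj = _forward(dw[j], coeffs)
                du_fields.append(duj)
                d[:, :, j] = duj[mask]
            d += np.eye(3)
            jac = (
                d[:, 0, 0] * (d[:, 1, 1] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 1])
                - d[:, 0, 1] * (d[:, 1, 0] * d[:, 2, 2] - d[:, 1, 2] * d[:, 2, 0])
                + d[:, 0, 2] * (d[:, 1, 0] * d[:, 2, 1] - d[:, 1, 1] * d[:, 2, 0])
            )
            cof = _cofactors(d)
            t1, g1 = _trilinear(self.tmpl_arr, idx, self.template.spacing, self.tmpl_fill)
            r = self.target_term - self.v2 * jac * t1
            f_sim = float(np.sum(r**2))
            # d f_sim / dh_c and / dD_cj
            coef_h = (-2.0 * r * self.v2 * jac)[:, None] * g1  # (n, 3)
            coef_d = (-2.0 * r * self.v2 * t1)[:, None, None] * cof  # (n, 3, 3)
            p_field[mask] += coef_h
            for j in range(3):
                q_field = np.zeros(tuple(self.shape) + (3,))
                q_field[mask] = coef_d[:, :, j]
                grad += _adjoint(dw[j], q_field)
        else:
            i1, gi1 = _trilinear(self.tmpl_arr, idx, self.template.spacing, self.tmpl_fill)
            r = self.target_term - i1
            f_sim = float(np.sum(r**2))
            p_field[mask] += (-2.0 * r)[:, None] * gi1

        # vesselness term
        fv1, gf1 = _trilinear(self.f1, idx, self.template.spacing, 0.0)
        s = self.f2m - fv1
        f_vess = float(np.sum(s**2))
        p_field[mask] += cfg.chi * (-2.0 * s)[:, None] * gf1

        grad += _adjoint(plain, p_field)

        # Laplacian regulariser
        f_lap = 0.0
        if cfg.gamma_reg > 0:
            d2w = [self._w(tuple(2 * (b == a) for b in range(3))) for a in range(3)]
            lap = np.zeros(tuple(self.shape) + (3,))
            for a in range(3):
                lap += _forward(d2w[a], coeffs)
            lap[~mask] = 0.0
            f_lap = float(np.sum(lap[mask] ** 2))
            lap *= 2.0
            for a in range(3):
                grad += cfg.gamma_reg * _adjoint(d2w[a], lap)

        self.n_eval += 1
        total = f_sim + cfg.chi * f_vess + cfg.gamma_reg * f_lap
        self.last_breakdown = CostBreakdown(f_sim, f_vess, f_lap, cfg.chi, cfg.gamma_reg)
        return total, grad.ravel()


def _pyramid(vol: ScalarVolume3D, level: int) -> ScalarVolume3D:
    for _ in range(level):
        vol = downsample_by_two(vol)
    return vol


def _pyramid_mask(mask: BinaryMask3D, level: int) -> BinaryMask3D:
    for _ in range(level):
        mask = downsample_mask_by_two(mask)
    return mask


def _landmark_errors(transform, target_lm, template_lm) -> np.ndarray:
    order = {lab: i for i, lab in enumerate(template_lm.labels)}
    truth = template_lm.points[[order[lab] for lab in target_lm.labels]]
    pred = transform.map_points(target_lm.points)
    return np.linalg.norm(pred - truth, axis=1)


class _IdentityTransform:
    def map_points(self, pts):
        return np.asarray(pts, dtype=np.float64)

    def jacobian_at(self, pts):
        return np.ones(np.asarray(pts).shape[:-1])


def register(
    template: ScalarVolume3D,
    target: ScalarVolume3D,
    template_mask: BinaryMask3D,
    target_mask: BinaryMask3D,
    cfg: RegistrationConfig,
    landmarks: "tuple | None" = None,
    feature_cache: dict | None = None,
) -> RegistrationResult:
    """Multiresolution bounded quasi-Newton registration of template onto target.

    ``landmarks``, when given, is a pair ``(on_target, truth_on_template)`` of
    :class:`~lavatrack.image_model.LandmarkSet`; errors before (identity) and
    after registration are reported in mm.  ``feature_cache`` optionally maps
    ``(content digest, level)`` to a precomputed vesselness array so repeated
    registrations against the same target reuse its features.
    For RIVP the template is histogram-matched to the target (within the lung
    masks) once at full resolution before the pyramid is built.
    """
    template_mask.require_nonempty("template mask")
    target_mask.require_nonempty("target mask")

    if cfg.mode == "rivp":
        template = histogram_match(template, target, template_mask, target_mask)

    levels = cfg.levels
    grids = cfg.grid_schedule()
    cache = feature_cache if feature_cache is not None else {}

    # pyramids
    tmpl_levels = {l: _pyramid(template, l) for l in set(levels)}
    targ_levels = {l: _pyramid(target, l) for l in set(levels)}
    tmask_levels = {l: _pyramid_mask(template_mask, l) for l in set(levels)}
    gmask_levels = {l: _pyramid_mask(target_mask, l) for l in set(levels)}

    # transform domain: cover every level's voxel centres on the target side
    los = np.array([targ_levels[l].bounds()[0] for l in set(levels)])
    his = np.array([targ_levels[l].bounds()[1] for l in set(levels)])
    lo, hi = los.min(axis=0), his.max(axis=0)

    transform = BSplineTransform.for_domain(lo, hi, grids[0])

    digests = {
        "template": hashlib.sha1(template.values.tobytes()).hexdigest(),
        "target": hashlib.sha1(target.values.tobytes()).hexdigest(),
    }

    def vesselness_of(which, vol, mask, level):
        key = (digests[which], cfg.frangi.scales_mm, level)
        if key not in cache:
            cache[key] = multiscale_vesselness(
                _pyramid(vol, level), cfg.frangi, mask=_pyramid_mask(mask, level)
            ).volume.values
        return cache[key]

    reports: list[LevelReport] = []
    for i, level in enumerate(levels):
        t0 = time.perf_counter()
        while max(transform.grid_spacing) > grids[i] * (1 + 1e-9):
            transform = transform.refined()
        tmpl, targ = tmpl_levels[level], targ_levels[level]
        f1 = vesselness_of("template", template, template_mask, level)
        f2 = vesselness_of("target", target, target_mask, level)
        omega = compute_omega(tmask_levels[level], gmask_levels[level], transform)
        problem = _LevelProblem(tmpl, targ, omega, f1, f2, transform, cfg)
        # Choi-Lee box on the per-level increment: the optimizer may move each
        # coefficient by at most 0.4 * grid spacing from the refined start
        bound = injectivity_bound(transform.grid_spacing)
        x0 = transform.coeffs.ravel()
        bounds_lo = x0 - np.broadcast_to(bound, transform.coeffs.shape).ravel()
        bounds_hi = x0 + np.broadcast_to(bound, transform.coeffs.shape).ravel()
        history: list[float] = []

        def fun(x):
            f, g = problem.cost_and_grad(x)
            problem.last_total = f
            return f, g

        f0, _ = fun(x0)
        res = optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(bounds_lo, bounds_hi)),
            callback=lambda xk: history.append(problem.last_total),
            options={
                "maxiter": cfg.max_iter,
                "ftol": cfg.tol,
                "maxcor": cfg.memory,
            },
        )
        transform = transform.with_coeffs(res.x.reshape(transform.coeffs.shape))
        problem.cost_and_grad(res.x)  # sync breakdown with the accepted coefficients
        reports.append(
            LevelReport(
                downsample=level,
                grid_spacing_mm=float(max(transform.grid_spacing)),
                n_parameters=transform.n_parameters,
                n_iterations=int(res.nit),
                initial_cost=float(f0),
                final_cost=float(res.fun),
                converged=bool(res.fun <= f0 + 1e-12),
                history=history,
                wall_time_s=time.perf_counter() - t0,
            )
        )

    breakdown = problem.last_breakdown
    failure = any(not r.converged for r in reports)

    # verify local injectivity of the returned transform on the target mask
    jac = transform.jacobian_map(target_mask).values[target_mask.values]
    min_jacobian = float(jac.min())

    err_before = err_after = None
    if landmarks is not None:
        on_target, truth = landmarks
        err_before = _landmark_errors(_IdentityTransform(), on_target, truth)
        err_after = _landmark_errors(transform, on_target, truth)

    return RegistrationResult(
        transform=transform,
        breakdown=breakdown,
        levels=reports,
        convergence_failure=failure,
        min_jacobian=min_jacobian,
        landmark_error_before_mm=err_before,
        landmark_error_after_mm=err_after,
    )
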