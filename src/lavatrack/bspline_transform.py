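"""Cubic B-spline parameterised free-form deformation h(x) = x + u(x).

The displacement u is a tensor-product cubic B-spline over a uniform
control grid with node displacement coefficients phi (mm).  The grid
extends one node beyond each face of the registration domain so the cubic
support (4 nodes per axis) is complete everywhere inside the domain.

The Jacobian determinant of h is evaluated analytically from B-spline
derivative kernels.  Local injectivity is enforced through box constraints
on the coefficients: if every displacement component stays below a fixed
fraction K of the grid spacing (the sufficient condition of Choi and Lee
for uniform cubic B-splines; K = 0.40 here, a conservative rounding of
~1/2.48), the transform is locally injective and J > 0 everywhere.

Grid refinement by a factor of two uses the exact cubic subdivision rules
(Lane-Riesenfeld masks 1/8*(1, 6, 1) and 1/2*(1, 1)), so the refined
transform reproduces the original displacement field exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .image_model import ScalarVolume3D

__all__ = [
    "BSplineTransform",
    "JacobianMap",
    "AffineTransform",
    "cubic_bspline",
    "injectivity_bound",
    "INJECTIVITY_K",
]

INJECTIVITY_K = 0.40


def cubic_bspline(s: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Centred uniform cubic B-spline basis (support |s| < 2) or a derivative."""
    s = np.asarray(s, dtype=np.float64)
    a = np.abs(s)
    inner = a <= 1.0
    outer = (a > 1.0) & (a < 2.0)
    out = np.zeros_like(s)
    if deriv == 0:
        out = np.where(inner, 2.0 / 3.0 - a**2 + a**3 / 2.0, out)
        out = np.where(outer, (2.0 - a) ** 3 / 6.0, out)
    elif deriv == 1:
        sign = np.sign(s)
        out = np.where(inner, -2.0 * s + 1.5 * s * a, out)
        out = np.where(outer, -0.5 * (2.0 - a) ** 2 * sign, out)
    elif deriv == 2:
        out = np.where(inner, -2.0 + 3.0 * a, out)
        out = np.where(outer, 2.0 - a, out)
    else:
        raise ValueError("deriv must be 0, 1 or 2")
    return out


def injectivity_bound(grid_spacing, k: float = INJECTIVITY_K) -> np.ndarray:
    """Per-axis coefficient bound (mm) guaranteeing local injectivity."""
    spacing = np.atleast_1d(np.asarray(grid_spacing, dtype=np.float64))
    if np.any(spacing <= 0):
        raise ValueError("grid spacing must be positive")
    return k * spacing


def _det3(d: np.ndarray) -> np.ndarray:
    """Determinant of stacked 3x3 matrices (..., 3, 3) without LAPACK overhead."""
    return (
        d[..., 0, 0] * (d[..., 1, 1] * d[..., 2, 2] - d[..., 1, 2] * d[..., 2, 1])
        - d[..., 0, 1] * (d[..., 1, 0] * d[..., 2, 2] - d[..., 1, 2] * d[..., 2, 0])
        + d[..., 0, 2] * (d[..., 1, 0] * d[..., 2, 1] - d[..., 1, 1] * d[..., 2, 0])
    )


@dataclass(frozen=True)
class JacobianMap:
    """Per-voxel Jacobian determinant of a transform on a stated lattice."""

    volume: ScalarVolume3D
    label: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


@dataclass(frozen=True)
class BSplineTransform:
    """h(x) = x + sum_i phi_i * B((x - x_i) / delta), phi on a uniform grid."""

    coeffs: np.ndarray  # (m1, m2, m3, 3) node displacements, mm
    grid_spacing: tuple[float, float, float]
    grid_origin: tuple[float, float, float]
    domain_lo: tuple[float, float, float]
    domain_hi: tuple[float, float, float]

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if coeffs.ndim != 4 or coeffs.shape[-1] != 3:
            raise ValueError("coefficients must have shape (m1, m2, m3, 3)")
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)
        for name in ("grid_spacing", "grid_origin", "domain_lo", "domain_hi"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        if any(s <= 0 for s in self.grid_spacing):
            raise ValueError("grid spacing must be positive")
        # cubic support margin: at least one node beyond each domain face
        g0 = np.asarray(self.grid_origin)
        delta = np.asarray(self.grid_spacing)
        m = np.asarray(coeffs.shape[:3])
        lo, hi = np.asarray(self.domain_lo), np.asarray(self.domain_hi)
        t_lo = (lo - g0) / delta
        t_hi = (hi - g0) / delta
        if np.any(np.floor(t_lo) - 1 < 0) or np.any(np.floor(t_hi) + 2 > m - 1):
            raise ValueError("control grid does not cover the domain with cubic support")

    # -- construction -------------------------------------------------------

    @classmethod
    def for_domain(cls, lo, hi, grid_spacing) -> "BSplineTransform":
        """Identity transform whose grid covers [lo, hi] with cubic support."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        delta = np.broadcast_to(np.asarray(grid_spacing, dtype=np.float64), (3,)).copy()
        if np.any(delta <= 0):
            raise ValueError("grid spacing must be positive")
        g0 = lo - delta
        m = np.ceil((hi - lo) / delta).astype(int) + 4
        coeffs = np.zeros(tuple(m) + (3,), dtype=np.float64)
        return cls(coeffs, tuple(delta), tuple(g0), tuple(lo), tuple(hi))

    def with_coeffs(self, coeffs: np.ndarray) -> "BSplineTransform":
        return replace(self, coeffs=np.asarray(coeffs, dtype=np.float64))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]  # type: ignore[return-value]

    @property
    def n_parameters(self) -> int:
        return self.coeffs.size

    def coefficient_bound(self, k: float = INJECTIVITY_K) -> np.ndarray:
        """Per-axis injectivity box bound for this grid, mm."""
        return injectivity_bound(self.grid_spacing, k)

    # -- point evaluation ---------------------------------------------------

    def _support(self, pts: np.ndarray):
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
        lo, hi = np.asarray(self.domain_lo), np.asarray(self.domain_hi)
        eps = 1e-9
        if np.any(pts < lo - eps) or np.any(pts > hi + eps):
            raise ValueError("point outside the transform domain")
        t = (pts - np.asarray(self.grid_origin)) / np.asarray(self.grid_spacing)
        base = np.floor(t).astype(int) - 1
        return pts, t, base

    def displacement_at(self, points: np.ndarray, jac: bool = False):
        """Displacement u (and optionally du/dx) at world points, by direct
        summation over the 4x4x4 coefficient support."""
        pts_in = np.asarray(points, dtype=np.float64)
        single = pts_in.ndim == 1
        pts, t, base = self._support(pts_in)
        n = len(pts)
        delta = np.asarray(self.grid_spacing)
        w = np.empty((3, 4, n))
        dw = np.empty((3, 4, n)) if jac else None
        for a in range(3):
            for o in range(4):
                s = t[:, a] - (base[:, a] + o)
                w[a, o] = cubic_bspline(s)
                if jac:
                    dw[a, o] = cubic_bspline(s, 1) / delta[a]
        u = np.zeros((n, 3))
        du = np.zeros((n, 3, 3)) if jac else None
        c = self.coeffs
        for o1 in range(4):
            for o2 in range(4):
                for o3 in range(4):
                    phi = c[base[:, 0] + o1, base[:, 1] + o2, base[:, 2] + o3]
                    w123 = w[0, o1] * w[1, o2] * w[2, o3]
                    u += phi * w123[:, None]
                    if jac:
                        du[:, :, 0] += phi * (dw[0, o1] * w[1, o2] * w[2, o3])[:, None]
                        du[:, :, 1] += phi * (w[0, o1] * dw[1, o2] * w[2, o3])[:, None]
                        du[:, :, 2] += phi * (w[0, o1] * w[1, o2] * dw[2, o3])[:, None]
        if single:
            u = u[0]
            du = du[0] if jac else None
        return (u, du) if jac else u

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """h(points): identity plus B-spline displacement."""
        return np.asarray(points, dtype=np.float64) + self.displacement_at(points)

    def jacobian_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic Jacobian determinant of h at world points."""
        _, du = self.displacement_at(points, jac=True)
        d = du + np.eye(3)
        return _det3(d)

    # -- lattice evaluation (separable fast path) ---------------------------

    def lattice_weights(self, geometry, derivs=(0, 0, 0)) -> list[np.ndarray]:
        """Per-axis dense weight matrices W_a[i, k] for a regular lattice."""
        shape, spacing, origin = geometry.geometry
        mats = []
        for a in range(3):
            x = origin[a] + np.arange(shape[a]) * spacing[a]
            g = self.grid_origin[a] + np.arange(self.grid_shape[a]) * self.grid_spacing[a]
            s = (x[:, None] - g[None, :]) / self.grid_spacing[a]
            w = cubic_bspline(s, derivs[a]) / self.grid_spacing[a] ** derivs[a]
            mats.append(w)
        return mats

    def displacement_on_lattice(self, geometry, derivs=(0, 0, 0)) -> np.ndarray:
        """u (or a spatial derivative of u) on every voxel centre, (n1,n2,n3,3)."""
        w1, w2, w3 = self.lattice_weights(geometry, derivs)
        return np.einsum(
            "ip,jq,kr,pqrc->ijkc", w1, w2, w3, self.coeffs, optimize=True
        )

    def jacobian_map(self, geometry, label: str = "") -> JacobianMap:
        """Analytic Jacobian determinant at each voxel centre of a lattice."""
        shape, spacing, origin = geometry.geometry
        d = np.empty(tuple(shape) + (3, 3), dtype=np.float64)
        for j in range(3):
            derivs = [0, 0, 0]
            derivs[j] = 1
            d[..., :, j] = self.displacement_on_lattice(geometry, tuple(derivs))
        d += np.eye(3)
        vol = ScalarVolume3D(_det3(d), spacing, origin)
        return JacobianMap(vol, label=label)

    # -- refinement ---------------------------------------------------------

    def refined(self) -> "BSplineTransform":
        """Halve the grid spacing; the displacement field is reproduced exactly."""
        c = self.coeffs
        for axis in range(3):
            c = np.moveaxis(c, axis, 0)
            m = c.shape[0]
            pad = np.zeros((1,) + c.shape[1:], dtype=c.dtype)
            cp = np.concatenate([pad, c, pad], axis=0)  # index i+1 == old node i
            even = (cp[:-2] + 6.0 * cp[1:-1] + cp[2:]) / 8.0  # new node at old i
            odd = (cp[1:-1][:-1] + cp[1:-1][1:]) / 2.0  # between old i, i+1
            new = np.empty((2 * m - 1,) + c.shape[1:], dtype=c.dtype)
            new[0::2] = even
            new[1::2] = odd
            c = np.moveaxis(new, 0, axis)
        spacing = tuple(s / 2.0 for s in self.grid_spacing)
        return BSplineTransform(
            c, spacing, self.grid_origin, self.domain_lo, self.domain_hi
        )

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        m = self.grid_shape
        with open(path, "w") as fh:
            fh.write("lavatrack-bspline-transform v1\n")
            for name, vals in (
                ("grid_spacing", self.grid_spacing),
                ("grid_origin", self.grid_origin),
                ("domain_lo", self.domain_lo),
                ("domain_hi", self.domain_hi),
            ):
                fh.write(name + ": " + " ".join(repr(v) for v in vals) + "\n")
            fh.write(f"dims: {m[0]} {m[1]} {m[2]}\n")
            np.savetxt(fh, self.coeffs.reshape(-1, 3), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "BSplineTransform":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "lavatrack-bspline-transform v1":
                raise ValueError(f"unrecognised transform file header: {header!r}")
            fields = {}
            for _ in range(5):
                key, _, rest = fh.readline().partition(":")
                fields[key.strip()] = rest.split()
            coeffs = np.loadtxt(fh)
        dims = tuple(int(v) for v in fields["dims"])
        coeffs = coeffs.reshape(dims + (3,))
        return cls(
            coeffs,
            tuple(float(v) for v in fields["grid_spacing"]),
            tuple(float(v) for v in fields["grid_origin"]),
            tuple(float(v) for v in fields["domain_lo"]),
            tuple(float(v) for v in fields["domain_hi"]),
        )


@dataclass(frozen=True)
class AffineTransform:
    """y = A (x - center) + center + shift; exact Jacobian, exact inverse.

    A small helper used as an analytic ground-truth transform in tests and
    by the phantom generator; it exposes the same point interface as
    :class:`BSplineTransform`.
    """

    matrix: np.ndarray  # (3, 3)
    shift: np.ndarray = None  # (3,)
    center: np.ndarray = None  # (3,)

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=np.float64).reshape(3, 3))
        shift = np.zeros(3) if self.shift is None else np.asarray(self.shift, dtype=np.float64)
        center = np.zeros(3) if self.center is None else np.asarray(self.center, dtype=np.float64)
        object.__setattr__(self, "shift", shift.reshape(3))
        object.__setattr__(self, "center", center.reshape(3))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return (pts - self.center) @ self.matrix.T + self.center + self.shift

    def jacobian_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        det = float(np.linalg.det(self.matrix))
        return np.full(pts.shape[:-1], det)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.shift, self.center)
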