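import numpy as np
import pytest
from scipy import ndimage

from lavatrack.bspline_transform import BSplineTransform
from lavatrack.image_model import BinaryMask3D, ScalarVolume3D
from lavatrack.registration import (
    RegistrationConfig,
    _LevelProblem,
    cost_laplacian,
    cost_ssd,
    cost_sstvd,
    cost_ssvmd,
    register,
    total_cost,
)

from conftest import full_mask, interior_mask, smooth_random_volume


def identity_for(vol, spacing=10.0) -> BSplineTransform:
    lo, hi = vol.bounds()
    return BSplineTransform.for_domain(lo, hi, spacing)


class TestConfig:
    def test_mode_validated(self):
        with pytest.raises(ValueError):
            RegistrationConfig(mode="elastic", chi=1.0, gamma_reg=0.0)

    def test_weights_nonnegative(self):
        with pytest.raises(ValueError):
            RegistrationConfig(mode="rtvp", chi=-1.0, gamma_reg=0.0)

    def test_schedule_coarse_to_fine(self):
        with pytest.raises(ValueError):
            RegistrationConfig(mode="rtvp", chi=1.0, gamma_reg=0.0, levels=(0, 2))

    def test_stated_defaults(self):
        rtvp = RegistrationConfig.rtvp()
        assert (rtvp.chi, rtvp.gamma_reg) == (1.0, 0.01)
        rivp = RegistrationConfig.rivp_defaults()
        assert (rivp.chi, rivp.gamma_reg) == (2.0, 10.0)
        assert rtvp.finest_grid_mm == 8.0
        f = rtvp.frangi
        assert (f.alpha, f.beta, f.gamma) == (0.5, 0.5, 5.0)

    def test_grid_schedule_halves_to_finest(self):
        cfg = RegistrationConfig.rtvp()
        assert cfg.grid_schedule() == (32.0, 16.0, 8.0, 8.0)


class TestCostTerms:
    def test_perfect_match_costs_nothing(self, smooth_volume):
        h = identity_for(smooth_volume)
        omega = full_mask(smooth_volume)
        assert cost_sstvd(smooth_volume, smooth_volume, h, omega) == pytest.approx(0.0, abs=1e-18)
        assert cost_ssd(smooth_volume, smooth_volume, h, omega) == pytest.approx(0.0, abs=1e-18)
        f = smooth_volume.with_values(np.random.default_rng(0).random(smooth_volume.shape))
        assert cost_ssvmd(f, f, h, omega) == pytest.approx(0.0, abs=1e-18)

    def test_sstvd_single_voxel_hand_value(self):
        # one masked voxel of 1 mm^3: target half tissue, template pure air
        target = ScalarVolume3D(np.full((3, 3, 3), -472.5), (1, 1, 1))
        template = ScalarVolume3D(np.full((3, 3, 3), -1000.0), (1, 1, 1))
        omega_vals = np.zeros((3, 3, 3), bool)
        omega_vals[1, 1, 1] = True
        omega = BinaryMask3D(omega_vals, (1, 1, 1))
        h = identity_for(target)
        assert cost_sstvd(template, target, h, omega) == pytest.approx(0.25)

    def test_ssd_arithmetic(self):
        target = ScalarVolume3D(np.full((5, 5, 4), -490.0), (1, 1, 1))
        template = ScalarVolume3D(np.full((5, 5, 4), -500.0), (1, 1, 1))
        h = identity_for(target)
        assert cost_ssd(template, target, h, full_mask(target)) == pytest.approx(1e4)

    def test_ssd_matches_scalar_loop(self, rng):
        target = ScalarVolume3D(rng.uniform(-900, -400, (5, 4, 3)), (1, 1, 1))
        template = ScalarVolume3D(rng.uniform(-900, -400, (5, 4, 3)), (1, 1, 1))
        h = identity_for(target)
        expected = 0.0
        for i in range(5):
            for j in range(4):
                for k in range(3):
                    expected += (target.values[i, j, k] - template.values[i, j, k]) ** 2
        got = cost_ssd(template, target, h, full_mask(target))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_ssvmd_constant_fields(self):
        shape = (5, 2, 1)
        f2 = ScalarVolume3D(np.ones(shape), (1, 1, 1))
        f1 = ScalarVolume3D(np.zeros(shape), (1, 1, 1))
        h = identity_for(f2)
        assert cost_ssvmd(f1, f2, h, full_mask(f2)) == pytest.approx(10.0)


class TestLaplacian:
    def test_identity_and_translation_cost_nothing(self, smooth_volume):
        omega = full_mask(smooth_volume)
        h = identity_for(smooth_volume)
        assert cost_laplacian(h, omega) == 0.0
        c = h.coeffs.copy()
        c[...] = [3.0, -2.0, 1.0]
        assert cost_laplacian(h.with_coeffs(c), omega) == pytest.approx(0.0, abs=1e-18)

    def _node_positions(self, t):
        g0 = np.asarray(t.grid_origin)
        d = np.asarray(t.grid_spacing)
        m = t.grid_shape
        return np.stack(
            np.meshgrid(
                g0[0] + np.arange(m[0]) * d[0],
                g0[1] + np.arange(m[1]) * d[1],
                g0[2] + np.arange(m[2]) * d[2],
                indexing="ij",
            ),
            axis=-1,
        )

    def test_affine_displacement_costs_nothing(self, smooth_volume):
        h = identity_for(smooth_volume)
        nodes = self._node_positions(h)
        coeffs = 0.05 * nodes + np.array([1.0, -2.0, 0.5])  # linear u
        t = h.with_coeffs(coeffs)
        assert cost_laplacian(t, full_mask(smooth_volume)) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_displacement_hand_value(self, smooth_volume):
        # u = (x1^2, 0, 0) has component Laplacian (2, 0, 0): 4 per voxel
        h = identity_for(smooth_volume)
        nodes = self._node_positions(h)
        coeffs = np.zeros_like(nodes)
        coeffs[..., 0] = nodes[..., 0] ** 2
        t = h.with_coeffs(coeffs)
        omega = full_mask(smooth_volume)
        assert cost_laplacian(t, omega) == pytest.approx(4.0 * omega.count, rel=1e-9)


class TestTotalCost:
    def test_zero_for_identical_images(self, smooth_volume):
        cfg = RegistrationConfig.rtvp()
        h = identity_for(smooth_volume)
        bd = total_cost(
            smooth_volume, smooth_volume, h, cfg, full_mask(smooth_volume)
        )
        assert bd.total == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_weights_reduce_to_similarity(self, rng, smooth_volume):
        other = smooth_volume.with_values(smooth_volume.values + rng.normal(0, 20, smooth_volume.shape))
        cfg = RegistrationConfig(mode="rtvp", chi=0.0, gamma_reg=0.0)
        h = identity_for(smooth_volume)
        omega = full_mask(smooth_volume)
        bd = total_cost(other, smooth_volume, h, cfg, omega)
        assert bd.total == pytest.approx(bd.similarity)

    def test_breakdown_identity(self, rng, smooth_volume):
        other = smooth_volume.with_values(smooth_volume.values + rng.normal(0, 30, smooth_volume.shape))
        cfg = RegistrationConfig(mode="rivp", chi=1.7, gamma_reg=0.3)
        h = identity_for(smooth_volume).with_coeffs(
            rng.uniform(-2, 2, identity_for(smooth_volume).coeffs.shape)
        )
        bd = total_cost(other, smooth_volume, h, cfg, interior_mask(smooth_volume))
        assert bd.total == pytest.approx(
            bd.similarity + 1.7 * bd.ssvmd + 0.3 * bd.laplacian, rel=1e-12
        )


class TestGradients:
    @pytest.mark.parametrize("mode", ["rtvp", "rivp"])
    def test_analytic_gradient_matches_finite_differences(self, rng, mode):
        shape = (12, 11, 10)
        tmpl = ScalarVolume3D(ndimage.gaussian_filter(rng.uniform(-950, -500, shape), 1.0), (2, 2, 2))
        targ = ScalarVolume3D(ndimage.gaussian_filter(rng.uniform(-950, -500, shape), 1.0), (2, 2, 2))
        omega = interior_mask(targ, margin=2)
        f1 = rng.uniform(0, 1, shape)
        f2 = rng.uniform(0, 1, shape)
        cfg = (
            RegistrationConfig.rtvp() if mode == "rtvp" else RegistrationConfig.rivp_defaults()
        )
        t = identity_for(targ, spacing=8.0)
        x0 = rng.uniform(-1.5, 1.5, t.coeffs.size)
        problem = _LevelProblem(tmpl, targ, omega, f1, f2, t.with_coeffs(x0.reshape(t.coeffs.shape)), cfg)
        f, g = problem.cost_and_grad(x0)
        step = 1e-4 if mode == "rivp" else 1e-6
        for i in rng.choice(x0.size, 20, replace=False):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += step
            xm[i] -= step
            fp, _ = problem.cost_and_grad(xp)
            fm, _ = problem.cost_and_grad(xm)
            fd = (fp - fm) / (2 * step)
            assert g[i] == pytest.approx(fd, rel=2e-3, abs=1e-9)


class TestRegister:
    def test_self_registration_returns_near_identity(self, rng):
        vol = smooth_random_volume(rng, shape=(20, 20, 20), spacing=(4, 4, 4), sigma=1.5)
        mask = interior_mask(vol, margin=2)
        cfg = RegistrationConfig.rtvp(levels=(1, 0), max_iter=30, finest_grid_mm=16.0)
        res = register(vol, vol, mask, mask, cfg)
        u = res.transform.displacement_on_lattice(vol)
        mean_disp = np.linalg.norm(u[mask.values], axis=1).mean()
        assert mean_disp < 0.1 * min(vol.spacing)
        assert not res.convergence_failure

    def test_recovers_small_translation(self, rng):
        # a textured blob translated by 3 mm; coarse single-level solve
        shape = (24, 24, 24)
        base = ndimage.gaussian_filter(rng.uniform(0, 1, shape), 2.0)
        idx = np.indices(shape).astype(float)
        blob = np.exp(-(((idx[0] - 12) ** 2 + (idx[1] - 12) ** 2 + (idx[2] - 12) ** 2) / 40.0))
        targ_vals = -900.0 + 300.0 * blob * (1 + base)
        vol = ScalarVolume3D(targ_vals, (2, 2, 2))
        tmpl_vals = np.roll(targ_vals, shift=-1, axis=0)  # template shifted one voxel down axis 0
        tmpl = ScalarVolume3D(tmpl_vals, (2, 2, 2))
        mask = interior_mask(vol, margin=3)
        cfg = RegistrationConfig.rtvp(levels=(0,), max_iter=80, finest_grid_mm=16.0)
        res = register(tmpl, vol, mask, mask, cfg)
        u = res.transform.displacement_on_lattice(vol)[mask.values]
        # h(x) must point one voxel (2 mm) towards +axis0 in the template
        assert np.mean(u[:, 0]) == pytest.approx(-2.0, abs=0.6)
        assert res.min_jacobian > 0.0

    def test_truth_transform_beats_identity_on_phantom(self, small_study):
        base = small_study.baseline
        truth = small_study.truth["intra_warps"]["base"]
        omega = base.tlc_mask
        at_truth = cost_sstvd(base.frc, base.tlc, truth, omega)
        lo, hi = base.tlc.bounds()
        ident = BSplineTransform.for_domain(lo, hi, 16.0)
        at_identity = cost_sstvd(base.frc, base.tlc, ident, omega)
        assert at_truth < 0.2 * at_identity
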