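import numpy as np
import pytest

from lavatrack.bspline_transform import BSplineTransform, JacobianMap
from lavatrack.image_model import (
    BinaryMask3D,
    DegenerateInputError,
    LandmarkSet,
    ScalarVolume3D,
)
from lavatrack.mixture_model import regional_tissue_volume
from lavatrack.tracking_analysis import (
    landmark_error,
    load_bal_study,
    load_whole_lung_tvcr,
    rank_change,
    rank_map,
    regress_tvc_vs_bal,
    slab_profile,
    track_tissue_volume,
    unretrieved_bal,
)


class TestBalRecord:
    @pytest.mark.parametrize(
        "total,retrieved,expected", [(300, 153, 147), (300, 300, 0), (300, 232, 68)]
    )
    def test_unretrieved_volume(self, total, retrieved, expected):
        assert unretrieved_bal(total, retrieved).v_bal == expected

    def test_retrieved_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            unretrieved_bal(300, 301)

    def test_volumes_nonnegative(self):
        with pytest.raises(ValueError):
            unretrieved_bal(-1, 0)


def jac_from(values, spacing=(1.0, 1.0, 1.0)):
    return JacobianMap(ScalarVolume3D(np.asarray(values, float), spacing))


class TestRankMap:
    def test_constant_field_ranks_one(self):
        jac = jac_from(np.ones((4, 4, 4)))
        mask = BinaryMask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        rm = rank_map(jac, mask)
        assert np.all(rm.values[mask.values] == 1.0)

    def test_two_level_field(self):
        values = np.full((4, 4, 2), 0.8)
        values[..., 1] = 1.2
        jac = jac_from(values)
        mask = BinaryMask3D(np.ones(values.shape, bool), (1, 1, 1))
        rm = rank_map(jac, mask)
        assert np.all(rm.values[..., 0] == 0.5)
        assert np.all(rm.values[..., 1] == 1.0)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        values = rng.normal(1.0, 0.2, (6, 6, 6))
        mask = BinaryMask3D(rng.random((6, 6, 6)) > 0.3, (1, 1, 1))
        a = rank_map(jac_from(values), mask)
        b = rank_map(jac_from(np.exp(values)), mask)
        assert np.array_equal(a.values, b.values)

    def test_values_in_half_open_unit_interval(self, rng):
        mask = BinaryMask3D(np.ones((5, 5, 5), bool), (1, 1, 1))
        rm = rank_map(jac_from(rng.normal(1, 0.1, (5, 5, 5))), mask)
        inside = rm.values[mask.values]
        assert inside.min() > 0.0 and inside.max() <= 1.0


class TestRankChange:
    def _masks(self, shape=(6, 6, 6)):
        lav = np.zeros(shape, bool)
        lav[:3] = True
        return (
            BinaryMask3D(lav, (1, 1, 1)),
            BinaryMask3D(~lav, (1, 1, 1)),
        )

    def test_identical_maps_give_zero_change(self, rng):
        mask = BinaryMask3D(np.ones((6, 6, 6), bool), (1, 1, 1))
        rm = rank_map(jac_from(rng.normal(1, 0.1, (6, 6, 6))), mask)
        lav, nonlav = self._masks()
        rc = rank_change(rm, rm, lav, nonlav)
        assert rc.mean_rc_lavage == 0.0
        assert rc.mean_rc_nonlavage == 0.0

    def test_suppressed_region_ranks_down_elsewhere_up(self, rng):
        shape = (6, 6, 6)
        mask = BinaryMask3D(np.ones(shape, bool), (1, 1, 1))
        base_vals = rng.normal(1.5, 0.05, shape)
        post_vals = base_vals.copy()
        lav, nonlav = self._masks(shape)
        post_vals[lav.values] *= 0.6  # function suppressed inside the region
        r0 = rank_map(jac_from(base_vals), mask)
        r1 = rank_map(jac_from(post_vals), mask)
        rc = rank_change(r0, r1, lav, nonlav)
        assert rc.mean_rc_lavage < 0.0
        assert rc.mean_rc_nonlavage >= 0.0

    def test_global_monotone_rescaling_leaves_change_unchanged(self, rng):
        shape = (6, 6, 6)
        mask = BinaryMask3D(np.ones(shape, bool), (1, 1, 1))
        base_vals = rng.normal(1.5, 0.1, shape)
        post_vals = rng.normal(1.4, 0.1, shape)
        lav, nonlav = self._masks(shape)
        r0 = rank_map(jac_from(base_vals), mask)
        rc_raw = rank_change(r0, rank_map(jac_from(post_vals), mask), lav, nonlav)
        rc_scaled = rank_change(
            r0, rank_map(jac_from(3.0 * post_vals - 1.0), mask), lav, nonlav
        )
        assert rc_raw.mean_rc_lavage == pytest.approx(rc_scaled.mean_rc_lavage)
        assert rc_raw.mean_rc_nonlavage == pytest.approx(rc_scaled.mean_rc_nonlavage)

    def test_lattice_mismatch_rejected(self, rng):
        mask6 = BinaryMask3D(np.ones((6, 6, 6), bool), (1, 1, 1))
        mask4 = BinaryMask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        r6 = rank_map(jac_from(rng.random((6, 6, 6))), mask6)
        r4 = rank_map(jac_from(rng.random((4, 4, 4))), mask4)
        lav, nonlav = self._masks()
        with pytest.raises(ValueError):
            rank_change(r6, r4, lav, nonlav)


class TestSlabProfile:
    def test_constant_field_gives_constant_slabs(self):
        jac = jac_from(np.full((8, 8, 40), 1.3))
        mask = BinaryMask3D(np.ones((8, 8, 40), bool), (1, 1, 1))
        prof = slab_profile(jac, mask, axis=2, n_slabs=30)
        assert len(prof) == 30
        assert np.allclose(prof, 1.3)

    def test_linear_gradient_gives_monotone_slabs(self):
        values = np.broadcast_to(
            np.linspace(0.8, 1.6, 60), (8, 8, 60)
        ).copy()
        jac = jac_from(values)
        mask = BinaryMask3D(np.ones(values.shape, bool), (1, 1, 1))
        prof = slab_profile(jac, mask, axis=2, n_slabs=30)
        assert np.all(np.diff(prof) > 0)

    def test_empty_slab_reported_missing(self):
        mask_vals = np.zeros((4, 4, 30), bool)
        mask_vals[..., :10] = True
        mask_vals[..., 20:] = True
        mask = BinaryMask3D(mask_vals, (1, 1, 1))
        prof = slab_profile(jac_from(np.ones((4, 4, 30))), mask, axis=2, n_slabs=30)
        assert np.isnan(prof).any()

    def test_invalid_slab_count(self):
        mask = BinaryMask3D(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            slab_profile(jac_from(np.ones((4, 4, 4))), mask, axis=0, n_slabs=0)


class TestLandmarkError:
    def test_identical_sets_have_zero_error(self):
        lm = LandmarkSet(("a", "b"), [[0, 0, 0], [5, 5, 5]])
        summary = landmark_error(lm, lm)
        assert np.all(summary.distances_mm == 0.0)

    def test_pythagorean_distance(self):
        a = LandmarkSet(("p",), [[0.0, 0.0, 0.0]])
        b = LandmarkSet(("p",), [[1.0, 2.0, 2.0]])
        assert landmark_error(a, b).distances_mm[0] == pytest.approx(3.0)

    def test_label_mismatch_rejected(self):
        a = LandmarkSet(("p",), [[0, 0, 0]])
        b = LandmarkSet(("q",), [[0, 0, 0]])
        with pytest.raises(ValueError):
            landmark_error(a, b)

    def test_order_independent(self):
        a = LandmarkSet(("p", "q"), [[0, 0, 0], [1, 1, 1]])
        b = LandmarkSet(("q", "p"), [[1, 1, 2], [0, 0, 3]])
        summary = landmark_error(a, b)
        by_label = dict(zip(summary.labels, summary.distances_mm))
        assert by_label["p"] == pytest.approx(3.0)
        assert by_label["q"] == pytest.approx(1.0)


def closed_form_ols(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy, syy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx**2) * (n * syy - sy**2))
    return slope, intercept, r2


class TestRegression:
    def test_reference_study_all_subjects(self):
        df = load_bal_study()
        records = [
            (unretrieved_bal(t, r).v_bal, tvc)
            for t, r, tvc in zip(df.v_total_ml, df.v_retrieved_ml, df.tvc1_ml)
        ]
        fit = regress_tvc_vs_bal(records)
        assert round(fit.slope, 2) == 0.83
        assert round(fit.r_squared, 2) == 0.81

    def test_reference_study_without_coughing_subject(self):
        df = load_bal_study()
        df = df[df.subject != 2]
        records = [
            (unretrieved_bal(t, r).v_bal, tvc)
            for t, r, tvc in zip(df.v_total_ml, df.v_retrieved_ml, df.tvc1_ml)
        ]
        fit = regress_tvc_vs_bal(records)
        assert round(fit.slope, 2) == 0.98
        assert round(fit.r_squared, 2) == 0.94

    def test_collinear_points(self):
        fit = regress_tvc_vs_bal([(1.0, 2.0), (2.0, 4.0), (5.0, 10.0)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        x = rng.uniform(50, 200, 12)
        y = 0.7 * x + rng.normal(0, 10, 12)
        fit = regress_tvc_vs_bal(np.column_stack([x, y]))
        slope, intercept, r2 = closed_form_ols(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            regress_tvc_vs_bal([(1.0, 2.0)])
        with pytest.raises(DegenerateInputError):
            regress_tvc_vs_bal([(1.0, 2.0), (1.0, 3.0)])


class TestTissueTracking:
    def test_identity_transforms_and_identical_images_give_no_change(self, small_study):
        base = small_study.baseline
        lo, hi = base.tlc.bounds()
        ident = BSplineTransform.for_domain(lo, hi, 16.0)
        # pretend every post image equals baseline
        import copy

        study = copy.copy(small_study)
        study.scans = dict(small_study.scans)
        for phase in ("post0", "post4", "post24"):
            scans = copy.copy(small_study.scans[phase])
            scans.tlc = base.tlc
            study.scans[phase] = scans
        region = small_study.lavage_mask.intersection(base.tlc_mask)
        series = track_tissue_volume(
            study, {p: ident for p in ("post0", "post4", "post24")}, region
        )
        assert np.allclose(series.tvc, 0.0, atol=1e-7)

    def test_region_outside_lung_rejected(self, small_study):
        base = small_study.baseline
        lo, hi = base.tlc.bounds()
        ident = BSplineTransform.for_domain(lo, hi, 16.0)
        outside = BinaryMask3D(
            np.ones(base.tlc.shape, bool), base.tlc.spacing, base.tlc.origin
        )
        with pytest.raises(ValueError):
            track_tissue_volume(
                small_study, {p: ident for p in ("post0", "post4", "post24")}, outside
            )

    def test_tissue_volume_additive_over_partition(self, small_study, rng):
        base = small_study.baseline
        lung = base.tlc_mask
        split = rng.random(lung.shape) > 0.5
        part_a = BinaryMask3D(lung.values & split, lung.spacing, lung.origin)
        part_b = BinaryMask3D(lung.values & ~split, lung.spacing, lung.origin)
        whole = regional_tissue_volume(base.tlc, lung)
        assert regional_tissue_volume(base.tlc, part_a) + regional_tissue_volume(
            base.tlc, part_b
        ) == pytest.approx(whole, rel=1e-12)


def test_reference_tvcr_table_layout():
    df = load_whole_lung_tvcr()
    assert list(df.columns) == ["subject", "tvcr1_pct", "tvcr2_pct", "tvcr3_pct"]
    assert len(df) == 6
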