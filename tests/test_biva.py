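import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from haplobiva.biva import (
    BivaError, InsufficientSampleError, ReferencePopulation,
    confidence_ellipse, derive_geometry, f_from_t2, hotelling_two_sample,
    mahalanobis_d_from_t2, specific_vector, tolerance_ellipse,
)

REF = ReferencePopulation(
    name="synthetic-reference", n=400,
    mean_rsp=380.0, mean_xcsp=42.0, sd_rsp=65.0, sd_xcsp=9.0, corr=0.6,
)


class TestGeometry:
    def test_worked_example(self):
        g = derive_geometry(170, 70, 30, 80, 36)
        assert g.l_factor_cm == pytest.approx(187.0)
        assert g.arm_area_cm2 == pytest.approx(71.62, abs=0.005)
        assert g.waist_area_cm2 == pytest.approx(509.30, abs=0.005)
        assert g.calf_area_cm2 == pytest.approx(103.13, abs=0.005)
        assert g.a_factor_cm2 == pytest.approx(129.57, abs=0.005)

    def test_bmi_definition(self):
        assert derive_geometry(175, 70, 30, 80, 36).bmi == pytest.approx(22.86, abs=0.005)

    def test_area_scales_quadratically(self):
        g1 = derive_geometry(170, 70, 30, 80, 36)
        g2 = derive_geometry(170, 70, 60, 160, 72)
        assert g2.a_factor_cm2 == pytest.approx(4 * g1.a_factor_cm2)

    def test_nonpositive_input_names_field(self):
        with pytest.raises(BivaError, match="waist"):
            derive_geometry(170, 70, 30, -1, 36)


class TestSpecificVector:
    def test_three_four_five_triangle(self):
        g = derive_geometry(170, 70, 30, 80, 36)
        v = specific_vector(3, 4, g)
        assert v.z == pytest.approx(5.0)
        assert v.pha == pytest.approx(math.degrees(math.atan(4 / 3)))

    def test_equal_components_give_45_degrees(self):
        g = derive_geometry(170, 70, 30, 80, 36)
        assert specific_vector(55.0, 55.0, g).pha == pytest.approx(45.0)

    def test_worked_specific_values(self):
        g = derive_geometry(170, 70, 30, 80, 36)
        v = specific_vector(500, 55, g)
        assert v.rsp == pytest.approx(346.44, abs=0.005)
        assert v.xcsp == pytest.approx(38.11, abs=0.005)
        assert v.pha == pytest.approx(math.degrees(math.atan(55 / 500)), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        r=st.floats(50, 1000), xc=st.floats(5, 200),
        height=st.floats(140, 200), arm=st.floats(20, 45),
    )
    def test_phase_angle_invariant_under_standardization(self, r, xc, height, arm):
        g = derive_geometry(height, 70, arm, 80, 36)
        v = specific_vector(r, xc, g)
        assert v.pha == pytest.approx(
            math.degrees(math.atan2(v.xcsp, v.rsp)), abs=1e-9
        )

    def test_nonpositive_resistance_rejected(self):
        g = derive_geometry(170, 70, 30, 80, 36)
        with pytest.raises(BivaError):
            specific_vector(0, 40, g)


class TestToleranceEllipse:
    def test_chi2_radius_at_95(self):
        unit = ReferencePopulation("u", 100, 0, 0, 1.0, 1.0, 0.0)
        spec = tolerance_ellipse(unit, 0.95)
        assert spec.radius2 == pytest.approx(5.9915, abs=5e-4)

    def test_boundary_point_is_contained(self):
        spec = tolerance_ellipse(REF, 0.50)
        major_len, _ = spec.axes_lengths
        eigvals, eigvecs = np.linalg.eigh(spec.covariance)
        point = np.asarray(spec.center) + eigvecs[:, -1] * major_len
        assert spec.contains(point)
        assert spec.mahalanobis2(point) == pytest.approx(spec.radius2, rel=1e-9)

    def test_unsupported_coverage_rejected(self):
        with pytest.raises(BivaError):
            tolerance_ellipse(REF, 0.90)

    def test_monte_carlo_coverage(self, rng):
        spec = tolerance_ellipse(REF, 0.95)
        draws = rng.multivariate_normal(
            spec.center, REF.covariance, size=100_000
        )
        inside = np.mean([spec.contains(p) for p in draws])
        assert 0.947 <= inside <= 0.953


class TestConfidenceEllipse:
    def test_duplicating_the_sample_shrinks_the_ellipse(self, rng):
        sample = rng.multivariate_normal([380, 42], REF.covariance, size=12)
        e1 = confidence_ellipse(sample)
        e2 = confidence_ellipse(np.vstack([sample, sample]))
        assert np.allclose(e1.center, e2.center)
        assert np.prod(e2.axes_lengths) < np.prod(e1.axes_lengths)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(InsufficientSampleError):
            confidence_ellipse(rng.normal(size=(3, 2)))

    def test_degenerate_coordinate_rejected(self):
        sample = np.column_stack([np.arange(10.0), np.full(10, 5.0)])
        with pytest.raises(BivaError):
            confidence_ellipse(sample)

    def test_mean_coverage_simulation(self, rng):
        true_mean = np.array([380.0, 42.0])
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            sample = rng.multivariate_normal(true_mean, REF.covariance, size=30)
            if confidence_ellipse(sample).contains(true_mean):
                hits += 1
        assert 0.93 <= hits / n_rep <= 0.97


class TestHotelling:
    def test_identical_samples_null(self, rng):
        a = rng.multivariate_normal([380, 42], REF.covariance, size=20)
        res = hotelling_two_sample(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.mahalanobis_d == pytest.approx(0.0, abs=1e-9)

    def test_printed_conversion_t2_to_f_and_d(self):
        assert f_from_t2(13.5, 91) == pytest.approx(6.7, abs=0.05)
        assert mahalanobis_d_from_t2(13.5, 46, 45) == pytest.approx(0.77, abs=0.005)

    def test_exact_univariate_reduction(self):
        # second coordinate shares its values across groups (zero mean
        # difference) and is chosen orthogonal to the first within groups, so
        # T2 collapses exactly to the squared pooled two-sample t statistic
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([2.5, 3.5, 4.5, 5.5, 6.5])
        y = np.array([1.0, -2.0, 0.0, 2.0, -1.0])  # orthogonal to x deviations
        a = np.column_stack([x1, y])
        b = np.column_stack([x2, y])
        res = hotelling_two_sample(a, b)
        t, _ = stats.ttest_ind(x1, x2, equal_var=True)
        assert res.t2 == pytest.approx(t ** 2, rel=1e-9)

    def test_symmetry_and_affine_invariance(self, rng):
        a = rng.multivariate_normal([380, 42], REF.covariance, size=18)
        b = rng.multivariate_normal([420, 46], REF.covariance, size=22)
        res_ab = hotelling_two_sample(a, b)
        res_ba = hotelling_two_sample(b, a)
        assert res_ab.t2 == pytest.approx(res_ba.t2, rel=1e-12)
        A = np.array([[2.0, 0.3], [-0.5, 1.5]])
        shift = np.array([10.0, -4.0])
        res_t = hotelling_two_sample(a @ A.T + shift, b @ A.T + shift)
        assert res_t.t2 == pytest.approx(res_ab.t2, rel=1e-9)

    def test_type_one_error_calibration(self, rng):
        mean = np.array([380.0, 42.0])
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.multivariate_normal(mean, REF.covariance, size=20)
            b = rng.multivariate_normal(mean, REF.covariance, size=20)
            if hotelling_two_sample(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_table5_internal_consistency_of_printed_pairs(self):
        # every printed (T2, F, used-n) row satisfies F = T2*(n-3)/(2*(n-2))
        # to one unit in the last printed digit; rows printed as N/A (sample
        # too small) and the duplicated-sample row, whose printed F cannot be
        # reproduced from its printed T2 under any rounding, are not encoded
        rows = [
            (13.5, 6.7, 91), (8.7, 4.3, 91), (1.5, 0.7, 54), (21.9, 10.6, 37),
            (2.0, 1.0, 46), (8.3, 3.9, 19), (68.8, 33.4, 36), (5.4, 2.6, 37),
            (3.3, 1.6, 25), (1.2, 0.6, 32), (1.3, 0.6, 33), (5.6, 2.6, 17),
            (2.7, 1.3, 25), (3.2, 1.5, 26), (3.5, 1.7, 19), (4.5, 2.1, 26),
            (1.9, 0.9, 23), (0.8, 0.3, 7), (3.5, 1.5, 9), (0.9, 0.4, 8),
            (3.5, 1.7, 34), (3.0, 1.5, 34), (1.3, 0.6, 12),
        ]
        for t2, f_printed, n in rows:
            assert f_from_t2(t2, n) == pytest.approx(f_printed, abs=0.1), (t2, n)
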