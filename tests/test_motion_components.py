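"""Motion-component estimators against closed forms and direct-summation
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    DT_EXACT,
    F_EXACT,
    FS,
    brute_sliding_correlation,
    brute_sliding_variance,
)
from xcski.classifier import classify_series
from xcski.imu_io import Session, Technique, ToleranceSet
from xcski.motion_components import (
    KICKROT_CAP,
    arm_correlation,
    arm_motion,
    assemble_components,
    kick_rotation,
    leg_angle_differences,
    leg_motion,
)
from xcski.preprocess import window_halfwidth

H_EXACT = window_halfwidth(DT_EXACT, FS)
T_LONG = np.arange(600) / FS
INTERIOR = slice(H_EXACT, -H_EXACT)


class TestArmCorrelation:
    def test_identical_arms_fully_correlated(self):
        x = np.sin(2 * np.pi * 0.8 * T_LONG)
        r = arm_correlation(x, x, 1.3, FS)
        h = window_halfwidth(1.3, FS)
        np.testing.assert_allclose(r[h:-h], 1.0, atol=1e-9)

    def test_mirrored_arms_fully_anticorrelated(self):
        x = np.sin(2 * np.pi * 0.8 * T_LONG)
        r = arm_correlation(x, -x, 1.3, FS)
        h = window_halfwidth(1.3, FS)
        np.testing.assert_allclose(r[h:-h], -1.0, atol=1e-9)

    def test_quadrature_arms_uncorrelated_over_full_periods(self):
        x = np.sin(2 * np.pi * F_EXACT * T_LONG)
        y = np.cos(2 * np.pi * F_EXACT * T_LONG)
        r = arm_correlation(x, y, DT_EXACT, FS)
        np.testing.assert_allclose(r[INTERIOR], 0.0, atol=1e-9)
        # and equals the direct-summation oracle everywhere
        ref = brute_sliding_correlation(x, y, DT_EXACT, FS)
        np.testing.assert_allclose(r, ref, atol=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 300))
        np.testing.assert_allclose(arm_correlation(x, y, 1.3, FS),
                                   arm_correlation(y, x, 1.3, FS), atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=-5, max_value=5).filter(lambda a: abs(a) > 1e-3),
           st.floats(min_value=-10, max_value=10))
    def test_affine_relation_gives_sign_of_slope(self, a, b):
        x = np.random.default_rng(9).standard_normal(300)
        r = arm_correlation(x, a * x + b, 1.3, FS)
        h = window_halfwidth(1.3, FS)
        np.testing.assert_allclose(r[h:-h], np.sign(a), atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            arm_correlation(np.zeros(100), np.zeros(99), 1.3, FS)


class TestArmMotion:
    def test_static_arms_zero(self):
        v = arm_motion(np.full(200, 1.0), np.full(200, -2.0), 1.3, FS)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_sinusoid_closed_form_sum_of_variances(self):
        A = 10.0
        x = A * np.sin(2 * np.pi * F_EXACT * T_LONG)
        v = arm_motion(x, x, DT_EXACT, FS)
        np.testing.assert_allclose(v[INTERIOR], A * A, rtol=1e-9)

    def test_race_pace_poling_exceeds_arm_tolerance(self):
        # 150 deg/s arm swings carry armMo = 2 * 150^2/2 = 22500 > 1e4
        A = 150.0
        x = A * np.sin(2 * np.pi * F_EXACT * T_LONG)
        v = arm_motion(x, x, DT_EXACT, FS)
        np.testing.assert_allclose(v[INTERIOR], 22_500.0, rtol=1e-9)
        assert np.all(v[INTERIOR] > ToleranceSet().tol_armMo)


class TestLegAngleDifferences:
    def test_identical_legs_cancel(self):
        rng = np.random.default_rng(1)
        gyro = rng.standard_normal((600, 3)) * 20
        d_theta, d_psi = leg_angle_differences(gyro, gyro, ToleranceSet())
        np.testing.assert_allclose(d_theta, 0.0, atol=1e-9)
        np.testing.assert_allclose(d_psi, 0.0, atol=1e-9)

    def test_antiphase_legs_double_the_angle(self):
        A, f = 5.0, 0.8
        rate = A * 2 * np.pi * f * np.cos(2 * np.pi * f * T_LONG)
        gl = np.zeros((len(T_LONG), 3))
        gr = np.zeros((len(T_LONG), 3))
        gl[:, 1], gr[:, 1] = rate, -rate
        d_theta, d_psi = leg_angle_differences(gl, gr, ToleranceSet())
        ref = 2 * A * np.sin(2 * np.pi * f * T_LONG)
        sl = slice(80, -80)  # past the zero-phase filter's edge transient
        assert np.max(np.abs(d_theta[sl] - ref[sl])) < 0.05 * 2 * A
        # motion purely about the lateral axis leaves the vertical channel flat
        assert np.max(np.abs(d_psi)) < 0.01 * np.max(np.abs(d_theta))


class TestLegMotion:
    def test_zero_differences(self):
        s, st_ = leg_motion(np.zeros(300), np.zeros(300), 1.3, FS)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)
        np.testing.assert_allclose(st_, 0.0, atol=1e-12)

    def test_sinusoid_closed_form(self):
        d = 6.0 * np.sin(2 * np.pi * F_EXACT * T_LONG)
        s, st_ = leg_motion(d, np.zeros_like(d), DT_EXACT, FS)
        np.testing.assert_allclose(s[INTERIOR], 18.0, rtol=1e-9)
        np.testing.assert_allclose(st_[INTERIOR], 18.0, rtol=1e-9)

    def test_transversal_term_is_nonnegative(self):
        rng = np.random.default_rng(2)
        d_theta, d_psi = rng.standard_normal((2, 500)) * 5
        s, st_ = leg_motion(d_theta, d_psi, 1.3, FS)
        assert np.all(st_ - s >= -1e-12)
        np.testing.assert_allclose(s, brute_sliding_variance(d_theta, 1.3, FS),
                                   rtol=1e-9, atol=1e-12)


class TestKickRotation:
    def test_equal_strengths_unity(self):
        x = np.sin(2 * np.pi * F_EXACT * T_LONG)
        r = kick_rotation(x, x.copy(), DT_EXACT, FS)
        np.testing.assert_allclose(r[INTERIOR], 1.0, atol=1e-9)

    def test_ratio_two_at_tolerance_boundary(self):
        th = 1.5 * np.sin(2 * np.pi * F_EXACT * T_LONG)
        ps = 3.0 * np.sin(2 * np.pi * F_EXACT * T_LONG)
        r = kick_rotation(ps, th, DT_EXACT, FS)
        np.testing.assert_allclose(r[INTERIOR], 2.0, rtol=1e-9)

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_invariant_under_common_scaling(self, c):
        rng = np.random.default_rng(3)
        th, ps = rng.standard_normal((2, 400))
        r1 = kick_rotation(ps, th, 1.3, FS)
        r2 = kick_rotation(c * ps, c * th, 1.3, FS)
        np.testing.assert_allclose(r1, r2, rtol=1e-9)

    def test_vanishing_sagittal_motion_capped(self):
        r = kick_rotation(np.sin(T_LONG), np.zeros_like(T_LONG), 1.3, FS)
        assert np.all(r <= KICKROT_CAP)
        assert np.all(r[window_halfwidth(1.3, FS):-window_halfwidth(1.3, FS)]
                      == KICKROT_CAP)


class TestAssembleComponents:
    def test_dp_session_strongly_correlated_arms(self, clean_dp_segment):
        session, _ = clean_dp_segment
        comp = assemble_components(session)
        mid = len(comp) // 2
        assert comp.armCorr[mid] > 0.9
        labels = classify_series(comp)
        assert labels.label[mid] == Technique.DP

    def test_dia_session_anticorrelated_arms(self, clean_dia_segment):
        session, _ = clean_dia_segment
        comp = assemble_components(session)
        mid = len(comp) // 2
        assert comp.armCorr[mid] < -0.5
        assert comp.legMoST[mid] >= comp.legMoS[mid]

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            assemble_components(Session(recordings={}))

    def test_legmost_dominates_legmos_everywhere(self, seven_segment_session):
        session, _ = seven_segment_session
        comp = assemble_components(session)
        assert np.all(comp.legMoST - comp.legMoS >= -1e-9)
        assert np.all(comp.armCorr >= -1.0) and np.all(comp.armCorr <= 1.0)
        assert np.all(comp.armMo >= 0) and np.all(comp.kickRot >= 0)
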