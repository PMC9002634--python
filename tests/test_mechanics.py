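"""Tendon force, moment arm, rotation correction and stiffness index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tendonmetrics as tm

from conftest import noiseless_config


class TestTendonForce:
    def test_hand_computation(self):
        """M = 60 N*m over a 50 mm moment arm gives 60 / 0.05 = 1200 N."""
        assert tm.tendon_force(np.array([60.0]), 50.0)[0] == pytest.approx(1200.0)

    def test_zero_moment(self):
        assert tm.tendon_force(np.array([0.0]), 50.0)[0] == 0.0

    def test_nonpositive_arm_rejected(self):
        with pytest.raises(tm.ValidationError):
            tm.tendon_force(np.array([1.0]), 0.0)


class TestMomentArmFromPoints:
    def test_vertical_line(self):
        assert tm.moment_arm_from_points((0, 0), (50, 0), (50, 100)) == pytest.approx(
            50.0
        )

    def test_hand_geometry(self):
        assert tm.moment_arm_from_points((10, 10), (0, 0), (0, 1)) == pytest.approx(
            10.0
        )

    def test_coincident_points_rejected(self):
        with pytest.raises(tm.ValidationError):
            tm.moment_arm_from_points((0, 0), (3, 4), (3, 4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-np.pi, np.pi), st.floats(-50, 50), st.floats(-50, 50))
    def test_isometry_invariance(self, rot, tx, ty):
        pts = np.array([[0.0, 0.0], [30.0, -5.0], [35.0, 90.0]])
        base = tm.moment_arm_from_points(*pts)
        c, s = np.cos(rot), np.sin(rot)
        moved = pts @ np.array([[c, s], [-s, c]]) + np.array([tx, ty])
        assert tm.moment_arm_from_points(*moved) == pytest.approx(base, abs=1e-9)


class TestRotationExcursion:
    def test_product_and_sign(self):
        assert tm.rotation_excursion(50.0, 0.04) == pytest.approx(2.0)
        assert tm.rotation_excursion(50.0, 0.0) == 0.0
        assert tm.rotation_excursion(50.0, -0.04) == pytest.approx(-2.0)


class TestTwoFrameProperties:
    def test_noiseless_recovery(self, clean_trial):
        cfg, record, truth, constants = clean_trial
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        props = tm.two_frame_properties(aligned, constants)
        assert props.method == "two_frame"
        assert props.valid
        assert props.stiffness_index_kn_per_strain == pytest.approx(
            truth.stiffness_index, rel=0.005
        )
        assert props.f_max_n == pytest.approx(truth.f_max_n, rel=1e-6)
        assert props.delta_theta_rad == pytest.approx(truth.delta_theta_rad, rel=1e-3)

    def test_stiffness_strain_consistency(self, clean_trial):
        """Internal invariants: stiffness = (f_max/1000)/strain and
        strain = dl_max / resting length."""
        cfg, record, truth, constants = clean_trial
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        props = tm.two_frame_properties(aligned, constants)
        assert props.stiffness_index_kn_per_strain == pytest.approx(
            (props.f_max_n / 1000.0) / props.strain_max, abs=1e-9
        )
        assert props.strain_max == pytest.approx(
            props.dl_max_mm / constants.resting_length_mm, abs=1e-12
        )

    def test_zero_rotation_leaves_measured_displacement(self):
        cfg = noiseless_config(joint_compliance_rad_per_nm=0.0)
        rng = np.random.default_rng(5)
        subject = tm.draw_subject(cfg, "s", rng)
        record, _ = tm.simulate_trial(cfg, subject, rng)
        constants = tm.AnatomicalConstants(
            subject.moment_arm_mm, subject.resting_length_mm,
            cfg.load_cell_positions_m,
        )
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        props = tm.two_frame_properties(aligned, constants)
        assert props.dl_max_mm == pytest.approx(props.dl_measured_mm, abs=1e-9)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        """The published day-level stiffness (71.6) is the mean of per-trial
        force/strain ratios, not the ratio of the mean force to the mean
        strain (4351/1000/0.063 = 69.06): the two aggregations differ and
        the package reports per-trial ratios."""
        f = np.array([3000.0, 4351.0, 5700.0])
        eps = np.array([0.050, 0.063, 0.076])
        ratio_of_means = (f.mean() / 1000.0) / eps.mean()
        mean_of_ratios = np.mean((f / 1000.0) / eps)
        assert (4351.0 / 1000.0) / 0.063 == pytest.approx(69.06, abs=0.01)
        assert mean_of_ratios != pytest.approx(ratio_of_means, rel=1e-3)

    def test_negative_corrected_strain_flagged_invalid(self, clean_trial):
        cfg, record, truth, constants = clean_trial
        # absurdly large moment arm makes the rotation correction overshoot
        bad = tm.AnatomicalConstants(
            moment_arm_mm=2000.0,
            resting_length_mm=constants.resting_length_mm,
            load_cell_positions_m=constants.load_cell_positions_m,
        )
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        props = tm.two_frame_properties(aligned, bad)
        assert not props.valid
        assert np.isnan(props.stiffness_index_kn_per_strain)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(100, 9000), st.floats(0.005, 0.15))
    def test_stiffness_scaling_property(self, f_max, strain):
        """Stiffness index scales linearly with force and inversely with
        strain."""
        k = (f_max / 1000.0) / strain
        k2 = (2.0 * f_max / 1000.0) / strain
        k3 = (f_max / 1000.0) / (2.0 * strain)
        assert k2 == pytest.approx(2.0 * k, rel=1e-12)
        assert k3 == pytest.approx(0.5 * k, rel=1e-12)


class TestFrameByFrame:
    def test_endpoint_matches_series_two_frame_displacement(self, clean_trial):
        """On a monotone noiseless trial the curve endpoint equals the
        displacement between the rest and maximal-force frames."""
        cfg, record, truth, constants = clean_trial
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        curve, props = tm.frame_by_frame_curve(aligned, constants)
        assert curve.measured_elongation_mm[-1] == pytest.approx(
            props.dl_measured_mm, abs=1e-12
        )
        assert curve.force_n[-1] == pytest.approx(props.f_max_n, abs=1e-9)
        assert curve.elongation_mm[0] == pytest.approx(0.0, abs=1e-9)

    def test_linear_law_slope_recovers_true_stiffness(self, clean_trial):
        cfg, record, truth, constants = clean_trial
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        curve, _ = tm.frame_by_frame_curve(aligned, constants)
        sel = curve.force_n > 0.2 * curve.force_n.max()
        slope = np.polyfit(curve.elongation_mm[sel], curve.force_n[sel], 1)[0]
        k_from_slope = slope * constants.resting_length_mm / 1000.0
        assert k_from_slope == pytest.approx(truth.stiffness_index, rel=0.005)

    def test_short_landmark_series_rejected(self, clean_trial):
        cfg, record, _, constants = clean_trial
        record.landmark_time_s = record.landmark_time_s[:2]
        record.landmark_mm = record.landmark_mm[:2]
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        with pytest.raises(tm.ValidationError):
            tm.frame_by_frame_curve(aligned, constants)

    def test_methods_identical_without_noise(self, clean_trial):
        """Two-frame and frame-by-frame measured maximal strain coincide on
        noiseless trials (same frames, same digitization)."""
        cfg, record, truth, constants = clean_trial
        aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
        two = tm.two_frame_properties(aligned, constants)
        _, fbf = tm.frame_by_frame_curve(aligned, constants)
        assert two.measured_strain_max == pytest.approx(
            fbf.measured_strain_max, abs=1e-9
        )
        assert two.stiffness_index_kn_per_strain == pytest.approx(
            fbf.stiffness_index_kn_per_strain, rel=1e-6
        )
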