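"""Ring calibration, angle handling, tilt correction and length conversion."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenoseed as ps


def make_obs(rows):
    return pd.DataFrame(rows, columns=["seedling_id", "radial_px", "observed_perimeter_px"])


class TestFitRingCalibration:
    def test_two_ring_direct_quotient(self):
        obs = make_obs([(1, 10.0, 100.0), (1, 500.0, 125.0)])
        model = ps.fit_ring_calibration(obs, n_rings=2, ring_edges_px=[50.0, 600.0])
        np.testing.assert_allclose(model.ring_ratio, [1.0, 0.8])

    def test_undistorted_camera_yields_unit_ratios(self):
        cfg = ps.SceneConfig(k1=0.0, seed=6)
        obs = ps.generate_calibration_set(cfg, n_groups=3, seed=6)
        model = ps.fit_ring_calibration(obs, n_rings=3, center_px=cfg.center_px)
        np.testing.assert_allclose(model.ring_ratio, 1.0, atol=0.01)

    def test_distorted_ratios_match_analytic_warp(
        self, scene_cfg, calibration_obs, calibration_model
    ):
        """Fitted ratios track the analytic radial arc stretch of the warp."""
        model = calibration_model
        assert model.ring_ratio[2] < model.ring_ratio[1] < 1.0
        obs = calibration_obs.copy()
        obs["ring"] = [model.ring_of(r) for r in obs.radial_px]
        k1, hd = scene_cfg.k1, scene_cfg.half_diag_px
        for ring in (1, 2):
            r_obs = obs.loc[obs.ring == ring, "radial_px"].mean()
            rho = r_obs / (1 + k1 * (r_obs / hd) ** 2)  # undo warp of the centroid
            analytic = 1.0 / (1.0 + 3 * k1 * (rho / hd) ** 2)
            assert model.ring_ratio[ring] == pytest.approx(analytic, rel=0.02)

    def test_empty_ring_is_named(self):
        obs = make_obs([(1, 10.0, 100.0), (1, 900.0, 120.0)])
        with pytest.raises(ValueError, match="ring 1"):
            ps.fit_ring_calibration(obs, ring_edges_px=[50.0, 500.0, 1000.0])

    def test_unanchored_seedling_excluded_with_warning(self):
        obs = make_obs(
            [(1, 10.0, 100.0), (1, 500.0, 125.0), (2, 400.0, 200.0), (2, 550.0, 202.0)]
        )
        with pytest.warns(UserWarning, match=r"\[2\]"):
            model = ps.fit_ring_calibration(obs, n_rings=2, ring_edges_px=[50.0, 600.0])
        np.testing.assert_allclose(model.ring_ratio, [1.0, 0.8])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ps.fit_ring_calibration(pd.DataFrame({"seedling_id": [1]}))


class TestCorrectPerimeter:
    @pytest.fixture()
    def model(self):
        return ps.CalibrationModel(
            center_px=(800.0, 800.0),
            ring_edges_px=np.array([100.0, 500.0, 900.0]),
            ring_ratio=np.array([1.0, 0.9, 0.8]),
            n_obs=np.array([10, 10, 10]),
        )

    def test_centre_unchanged(self, model):
        assert ps.correct_perimeter(123.0, (800.0, 800.0), model) == 123.0

    def test_ring_ratio_applied(self, model):
        assert ps.correct_perimeter(125.0, (800.0, 1500.0), model) == pytest.approx(100.0)

    def test_beyond_outermost_warns_and_uses_last(self, model):
        with pytest.warns(UserWarning, match="outermost"):
            out = ps.correct_perimeter(100.0, (800.0, 1750.0), model)
        assert out == pytest.approx(80.0)

    def test_negative_perimeter_rejected(self, model):
        with pytest.raises(ValueError):
            ps.correct_perimeter(-1.0, (800.0, 800.0), model)

    def test_innermost_ratio_must_be_one(self):
        with pytest.raises(ValueError):
            ps.CalibrationModel(
                center_px=(0, 0),
                ring_edges_px=np.array([10.0, 20.0]),
                ring_ratio=np.array([0.9, 0.8]),
                n_obs=np.array([1, 1]),
            )


class TestSmoothAngle:
    def test_lambda_zero_returns_raw(self):
        assert ps.smooth_angle(70.0, lam=0.0) == 70.0

    def test_lambda_one_snaps_to_prior(self):
        assert ps.smooth_angle(70.0, lam=1.0) == 45.0

    def test_within_tolerance_band_unshrunk(self):
        assert ps.smooth_angle(50.0, lam=1.0) == 50.0

    def test_wrap_aware_across_north(self):
        # raw 5 deg: nearest prior 45 (delta +40); shrink half-way -> 25
        assert ps.smooth_angle(5.0, lam=0.5) == pytest.approx(25.0)
        # raw 355: nearest prior 315, delta -40 -> 335
        assert ps.smooth_angle(355.0, lam=0.5) == pytest.approx(335.0)

    def test_empty_priors_identity_with_warning(self):
        with pytest.warns(UserWarning):
            assert ps.smooth_angle(70.0, priors=(), lam=1.0) == 70.0

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            ps.smooth_angle(70.0, lam=1.5)


class TestRotateAlign:
    def test_zero_rotation_identity(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(ps.rotate_align(pts, 0.0), pts)

    def test_quarter_turn_about_origin(self):
        out = ps.rotate_align(np.array([[1.0, 0.0]]), 90.0, origin=(0.0, 0.0))
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=8),
           st.floats(-360, 360))
    def test_isometry(self, pts, theta):
        pts = np.asarray(pts, float)
        out = ps.rotate_align(pts, theta)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_arc_length_preserved(self):
        rng = np.random.default_rng(1)
        poly = rng.normal(size=(20, 2)) * 10
        arc = lambda p: np.hypot(*np.diff(p, axis=0).T).sum()
        assert arc(ps.rotate_align(poly, 37.0)) == pytest.approx(arc(poly), abs=1e-9)


class TestTiltFactor:
    def test_in_plane_is_identity(self):
        assert ps.tilt_factor(90.0) == 1.0

    def test_45_degrees_is_sqrt2(self):
        assert ps.tilt_factor(45.0) == pytest.approx(math.sqrt(2.0), abs=1e-12)

    def test_below_clamp_capped_at_two(self):
        assert ps.tilt_factor(10.0) == pytest.approx(2.0)

    def test_monotone_non_increasing_on_trusted_range(self):
        tilts = np.linspace(30.0, 90.0, 61)
        factors = [ps.tilt_factor(t) for t in tilts]
        assert all(a >= b - 1e-12 for a, b in zip(factors, factors[1:]))
        assert ps.tilt_factor(29.0) == ps.tilt_factor(30.0)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            ps.tilt_factor(95.0)


class TestAgeFilter:
    @pytest.mark.parametrize(
        "conf,age,kept",
        [(0.5, 30.0, True), (0.5, 70.0, False), (1.0, 30.0, True),
         (1.0, 70.0, True), (0.3, 30.0, False), (0.6, 70.0, True)],
    )
    def test_threshold_switches_with_age(self, conf, age, kept):
        df = pd.DataFrame({"confidence": [conf], "age_h": [age]})
        out = ps.age_filter(df, cutoff_age_h=60.0)
        assert (len(out) == 1) is kept

    def test_invalid_confidence_rejected(self):
        df = pd.DataFrame({"confidence": [1.2], "age_h": [10.0]})
        with pytest.raises(ValueError):
            ps.age_filter(df)


class TestTrueLength:
    def test_direct_formula_at_centre(self):
        model = ps.CalibrationModel(
            center_px=(800.0, 800.0),
            ring_edges_px=np.array([800.0]),
            ring_ratio=np.array([1.0]),
            n_obs=np.array([1]),
        )
        out = ps.true_length(200.0, (800.0, 800.0), 90.0, model, ps.SceneConfig())
        assert out == pytest.approx(100.0 * 25.0 / 1600.0)  # 1.5625 cm

    def test_composition_applies_ring_then_tilt(self):
        model = ps.CalibrationModel(
            center_px=(800.0, 800.0),
            ring_edges_px=np.array([100.0, 1200.0]),
            ring_ratio=np.array([1.0, 0.8]),
            n_obs=np.array([1, 1]),
        )
        out = ps.true_length(200.0, (800.0, 1400.0), 45.0, model, ps.SceneConfig())
        assert out == pytest.approx(200.0 * 0.8 / 2 * math.sqrt(2) * 25 / 1600)

    def test_correction_tightens_every_outer_ring(
        self, scene_measurements, calibration_model
    ):
        """Distortion correction brings lengths closer to truth in every
        ring beyond the anchor."""
        corr = scene_measurements["corrected"]
        unc = scene_measurements["uncorrected"]
        cx, cy = calibration_model.center_px
        radial = np.hypot(corr.centroid_x_px - cx, corr.centroid_y_px - cy)
        rings = np.array([calibration_model.ring_of(r) for r in radial])
        for ring in range(1, calibration_model.n_rings):
            sel = rings == ring
            assert sel.any()
            assert (
                np.median(np.abs(corr.rel_err[sel]))
                < np.median(np.abs(unc.rel_err[sel]))
            )


class TestAgreementSlope:
    def test_identity_slope_one(self):
        x = np.linspace(1, 5, 10)
        slope, intercept = ps.agreement_slope(x, x)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubling_slope_two(self):
        x = np.linspace(1, 5, 10)
        slope, _ = ps.agreement_slope(x, 2 * x)
        assert slope == pytest.approx(2.0)

    def test_constant_manual_rejected(self):
        with pytest.raises(ValueError):
            ps.agreement_slope([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noisy_pairs_within_oracle_standard_error(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1.0, 6.0, 20)
        y = 0.95 * x + rng.normal(0.0, 0.05, 20)
        slope, _ = ps.agreement_slope(x, y)
        # independent normal-equations oracle
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        oracle_slope = sxy / sxx
        se = 0.05 / math.sqrt(sxx)
        assert slope == pytest.approx(oracle_slope, abs=1e-9)
        assert abs(slope - 0.95) < 3 * se

    def test_module_agrees_with_truth_on_fixture_scene(self, scene_measurements):
        """Corrected module lengths regress on ground truth with slope ~1."""
        corr = scene_measurements["corrected"]
        slope, _ = ps.agreement_slope(corr.true_length_cm, corr.length_cm)
        assert slope == pytest.approx(1.0, abs=0.05)


def test_measure_scene_accepts_label_image(scene_cfg, fixture_scene, calibration_model):
    label, truth, masks = fixture_scene
    sub = truth.head(3)
    lab = np.where(np.isin(label, sub.id.to_numpy()), label, 0).astype(np.uint16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = ps.measure_scene(lab, sub[["id", "tilt_deg"]], calibration_model, scene_cfg)
    assert set(df.id) == set(sub.id)
    assert (df.length_cm > 0).all()
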