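"""Sole-normal estimators, force projection, mirroring and correction."""

import numpy as np
import pytest

import skategrf as sg
from skategrf.direction_estimator import estimate_trial
from skategrf.errors import (
    ConfigurationError,
    ContractError,
    FitError,
    GeometryError,
)


class TestEstimateDirection:
    def test_upright_shank_flat_blade(self):
        z = sg.estimate_direction([0, 0, 0], [0.3, 0, 0], [0.15, 0, 0.40])
        assert np.allclose(z, [0, 0, 1], atol=1e-12)

    def test_tilted_joint_hand_case(self):
        # y_b=(1,0,0); lever=(0.5,0.3,0.4); y_b x lever=(0,-0.4,0.3)
        # x_b=(0,-0.8,0.6); y_b x x_b=(0,-0.6,-0.8) -> flipped to (0,0.6,0.8)
        z = sg.estimate_direction([0, 0, 0], [1, 0, 0], [0.5, 0.3, 0.4])
        assert np.allclose(z, [0, 0.6, 0.8], atol=1e-12)

    def test_blade_along_y_hand_case(self):
        z = sg.estimate_direction([0, 0, 0], [0, 1, 0], [0, 0.3, 1])
        assert np.allclose(z, [0, 0, 1], atol=1e-12)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            sg.estimate_direction([0, 0, 0], [1, 0, 0], [0.5, 0, 0])
        with pytest.raises(GeometryError):
            sg.estimate_direction([0, 0, 0], [0, 0, 0], [0.5, 0.3, 0.4])

    def test_perpendicular_to_blade_and_unit(self):
        rng = np.random.default_rng(7)
        rear = rng.normal(size=(200, 3))
        front = rear + rng.normal(size=(200, 3))
        joint = rear + rng.normal(size=(200, 3)) + [0, 0, 2.0]
        z = sg.estimate_direction(rear, front, joint)
        y_b = front - rear
        y_b /= np.linalg.norm(y_b, axis=1)[:, None]
        assert np.allclose(np.einsum("ij,ij->i", z, y_b), 0.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(z, axis=1), 1.0, atol=1e-9)
        assert np.all(z[:, 2] > 0)

    def test_frame_equivariance_under_z_rotation(self):
        """Rotating markers and frame together leaves local components fixed."""
        rear = np.array([0.1, 0.2, 0.0])
        front = np.array([0.4, 0.25, 0.0])
        joint = np.array([0.2, 0.2, 0.45])
        vel = np.array([[0.5, 4.0, 0.0]])
        e0 = sg.to_local(
            sg.estimate_direction(rear, front, joint), sg.local_frame(vel)
        )
        ang = 1.1
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        e1 = sg.to_local(
            sg.estimate_direction(R @ rear, R @ front, R @ joint),
            sg.local_frame(vel @ R.T),
        )
        assert np.allclose(e0, e1, atol=1e-9)

    def test_longer_lever_is_less_noise_sensitive(self):
        """Knee-lever estimates beat ankle-lever ones under marker noise.

        With isotropic 3 mm noise on all four markers, the angular error of
        the sole normal scales like noise / lever length, so the ~2x longer
        knee lever halves the mean error.
        """
        rear = np.array([0.0, 0.0, 0.0])
        front = np.array([0.3, 0.0, 0.0])
        ankle = np.array([0.15, 0.05, 0.25])  # lever ~0.30 m
        knee = np.array([0.15, 0.12, 0.55])  # lever ~0.60 m (~2x)
        truth = {
            "Est1": sg.estimate_direction(rear, front, ankle, "Est1"),
            "Est2": sg.estimate_direction(rear, front, knee, "Est2"),
        }
        rng = np.random.default_rng(123)
        n = 1000
        noisy = {
            name: pt + rng.normal(0, 0.003, (n, 3))
            for name, pt in [("rear", rear), ("front", front), ("ankle", ankle), ("knee", knee)]
        }
        ang = {}
        for method, joint in [("Est1", "ankle"), ("Est2", "knee")]:
            z = sg.estimate_direction(noisy["rear"], noisy["front"], noisy[joint], method)
            dots = np.clip(z @ truth[method], -1, 1)
            ang[method] = np.mean(np.arccos(dots))
        assert ang["Est2"] < ang["Est1"]


class TestGrfComponents:
    def test_scalar_multiply(self):
        est = sg.grf_components(np.array([1.5]), np.array([[0, 0.6, 0.8]]))
        assert np.allclose(est.components, [[0, 0.9, 1.2]])

    def test_zero_force_and_vertical_standing(self):
        assert np.allclose(
            sg.grf_components(np.array([0.0]), np.array([[0, 0, 1.0]])).components, 0
        )
        assert np.allclose(
            sg.grf_components(np.array([1.0]), np.array([[0, 0, 1.0]])).components,
            [[0, 0, 1.0]],
        )

    def test_norm_equals_resultant(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=(50, 3))
        e /= np.linalg.norm(e, axis=1)[:, None]
        F = rng.uniform(0, 2, 50)
        est = sg.grf_components(F, e)
        assert np.allclose(np.linalg.norm(est.components, axis=1), F, atol=1e-12)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ContractError):
            sg.grf_components(np.array([1.0]), np.array([[0, 0, 2.0]]))


class TestMirrorLeft:
    def test_negates_x_only_and_is_involutive(self):
        v = np.array([[0.2, 0.1, 1.0], [0.0, 0.1, 1.0]])
        m = sg.mirror_left(v)
        assert np.allclose(m, [[-0.2, 0.1, 1.0], [0.0, 0.1, 1.0]])
        assert np.allclose(sg.mirror_left(m), v)


class TestCorrection:
    def test_default_model_pointwise(self):
        model = sg.default_correction()
        est = sg.EstimatedGRF(
            components=np.array([[0.0, 1.0, 1.0]]), method="Est2"
        )
        out = sg.apply_correction(est, model, motion="curve-left")
        assert out.components[0, 0] == pytest.approx(-0.029)
        assert out.components[0, 1] == pytest.approx(0.596 * 1.0 - 0.025)
        assert out.components[0, 2] == pytest.approx(0.987 * 1.0 + 0.030)
        assert out.corrected

    def test_motion_mismatch_needs_override(self):
        est = sg.EstimatedGRF(components=np.zeros((1, 3)), method="Est2")
        with pytest.raises(ConfigurationError):
            sg.apply_correction(est, motion="straight")
        out = sg.apply_correction(est, motion="straight", override=True)
        assert out.corrected

    def test_fit_exact_linear(self):
        x = np.linspace(-1, 1, 21)
        est = np.column_stack([x, x, x])
        true = 0.9 * est + 0.1
        model = sg.fit_correction(true, est)
        assert np.allclose(model.slopes, 0.9, atol=1e-12)
        assert np.allclose(model.intercepts, 0.1, atol=1e-12)
        ident = sg.fit_correction(est, est)
        assert np.allclose(ident.slopes, 1.0, atol=1e-12)
        assert np.allclose(ident.intercepts, 0.0, atol=1e-12)

    def test_fit_recovers_under_noise(self):
        rng = np.random.default_rng(9)
        x = np.linspace(-1, 1, 200)
        est = np.column_stack([x, x, x])
        true = 0.85 * est - 0.03 + rng.normal(0, 0.01, est.shape)
        model = sg.fit_correction(true, est)
        assert np.allclose(model.slopes, 0.85, atol=0.02)
        assert np.allclose(model.intercepts, -0.03, atol=0.01)

    def test_fit_zero_variance_raises(self):
        with pytest.raises(FitError):
            sg.fit_correction(np.ones((5, 3)), np.ones((5, 3)))


class TestTrialPipeline:
    def test_est2_beats_est1_on_noisy_trial(self, small_cohorts):
        for motion, trials in small_cohorts.items():
            r1 = sg.cohort_rmse(trials, "Est1", cutoff_policy="fixed:12")
            r2 = sg.cohort_rmse(trials, "Est2", cutoff_policy="fixed:12")
            for comp in "XYZ":
                assert r2[comp] < r1[comp], (motion, comp)

    def test_left_straight_trial_is_mirrored(self):
        cfg = sg.SimulationConfig(side="left", marker_noise_sd=0.0, seed=2)
        trial = sg.simulate_stride(cfg)
        _, est, _, _ = estimate_trial(
            trial.raw, "Est2", motion="straight",
            cutoff_policy="none", antialias=False,
        )
        # generator mirrors its stored truth the same way
        assert np.allclose(est.components, trial.truth_components_local, atol=1e-9)
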