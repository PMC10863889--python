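"""Anatomical frames, joint centres, stance windowing, joint angles."""

import numpy as np
import pytest

import footmech as fm
from footmech.config import PipelineConfig
from footmech.errors import DegenerateGeometryError, NoContactError, ParameterError
from footmech.foot_models import StanceWindow, _rearfoot_frame
from footmech.synthetic_data import DEFAULT_GEOMETRY


class TestAnatomicalFrames:
    def test_rearfoot_x_axis_from_markers(self):
        m = {"CA": np.zeros(3), "M1H": np.array([0.15, 0.0, 0.02]),
             "M5H": np.array([0.13, 0.0, -0.04])}
        # make the foot plane non-degenerate by lifting the heel slightly
        m["CA"] = np.array([0.0, 0.01, 0.0])
        R = _rearfoot_frame(m, fm.LabConfig())
        expect_x = (m["M1H"] - m["CA"]) / np.linalg.norm(m["M1H"] - m["CA"])
        assert np.abs(R[:, 0] - expect_x).max() < 1e-12
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-12

    def test_all_frames_orthonormal_right_handed(self, clean_trial, nofilter_config):
        bundle, _ = clean_trial
        for model_id in ("SINGLE", "MULTI"):
            model = fm.make_model(model_id, nofilter_config)
            frames = fm.build_anatomical_frames(bundle.static, model,
                                                nofilter_config.lab)
            for name, R in frames.items():
                assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10, name
                assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
                assert R[1, 1] > 0  # y-axes point superiorly in standing

    def test_single_and_multi_share_ankle_frames(self, clean_trial, nofilter_config):
        bundle, _ = clean_trial
        fM = fm.build_anatomical_frames(bundle.static,
                                        fm.make_model("MULTI", nofilter_config))
        fS = fm.build_anatomical_frames(bundle.static,
                                        fm.make_model("SINGLE", nofilter_config))
        assert np.array_equal(fM["RF"], fS["FOOT"])
        assert np.array_equal(fM["SHANK"], fS["SHANK"])

    def test_collinear_markers_rejected(self):
        m = {"CA": np.zeros(3), "M1H": np.array([0.15, 0.0, 0.0]),
             "M5H": np.array([0.30, 0.0, 0.0])}
        with pytest.raises(DegenerateGeometryError):
            _rearfoot_frame(m, fm.LabConfig())


class TestJointCenters:
    def test_definitions(self, nofilter_config):
        model = fm.make_model("MULTI", nofilter_config)
        markers = {"MMAL": np.array([0.0, 0.07, -0.03]),
                   "LMAL": np.array([0.0, 0.07, 0.04]),
                   "NT": np.array([0.09, 0.03, -0.02]),
                   "M5B": np.array([0.09, 0.03, -0.02]),
                   "M1H": np.array([0.16, 0.03, -0.03])}
        centers = fm.joint_centers(markers, model)
        assert np.allclose(centers["ankle"], [0.0, 0.07, 0.005])
        assert np.allclose(centers["midtarsal"], markers["NT"])  # NT == M5B
        assert np.array_equal(centers["mtp"], markers["M1H"])


class TestStance:
    def make_forces(self, fy, rate=1500.0):
        n = len(fy)
        force = np.stack([np.zeros(n), fy, np.zeros(n)], axis=1)
        return fm.ForcePlateRecord(rate, force, np.full((n, 3), np.nan),
                                   np.zeros(n))

    def test_double_peak_window(self):
        t = np.arange(0, 0.5, 1 / 1500)
        fy = np.where((t >= 0.10) & (t <= 0.33),
                      800 * np.sin(np.pi * (t - 0.10) / 0.23) + 25, 0.0)
        w = fm.detect_stance(self.make_forces(fy), threshold=20.0)
        assert abs(w.first / 1500 - 0.10) < 0.005
        assert abs(w.last / 1500 - 0.33) < 0.005

    def test_no_contact(self):
        with pytest.raises(NoContactError):
            fm.detect_stance(self.make_forces(np.zeros(100)))

    def test_always_loaded_warns_full_record(self):
        with pytest.warns(UserWarning):
            w = fm.detect_stance(self.make_forces(np.full(100, 500.0)))
        assert (w.first, w.last) == (0, 99)

    def test_debounce_drops_spikes(self):
        fy = np.zeros(1500)
        fy[10:12] = 100.0          # 1.3 ms spike: below the 10 ms debounce
        fy[600:900] = 600.0
        w = fm.detect_stance(self.make_forces(fy), threshold=20.0)
        assert w.first == 600


class TestTimeNormalize:
    def test_constant(self):
        w = StanceWindow(2, 42, 150.0)
        out = fm.time_normalize(np.full(60, 7.0), w)
        assert out.shape == (101,)
        assert np.allclose(out, 7.0)

    def test_linear_ramp_exact(self):
        w = StanceWindow(0, 59, 150.0)
        out = fm.time_normalize(np.arange(60.0), w)
        assert np.allclose(out, np.linspace(0, 59, 101), atol=1e-12)

    def test_sine_against_analytic(self):
        rate = 150.0
        t = np.arange(0, 1.0, 1 / rate)
        x = np.sin(2 * np.pi * 2.0 * t)
        w = StanceWindow(10, 120, rate)
        out = fm.time_normalize(x, w)
        t_nodes = np.linspace(10, 120, 101) / rate
        assert np.abs(out - np.sin(2 * np.pi * 2.0 * t_nodes)).max() < 1e-3

    def test_window_outside_record_rejected(self):
        with pytest.raises(ParameterError):
            fm.time_normalize(np.arange(10.0), StanceWindow(5, 30, 150.0))


class TestExcursion:
    @pytest.mark.parametrize("series,expect", [
        (np.full(50, 3.0), 0.0),
        (10 * np.sin(np.linspace(0, 2 * np.pi, 101)), 20.0),
    ])
    def test_known_values(self, series, expect):
        assert fm.excursion(series) == pytest.approx(expect, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 5, 101)
        assert fm.excursion(x) == max(x) - min(x)


class TestJointAngles:
    def test_static_dynamic_identical_gives_zero(self, nofilter_config):
        spec = fm.SyntheticTrialSpec(noise_sigma=0.0)
        bundle, _ = fm.generate_running_trial(spec, nofilter_config)
        # replace the dynamic trial by the static geometry, rigidly held
        n = bundle.dynamic.n_frames
        names = list(bundle.static.names)
        pos = np.tile(bundle.static.positions[0], (n, 1, 1))
        still = fm.MarkerTrajectorySet(bundle.dynamic.rate, names, pos)
        bundle = fm.TrialBundle(bundle.static, still, bundle.forces, bundle.subject)
        for model_id in ("SINGLE", "MULTI"):
            angles = fm.compute_joint_angles(
                bundle, fm.make_model(model_id, nofilter_config), nofilter_config)
            for jas in angles.values():
                assert jas.angles.shape == (101, 3)
                assert np.abs(jas.angles).max() < 1e-9

    def test_rigid_foot_collapse(self, nofilter_config):
        bundle, _ = fm.generate_rigid_foot_trial(
            fm.SyntheticTrialSpec(noise_sigma=0.0), nofilter_config)
        kM = fm.compute_trial_kinematics(bundle, fm.make_model("MULTI", nofilter_config),
                                         nofilter_config)
        aM = fm.compute_joint_angles(kM, config=nofilter_config)
        aS = fm.compute_joint_angles(bundle, fm.make_model("SINGLE", nofilter_config),
                                     nofilter_config)
        assert np.abs(aM["midtarsal"].angles).max() < 1e-8
        assert np.abs(aM["mtp"].angles).max() < 1e-8
        assert np.abs(aM["ankle"].angles - aS["ankle"].angles).max() < 1e-8

    def test_midfoot_motion_inflates_single_ankle_excursion(self, clean_trial,
                                                            nofilter_config):
        bundle, _ = clean_trial
        aM = fm.compute_joint_angles(bundle, fm.make_model("MULTI", nofilter_config),
                                     nofilter_config)
        aS = fm.compute_joint_angles(bundle, fm.make_model("SINGLE", nofilter_config),
                                     nofilter_config)
        excS = fm.excursion(aS["ankle"].angles[:, 0])
        excM = fm.excursion(aM["ankle"].angles[:, 0])
        assert excS > excM

    def test_clinical_sign_conventions(self, nofilter_config):
        """Geometric sign checks for a right foot: toes up = dorsiflexion+,
        medial sole border up = inversion+, toes swung laterally =
        abduction+."""
        geometry = {k: np.asarray(v, float) for k, v in DEFAULT_GEOMETRY.items()}
        names = list(geometry.keys())
        static_pos = np.tile(np.stack([geometry[k] for k in names]), (5, 1, 1))
        static = fm.MarkerTrajectorySet(150.0, names, static_pos)
        model = fm.make_model("MULTI", nofilter_config)
        ankle0 = 0.5 * (geometry["MMAL"] + geometry["LMAL"])
        foot = [k for k in names if k not in
                ("MMAL", "LMAL", "SH1", "SH2", "SH3", "SH4", "SH5", "SH6",
                 "SH7", "SH8")]

        def rotated_trial(axis, deg):
            c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + s * K + (1 - c) * (K @ K)
            pos = static_pos.copy()
            idx = [names.index(k) for k in foot]
            pos[:, idx, :] = (pos[:, idx, :] - ankle0) @ R.T + ankle0
            n = 30
            pos = np.tile(pos[:1], (n, 1, 1))
            dyn = fm.MarkerTrajectorySet(150.0, names, pos)
            fy = np.full(n * 10, 500.0)
            forces = fm.ForcePlateRecord(
                1500.0, np.stack([0 * fy, fy, 0 * fy], 1),
                np.tile(ankle0 * [1, 0, 1], (n * 10, 1)), np.zeros(n * 10))
            with pytest.warns(UserWarning):  # always-loaded stance
                bundle = fm.TrialBundle(static, dyn, forces,
                                        fm.SubjectMeta(70, 0.25, 0.4))
                angles = fm.compute_joint_angles(bundle, model, nofilter_config)
            return angles["ankle"].angles.mean(axis=0)

        up = rotated_trial([0, 0, 1], 10.0)       # toes rise: dorsiflexion
        assert up[0] > 5.0
        inv = rotated_trial([1, 0, 0], 10.0)      # medial border rises
        assert inv[1] > 5.0
        abd = rotated_trial([0, -1, 0], 10.0)     # toes swing laterally
        assert abd[2] > 5.0
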