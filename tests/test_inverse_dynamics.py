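"""GRF assignment, Newton-Euler recursion, power and work accounting."""

import numpy as np
import pytest

import footmech as fm
from footmech.anthropometry import InertialParams
from footmech.errors import ParameterError
from footmech.inverse_dynamics import (
    LoadAssignmentSeries,
    assign_grf,
    free_body_joint_loads,
    joint_power,
    joint_work,
    newton_euler,
    normalize_by_mass,
)
from footmech.io_formats import ForcePlateRecord
from footmech.planar import default_links, generate_planar_consistent_case

from conftest import random_rotations


class TestAssignGrf:
    centers = {"midtarsal": np.array([0.095, 0.03, 0.01]),
               "mtp": np.array([0.16, 0.03, -0.03])}
    axis = np.array([1.0, 0.05, 0.0])

    def test_heel_to_rearfoot(self):
        assert assign_grf([0.01, 0, 0], self.centers, self.axis) == "RF"

    def test_between_centers_to_forefoot(self):
        mid = 0.5 * (self.centers["midtarsal"] + self.centers["mtp"])
        assert assign_grf(mid * [1, 0, 1], self.centers, self.axis) == "FF"

    def test_boundary_assigns_distally(self):
        on_mtp = self.centers["mtp"] * [1, 0, 1]
        assert assign_grf(on_mtp, self.centers, self.axis) == "TOE"

    def test_matches_brute_force_interval_rule(self):
        rng = np.random.default_rng(31)
        ax = self.axis / np.linalg.norm(self.axis * [1, 0, 1])
        axh = self.axis * [1, 0, 1]
        axh = axh / np.linalg.norm(axh)
        s_mt = self.centers["midtarsal"] @ axh
        s_mtp = self.centers["mtp"] @ axh
        for _ in range(200):
            cop = np.array([rng.uniform(-0.05, 0.3), 0.0, rng.uniform(-0.05, 0.05)])
            s = cop @ axh
            expect = "RF" if s < s_mt else ("FF" if s < s_mtp else "TOE")
            assert assign_grf(cop, self.centers, self.axis) == expect

    def test_outside_extent_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = assign_grf([0.9, 0, 0], self.centers, self.axis,
                             extent=(-0.02, 0.30))
        assert out == "TOE"


def static_kinematics(n, com):
    eye = np.repeat(np.eye(3)[None], n, axis=0)
    z = np.zeros((n, 3))
    return type("K", (), {"R_anat": eye, "omega": z.copy(), "alpha": z.copy(),
                          "com": np.tile(com, (n, 1)), "com_acc": z.copy()})()


class TestNewtonEulerStatics:
    def test_static_segment_balances_gravity(self):
        n = 5
        kin = {"S": static_kinematics(n, np.array([0.1, 0.05, 0.0]))}
        inertial = {"S": InertialParams("S", 2.0, np.diag([1e-4, 1e-3, 1e-3]))}
        forces = ForcePlateRecord(100.0, np.zeros((n, 3)),
                                  np.full((n, 3), np.nan), np.zeros(n),
                                  contact_threshold=0.0)
        assign = LoadAssignmentSeries(np.full(n, "", dtype=object))
        centers = {"J": np.zeros((n, 3))}
        out = newton_euler(["S"], ["J"], kin, inertial, assign, forces, centers)
        assert np.allclose(out["J"].force, [0.0, 2.0 * 9.81, 0.0], atol=1e-12)
        # proximal moment balances gravity about the COM: M = -r_p x F_p
        expect_m = -np.cross(np.array([-0.1, -0.05, 0.0]),
                             np.array([0.0, 19.62, 0.0]))
        assert np.allclose(out["J"].moment[0], expect_m, atol=1e-12)

    def test_massless_segment_transfers_grf_moment(self):
        # GRF (0,100,0) at COP (0.1,0,0); joint at origin; massless segment
        n = 3
        kin = {"S": static_kinematics(n, np.array([0.05, 0.02, 0.0]))}
        inertial = {"S": InertialParams("S", 0.0, np.zeros((3, 3)))}
        force = np.tile([0.0, 100.0, 0.0], (n, 1))
        cop = np.tile([0.1, 0.0, 0.0], (n, 1))
        forces = ForcePlateRecord(100.0, force, cop, np.zeros(n),
                                  contact_threshold=0.0)
        assign = LoadAssignmentSeries(np.full(n, "S", dtype=object))
        centers = {"J": np.zeros((n, 3))}
        out = newton_euler(["S"], ["J"], kin, inertial, assign, forces, centers)
        assert np.allclose(out["J"].force, [0.0, -100.0, 0.0], atol=1e-12)
        assert np.allclose(out["J"].moment[0], [0.0, 0.0, -10.0], atol=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_seg", [1, 2, 3])
    def test_recursion_equals_free_body_on_arbitrary_kinematics(self, n_seg):
        """The recursion and the direct free-body sums must agree for ANY
        kinematic input, consistent or not."""
        rng = np.random.default_rng(100 + n_seg)
        T = 40
        chain = [f"S{i}" for i in range(n_seg)]
        joints = [f"J{i}" for i in range(n_seg)]
        kin = {}
        for name in chain:
            kin[name] = type("K", (), {
                "R_anat": random_rotations(rng, T),
                "omega": rng.normal(0, 3, (T, 3)),
                "alpha": rng.normal(0, 20, (T, 3)),
                "com": rng.normal(0, 0.2, (T, 3)),
                "com_acc": rng.normal(0, 10, (T, 3))})()
        inertial = {name: InertialParams(name, rng.uniform(0.05, 1.0),
                                         np.diag(rng.uniform(1, 2, 3) * 1e-3))
                    for name in chain}
        force = rng.normal(0, 300, (T, 3))
        cop = rng.normal(0, 0.1, (T, 3))
        forces = ForcePlateRecord(100.0, force, cop, rng.normal(0, 2, T),
                                  contact_threshold=-1e9)
        assign = LoadAssignmentSeries(
            np.asarray(rng.choice(chain, T), dtype=object))
        centers = {j: rng.normal(0, 0.2, (T, 3)) for j in joints}
        out = newton_euler(chain, joints, kin, inertial, assign, forces, centers)
        for j in joints:
            F, M = free_body_joint_loads(j, chain, joints, kin, inertial,
                                         assign, forces, centers)
            assert np.abs(out[j].force - F).max() < 1e-8
            assert np.abs(out[j].moment - M).max() < 1e-8

    def test_planar_consistent_case_recovers_analytic_moments(self):
        for n in (1, 2, 3):
            case = generate_planar_consistent_case(default_links(n))
            out = newton_euler(case.chain, case.joints, case.kinematics,
                               case.inertial, case.assignment, case.forces,
                               case.joint_centers)
            for j in case.joints:
                assert np.abs(out[j].moment - case.true_moments[j]).max() < 1e-8
            base = case.joints[-1]
            assert np.abs(out[base].moment).max() < 1e-8
            assert np.abs(out[base].force).max() < 1e-8

    def test_work_energy_identity_single_segment(self):
        case = generate_planar_consistent_case(default_links(1), with_grf=False,
                                               rate=2000.0)
        out = newton_euler(case.chain, case.joints, case.kinematics,
                           case.inertial, case.assignment, case.forces,
                           case.joint_centers)
        P = joint_power(out["J0"].moment, case.kinematics["RF"].omega)
        net = joint_work(P, 1.0 / case.rate).net
        dE = case.energy[-1] - case.energy[0]
        assert abs(net - dE) <= 0.01 * max(abs(dE), 1e-9)


class TestPowerAndWork:
    def test_aligned_vectors(self):
        assert joint_power(np.array([0.0, 0, 2]), np.array([0.0, 0, 1])) == 2.0

    def test_orthogonal_vectors(self):
        assert joint_power(np.array([1.0, 0, 0]), np.array([0.0, 1, 0])) == 0.0

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(41)
        m = rng.normal(0, 1, (50, 3))
        w = rng.normal(0, 1, (50, 3))
        expect = np.array([mi @ wi for mi, wi in zip(m, w)])
        assert np.allclose(joint_power(m, w), expect, atol=1e-14)

    def test_sine_integral(self):
        t = np.linspace(0, np.pi, 20001)
        w = joint_work(np.sin(t), t[1] - t[0])
        assert w.positive == pytest.approx(2.0, abs=1e-4)
        assert w.negative == pytest.approx(0.0, abs=1e-8)
        assert w.net == pytest.approx(2.0, abs=1e-4)

    def test_zero_power(self):
        w = joint_work(np.zeros(100), 0.01)
        assert (w.positive, w.negative, w.net) == (0.0, 0.0, 0.0)

    def test_quadrature_convergence(self):
        t1 = np.linspace(0, 1, 2001)
        t2 = np.linspace(0, 1, 4001)
        p = lambda t: np.sin(2 * np.pi * t) + 0.3 * np.cos(4 * np.pi * t)  # noqa: E731
        w1 = joint_work(p(t1), t1[1] - t1[0])
        w2 = joint_work(p(t2), t2[1] - t2[0])
        assert abs(w1.net - w2.net) < 1e-6

    def test_bookkeeping_positive_plus_negative_is_net(self):
        rng = np.random.default_rng(43)
        p = rng.normal(0, 5, 500)
        w = joint_work(p, 0.01)
        assert w.positive + w.negative == pytest.approx(w.net, abs=1e-9)
        assert w.positive >= 0 >= w.negative

    def test_normalize_by_mass(self):
        w = joint_work(np.full(11, 7.0), 1.0, joint="ankle")
        wn = normalize_by_mass(w, 70.0)
        assert wn.net == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            normalize_by_mass(wn, 70.0)   # refuses to normalise twice
        with pytest.raises(ParameterError):
            normalize_by_mass(w, 0.0)


class TestTrialKinetics:
    def test_assignment_series_invariants(self, config):
        bundle, truth = fm.generate_running_trial(fm.SyntheticTrialSpec(seed=2),
                                                  config)
        kin = fm.compute_trial_kinematics(bundle, fm.make_model("MULTI", config),
                                          config)
        assignment = fm.assign_grf_series(kin, config)
        loaded = kin.forces.contact_mask
        lab = assignment.segments
        assert set(lab[loaded]) <= {"RF", "FF", "TOE"}
        assert (lab[~loaded] == "").all()
        # COP advances heel -> toe, so assignment moves distally overall
        order = {"RF": 0, "FF": 1, "TOE": 2}
        seq = [order[s] for s in lab[loaded]]
        assert seq[0] == 0 and seq[-1] == 2

    def test_assignment_matches_generator_truth(self, config):
        bundle, truth = fm.generate_running_trial(
            fm.SyntheticTrialSpec(seed=2, noise_sigma=0.0), config)
        kin = fm.compute_trial_kinematics(bundle, fm.make_model("MULTI", config),
                                          config)
        assignment = fm.assign_grf_series(kin, config)
        both = (assignment.segments != "") & (truth.assignment != "")
        agree = assignment.segments[both] == truth.assignment[both]
        assert agree.mean() > 0.9   # boundary samples may differ by one frame

    def test_power_consistency_invariant(self, config):
        bundle, _ = fm.generate_running_trial(fm.SyntheticTrialSpec(seed=1), config)
        model = fm.make_model("MULTI", config)
        kin = fm.compute_trial_kinematics(bundle, model, config)
        inertial = fm.foot_segment_inertia(bundle.subject, config.anthropometry)
        kinetics, works, _ = fm.compute_joint_kinetics(kin, inertial,
                                                       bundle.subject.mass, config)
        w = kin.stance
        prox_of = {j.name: j.proximal for j in model.joints}
        dist_of = {j.name: j.distal for j in model.joints}
        for jname, jk in kinetics.items():
            w_rel = (kin.segments[dist_of[jname]].omega[w.first:w.last + 1]
                     - kin.segments[prox_of[jname]].omega[w.first:w.last + 1])
            assert np.abs(jk.power - np.einsum("ti,ti->t", jk.moment, w_rel)).max() < 1e-9
            assert works[jname].positive + works[jname].negative == pytest.approx(
                works[jname].net, abs=1e-9)

    def test_work_partition_property(self, config):
        """On the shipped default trial, SINGLE ankle positive work is close
        to MULTI ankle + midfoot positive work."""
        bundle, _ = fm.generate_running_trial(fm.SyntheticTrialSpec(seed=0), config)
        r = fm.run_trial(bundle, config)
        wS = r.models["SINGLE"].works["ankle"].positive
        wM = r.models["MULTI"].works["ankle"].positive
        wmid = r.models["MULTI"].works["midtarsal"].positive
        assert abs(wS - (wM + wmid)) < 0.15 * wS
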