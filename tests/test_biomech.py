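"""Key-finger-exoskeleton dynamics: closed forms, oracles, integrator checks."""

import numpy as np
import pytest

from pianorehab import biomech as bm
from pianorehab.errors import SimulationDivergedError


@pytest.fixture
def chain():
    return bm.FingerChain.index_finger()


class TestKeyForce:
    def test_rest(self):
        assert bm.key_force(0.0, 0.0, bm.KeyModel()) == 0.0

    def test_hand_value(self):
        key = bm.KeyModel(ks=100.0, bs=1.0)
        assert bm.key_force(0.01, 0.05, key) == pytest.approx(1.05)

    def test_linearity(self):
        key = bm.KeyModel(ks=150.0, bs=2.0)
        assert bm.key_force(0.02, 0.1, key) == pytest.approx(
            2 * bm.key_force(0.01, 0.05, key))


class TestJacobian:
    def test_single_link_closed_form(self):
        chain = bm.FingerChain(lengths=[0.05, 0.03], masses=[0.01, 0.005])
        J = bm.fingertip_jacobian(chain, np.array([0.0, 0.0]))
        # at full extension both columns point straight up
        np.testing.assert_allclose(J[:, 1], [0.0, 0.03], atol=1e-12)
        np.testing.assert_allclose(J[:, 0], [0.0, 0.08], atol=1e-12)

    def test_matches_finite_difference_oracle(self, chain):
        rng = np.random.default_rng(0)
        h = 1e-7
        for _ in range(5):
            theta = rng.uniform(-0.8, 0.8, size=3)
            J = bm.fingertip_jacobian(chain, theta)
            J_fd = np.empty_like(J)
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                J_fd[:, j] = (bm.fingertip_position(chain, theta + e)
                              - bm.fingertip_position(chain, theta - e)) / (2 * h)
            np.testing.assert_allclose(J, J_fd, atol=1e-6)

    def test_zero_force_zero_torque(self, chain):
        J = bm.fingertip_jacobian(chain, np.array([0.1, 0.2, 0.3]))
        np.testing.assert_allclose(J.T @ np.zeros(2), 0.0)


class TestHill:
    def _muscle(self):
        return bm.MuscleModel(fmax=50.0, lmt=lambda th: 0.2 + 0.01 * th)

    def test_zero_activation(self):
        assert bm.hill_torque(self._muscle(), 1.0, 0.0, 0.0, 0.3) == 0.0

    def test_isometric_optimum(self):
        m = self._muscle()
        tau = bm.hill_torque(m, 1.0, 0.0, 1.0, 0.3)
        assert tau == pytest.approx(m.fmax * 0.01, rel=1e-6)

    def test_suboptimal_length_reduces_torque(self):
        m = self._muscle()
        opt = bm.hill_torque(m, 1.0, 0.0, 1.0, 0.3)
        assert bm.hill_torque(m, 1.4, 0.0, 1.0, 0.3) < opt
        assert bm.hill_torque(m, 0.6, 0.0, 1.0, 0.3) < opt

    def test_curve_normalization(self):
        assert bm.force_length(1.0) == pytest.approx(1.0)
        assert bm.force_velocity(0.0) == pytest.approx(1.0)
        assert bm.force_velocity(1.0) == 0.0

    def test_out_of_range_activation_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            tau = bm.hill_torque(self._muscle(), 1.0, 0.0, 1.5, 0.3)
        assert tau == pytest.approx(bm.hill_torque(self._muscle(), 1.0, 0.0,
                                                   1.0, 0.3))


class TestMomentArm:
    def test_linear_length_exact(self):
        assert bm.moment_arm(lambda th: 0.1 + 0.02 * th, 0.5) == \
            pytest.approx(0.02, abs=1e-9)

    def test_sinusoidal_length_analytic(self):
        assert bm.moment_arm(lambda th: 0.1 + 0.015 * np.sin(th), 0.0) == \
            pytest.approx(0.015, abs=1e-6)

    def test_step_halving_converged(self):
        lmt = lambda th: 0.1 + 0.01 * np.sin(th)  # noqa: E731
        a = bm.moment_arm(lmt, 0.3, h=1e-5)
        b = bm.moment_arm(lmt, 0.3, h=5e-6)
        assert abs(a - b) < 1e-8


class TestTorqueAssist:
    def test_hand_values(self):
        tau, fa = bm.joint_torque_and_assist(10.0, 0.02, 0.02)
        assert tau == pytest.approx(0.2)
        assert fa == pytest.approx(10.0)

    def test_zero_force(self):
        assert bm.joint_torque_and_assist(0.0, 0.02, 0.02) == (0.0, 0.0)

    def test_reciprocal_in_distance(self):
        _, fa1 = bm.joint_torque_and_assist(10.0, 0.02, 0.02)
        _, fa2 = bm.joint_torque_and_assist(10.0, 0.02, 0.01)
        assert fa2 == pytest.approx(2 * fa1)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            bm.joint_torque_and_assist(1.0, 0.02, 0.0)


class TestExoTorque:
    def test_zero_error_zero_torque(self):
        exo = bm.ExoModel.pd_default(2, theta_d=[0.3, 0.1])
        tau = bm.exo_torque(exo, np.array([0.3, 0.1]), np.zeros(2))
        np.testing.assert_allclose(tau, 0.0)

    def test_hand_value(self):
        exo = bm.ExoModel(me=[0.0], ce=[0.0], ks_struct=[0.0], theta_eq=[0.0],
                          kp=[2.0], kd=[0.5], theta_d=[0.1])
        tau = bm.exo_torque(exo, np.array([0.0]), np.array([-0.2]))
        assert tau[0] == pytest.approx(2.0 * 0.1 + 0.5 * 0.2)

    def test_restoring_direction(self):
        exo = bm.ExoModel.pd_default(1, theta_d=[0.0])
        assert bm.exo_torque(exo, np.array([0.2]), np.zeros(1))[0] < 0
        assert bm.exo_torque(exo, np.array([-0.2]), np.zeros(1))[0] > 0

    def test_dimension_mismatch_rejected(self):
        exo = bm.ExoModel.pd_default(2)
        with pytest.raises(ValueError):
            bm.exo_torque(exo, np.zeros(3), np.zeros(3))


class TestSimulate:
    def test_pd_steady_state_reaches_target(self, chain):
        thd = np.array([0.3, 0.2, 0.1])
        exo = bm.ExoModel.pd_default(3, theta_d=thd)
        trace = bm.simulate(chain, None, exo, duration=1.5, dt=1e-3)
        np.testing.assert_allclose(trace.theta[-1], thd, atol=1e-3)

    def test_equilibrium_without_torques(self, chain):
        exo = bm.ExoModel(me=[1e-3] * 3, ce=[0.0] * 3, ks_struct=[0.0] * 3,
                          theta_eq=[0.0] * 3, kp=[0.0] * 3, kd=[0.0] * 3)
        theta0 = np.array([0.2, 0.1, 0.05])
        trace = bm.simulate(chain, None, exo, duration=0.2, dt=1e-3,
                            theta0=theta0)
        np.testing.assert_allclose(trace.theta[-1], theta0, atol=1e-12)

    def test_passive_energy_nonincreasing(self, chain):
        exo = bm.ExoModel.passive_only(3)
        trace = bm.simulate(chain, None, exo, duration=1.0, dt=1e-3,
                            theta0=np.array([0.4, 0.3, 0.2]))

        def energy(s):
            th, thd = trace.theta[s], trace.theta_dot[s]
            M = bm.mass_matrix(chain, th) + exo.me
            el = 0.5 * (th - exo.theta_eq) @ exo.ks_struct @ (th - exo.theta_eq)
            return 0.5 * thd @ M @ thd + el

        E = np.array([energy(s) for s in range(0, trace.t.size, 20)])
        assert np.all(np.diff(E) <= 1e-12)

    def test_static_key_force_balance(self, chain):
        """Held 5 mm compression at ks=150 gives a 0.75 N contact force."""
        key = bm.KeyModel(ks=150.0, bs=0.0)
        th0 = np.array([0.35, 0.25, 0.15])
        tip = bm.fingertip_position(chain, th0)
        contact = bm.default_contact(key, key_height=tip[1] + 0.005)
        exo = bm.ExoModel.pd_default(3, theta_d=th0, kp=200.0, kd=2.0)
        trace = bm.simulate(chain, key, exo, duration=0.4, dt=2.5e-4,
                            theta0=th0, contact=contact)
        assert trace.f_key[-1] == pytest.approx(0.75, rel=0.01)
        # reaction torque balances the PD + structural torque at equilibrium
        th_end = trace.theta[-1]
        J = bm.fingertip_jacobian(chain, th_end)
        tau_key = J.T @ np.array([0.0, trace.f_key[-1]])
        tau_hold = (bm.exo_torque(exo, th_end, trace.theta_dot[-1])
                    - exo.ks_struct @ (th_end - exo.theta_eq))
        np.testing.assert_allclose(tau_key, -tau_hold, atol=2e-4)

    def test_rk4_order(self, chain):
        exo = bm.ExoModel.pd_default(3, theta_d=[0.3, 0.2, 0.1])

        def end_state(dt):
            tr = bm.simulate(chain, None, exo, duration=0.25, dt=dt,
                             theta0=np.array([0.1, 0.0, 0.0]))
            return np.concatenate([tr.theta[-1], tr.theta_dot[-1]])

        ref = end_state(1.25e-4)
        e_coarse = np.linalg.norm(end_state(1e-3) - ref)
        e_fine = np.linalg.norm(end_state(5e-4) - ref)
        assert e_coarse / e_fine >= 12.0

    def test_assistive_force_identity(self, chain):
        """Fa from the trace equals tau_m / d_joint for an active muscle."""
        muscle = bm.MuscleModel(fmax=20.0, lmt=lambda th: 0.2 + 0.01 * th,
                                l_opt=0.2, activation=0.5)
        exo = bm.ExoModel.pd_default(3, theta_d=[0.0, 0.0, 0.0])
        trace = bm.simulate(chain, None, exo, muscles=[muscle, None, None],
                            duration=0.05, dt=1e-3)
        np.testing.assert_allclose(trace.f_assist[:, 0],
                                   trace.tau_m[:, 0] / chain.d_joint[0])
        assert np.all(trace.f_assist[:, 1:] == 0.0)

    def test_oversized_dt_rejected(self, chain):
        exo = bm.ExoModel.pd_default(3)
        with pytest.raises(ValueError):
            bm.simulate(chain, None, exo, duration=0.1, dt=5e-3)

    def test_divergence_reported_with_last_valid_time(self, chain):
        # negative-definite "damping" pumps energy until the state blows up
        exo = bm.ExoModel(me=[1e-6] * 3, ce=[0.0] * 3, ks_struct=[0.0] * 3,
                          theta_eq=[0.0] * 3, kp=[0.0] * 3, kd=[0.0] * 3)
        exo.ce = -5.0 * np.eye(3)  # bypass PSD validation deliberately
        with pytest.raises(SimulationDivergedError) as err:
            bm.simulate(chain, None, exo, duration=2.0, dt=1e-3,
                        theta_dot0=np.array([1.0, 0.0, 0.0]))
        assert err.value.last_valid_time >= 0.0


class TestChainValidation:
    def test_thumb_has_two_links(self):
        thumb = bm.FingerChain(lengths=[0.05, 0.03], masses=[0.01, 0.008])
        assert thumb.joint_names == ["MC", "IP"]

    def test_wrong_link_count_rejected(self):
        with pytest.raises(ValueError):
            bm.FingerChain(lengths=[0.05], masses=[0.01])

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            bm.FingerChain(lengths=[0.05, -0.03], masses=[0.01, 0.008])
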