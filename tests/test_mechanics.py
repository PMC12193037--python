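"""Multibody mechanics: geometry, kinematic recursion, Jourdain assembly."""

import numpy as np
import pytest

from wormloop.errors import DegenerateGeometryError
from wormloop.geometry import BodyGeometry, BodyState, EnvironmentParams
from wormloop.mechanics import (
    assemble_generalized_dynamics,
    drag_force,
    muscle_geometry,
    passive_muscle_force,
    recursive_kinematics,
    segment_forces,
    segment_kinematics,
    solve_accelerations,
)
from lagrangian_oracle import chain_accelerations

from wormloop.circuit import MuscleSpec, REST_LENGTH_UM


def random_state(geom, rng, angle_scale=0.4, rate_scale=2.0):
    y = np.zeros(geom.dof)
    y[0:2] = 50.0 * rng.standard_normal(2)
    y[2:] = angle_scale * rng.standard_normal(geom.n_segments)
    ydot = rate_scale * rng.standard_normal(geom.dof)
    return BodyState(y, ydot)


class TestMuscleGeometry:
    def test_straight_rest_pose_has_zero_deformation(self):
        geom = BodyGeometry.default()
        out = muscle_geometry(BodyState.straight(geom), geom)
        np.testing.assert_allclose(out.length, geom.rest_length, rtol=1e-12)
        np.testing.assert_allclose(out.deformation, 0.0, atol=1e-9)

    def test_rigid_translation_keeps_lengths_constant(self, rng):
        geom = BodyGeometry.default(n_segments=5)
        state = random_state(geom, rng, rate_scale=0.0)
        state.ydot[0:2] = [33.0, -12.0]  # pure translation
        out = muscle_geometry(state, geom)
        np.testing.assert_allclose(out.length_rate, 0.0, atol=1e-9)

    def test_length_rate_matches_finite_difference(self, rng):
        geom = BodyGeometry.default(n_segments=4)
        state = random_state(geom, rng)
        dt = 1e-6
        out = muscle_geometry(state, geom)
        plus = BodyState(state.y + dt * state.ydot, state.ydot)
        minus = BodyState(state.y - dt * state.ydot, state.ydot)
        fd = (muscle_geometry(plus, geom).length
              - muscle_geometry(minus, geom).length) / (2 * dt)
        np.testing.assert_allclose(out.length_rate, fd, rtol=1e-6, atol=1e-6)

    def test_degenerate_geometry_detected(self):
        # pathological geometry whose anchors coincide in the straight pose
        n = 2
        geom = BodyGeometry(
            masses=np.ones(n), inertias=np.ones(n),
            rho_p=np.zeros((n, 2)), rho_q=np.zeros((n, 2)),
            b_d=np.zeros((n, 2)), b_v=np.zeros((n, 2)),
        )
        with pytest.raises(DegenerateGeometryError):
            muscle_geometry(BodyState.straight(geom), geom)


class TestForces:
    def test_passive_force_at_rest_is_zero(self):
        m = MuscleSpec("m", "dorsal", 1, rest_length=REST_LENGTH_UM)
        el, dmp = passive_muscle_force(REST_LENGTH_UM, 0.0, np.array([1.0, 0]), m)
        assert el == 0.0 and dmp == 0.0

    def test_elastic_force_linear_in_extension(self):
        m = MuscleSpec("m", "dorsal", 1, spring_constant=2.0,
                       rest_length=REST_LENGTH_UM)
        el, _ = passive_muscle_force(REST_LENGTH_UM + 1.0, 0.0,
                                     np.array([1.0, 0]), m)
        assert el == pytest.approx(2.0)

    def test_drag_decomposition(self):
        env = EnvironmentParams(drag_normal=1.0, drag_tangent=3.0)
        f_perp, f_par = drag_force(np.array([1.0, 0.0]), np.array([1.0, 0.0]), env)
        np.testing.assert_allclose(f_par, [3.0, 0.0])
        np.testing.assert_allclose(f_perp, [0.0, 0.0])

    def test_drag_dissipates_power(self, rng):
        env = EnvironmentParams(1.3, 0.4)
        for _ in range(50):
            v = rng.standard_normal(2) * 10
            angle = rng.uniform(0, 2 * np.pi)
            tangent = np.array([np.cos(angle), np.sin(angle)])
            f_perp, f_par = drag_force(v, tangent, env)
            assert (-f_perp - f_par) @ v <= 1e-12


class TestRecursiveKinematics:
    def test_rigid_translation_velocities(self):
        geom = BodyGeometry.default(n_segments=6)
        state = BodyState.straight(geom)
        state.ydot[0:2] = [7.0, -3.0]
        v, G, ghat = recursive_kinematics(state, geom)
        v = v.reshape(-1, 3)
        np.testing.assert_allclose(v[:, 0], 7.0)
        np.testing.assert_allclose(v[:, 1], -3.0)
        np.testing.assert_allclose(v[:, 2], 0.0)

    def test_velocity_map_identity(self, rng):
        geom = BodyGeometry.default(n_segments=5)
        for _ in range(10):
            state = random_state(geom, rng)
            v, G, _ = recursive_kinematics(state, geom)
            _, omega, _, rdot = segment_kinematics(state, geom)
            direct = np.column_stack([rdot, omega]).ravel()
            np.testing.assert_allclose(v, direct, rtol=1e-12, atol=1e-9)
            np.testing.assert_allclose(G @ state.ydot, direct, rtol=1e-12,
                                       atol=1e-9)

    def test_lower_block_triangular(self, rng):
        geom = BodyGeometry.default(n_segments=5)
        _, G, _ = recursive_kinematics(random_state(geom, rng), geom)
        for i in range(geom.n_segments):
            # block row i depends only on r1, theta_1..theta_i
            assert np.allclose(G[3 * i: 3 * i + 3, i + 3:], 0.0)

    def test_acceleration_bias_matches_finite_difference(self, rng):
        geom = BodyGeometry.default(n_segments=4)
        state = random_state(geom, rng)
        _, G, ghat = recursive_kinematics(state, geom)
        dt = 1e-6
        # vdot with yddot = 0 equals ghat
        plus = BodyState(state.y + dt * state.ydot, state.ydot)
        minus = BodyState(state.y - dt * state.ydot, state.ydot)
        vp, _, _ = recursive_kinematics(plus, geom)
        vm, _, _ = recursive_kinematics(minus, geom)
        np.testing.assert_allclose((vp - vm) / (2 * dt), ghat, rtol=1e-5,
                                   atol=1e-4)


class TestGeneralizedDynamics:
    def test_equilibrium_at_rest(self):
        geom = BodyGeometry.default()
        state = BodyState.straight(geom)
        forces = np.zeros((geom.n_segments, 3))
        Z, z = assemble_generalized_dynamics(state, geom, forces)
        np.testing.assert_allclose(z, 0.0, atol=1e-9)
        np.testing.assert_allclose(solve_accelerations(Z, z), 0.0, atol=1e-9)

    def test_mass_matrix_symmetric_positive_definite(self, rng):
        geom = BodyGeometry.default(n_segments=7)
        for _ in range(10):
            state = random_state(geom, rng)
            Z, _ = assemble_generalized_dynamics(
                state, geom, np.zeros((7, 3)))
            np.testing.assert_allclose(Z, Z.T, atol=1e-8 * np.abs(Z).max())
            assert np.all(np.linalg.eigvalsh(Z) > 0)

    def test_solver_contract(self, rng):
        for _ in range(20):
            A = rng.standard_normal((6, 6))
            Z = A @ A.T + 6 * np.eye(6)
            z = rng.standard_normal(6)
            ydd = solve_accelerations(Z, z)
            assert np.linalg.norm(Z @ ydd - z) / np.linalg.norm(z) < 1e-10

    def test_identity_system(self):
        ydd = solve_accelerations(np.eye(3), np.array([1.0, 0, 0]))
        np.testing.assert_allclose(ydd, [1.0, 0, 0])

    def test_three_by_three_against_explicit_inverse(self, rng):
        A = rng.standard_normal((3, 3))
        Z = A @ A.T + 3 * np.eye(3)
        z = rng.standard_normal(3)
        np.testing.assert_allclose(solve_accelerations(Z, z),
                                   np.linalg.inv(Z) @ z, rtol=1e-10)


class TestLagrangianOracle:
    """1-3 segment chains against the independent symbolic derivation."""

    @pytest.mark.parametrize("n_seg", [1, 2, 3])
    def test_forced_chain_matches_oracle(self, n_seg, rng):
        geom = BodyGeometry.default(n_segments=n_seg)
        for _ in range(25):
            state = random_state(geom, rng)
            forces = rng.standard_normal((n_seg, 3)) * np.array([5.0, 5.0, 100.0])
            Z, z = assemble_generalized_dynamics(state, geom, forces)
            got = solve_accelerations(Z, z)
            want = chain_accelerations(
                state.y, state.ydot, geom.masses, geom.inertias,
                geom.rest_length, forces=forces,
            )
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-8)

    def test_sprung_chain_matches_oracle(self, rng):
        # two segments joined by the dorsoventral elastic spring pair
        geom = BodyGeometry.default(n_segments=2)
        k, L0 = 4.0, geom.rest_length
        half_width = float(geom.b_d[0, 1])
        for _ in range(25):
            state = random_state(geom, rng)
            sg = muscle_geometry(state, geom)
            tensions = k * (sg.length - L0)
            env = EnvironmentParams(0.0, 0.0)
            forces = segment_forces(state, geom, env, tensions, sg)
            Z, z = assemble_generalized_dynamics(state, geom, forces)
            got = solve_accelerations(Z, z)
            want = chain_accelerations(
                state.y, state.ydot, geom.masses, geom.inertias,
                geom.rest_length, spring=(half_width, k, L0),
            )
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-8)
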