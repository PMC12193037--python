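"""Multibody dynamics of the segmented body (reference implementation).

The chain's generalised coordinates are y = [r1, theta_1, ..., theta_n]
(centroid of segment 1 plus one absolute + n-1 relative joint angles).
Segment velocities are related to coordinate rates by a recursion over
adjacent segments, v = G ydot and vdot = G yddot + ghat, and the equations
of motion follow from Jourdain's variational principle by projecting the
Newton-Euler equations of every rod through G:

    Z yddot = z,   Z = sum_i Gi^T Mi Gi,   z = sum_i Gi^T (fi - Mi ghat_i)

External forces are the muscle spring tensions (active + elastic + damping),
applied with opposite signs at the two anchor points of each spring, and
linear resistive drag at the centroids.  This module favours clarity; the
performance path in :mod:`wormloop.kernel` is cross-checked against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .circuit import MuscleSpec
from .errors import DegenerateGeometryError
from .geometry import I_TILDE, BodyGeometry, BodyState, EnvironmentParams
from .neural import sigmoid_activation

log = logging.getLogger(__name__)


def _rotations(phi: np.ndarray) -> np.ndarray:
    """Stack of 2x2 world-from-body rotation matrices."""
    c, s = np.cos(phi), np.sin(phi)
    return np.stack([np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2)


def segment_kinematics(state: BodyState, geom: BodyGeometry):
    """Absolute angles, angular velocities, centroid positions and velocities.

    Returns ``(phi, omega, r, rdot)`` with shapes (n,), (n,), (n,2), (n,2).
    """
    n = geom.n_segments
    phi = np.cumsum(state.y[2:])
    omega = np.cumsum(state.ydot[2:])
    rot = _rotations(phi)
    rho_p_w = np.einsum("nij,nj->ni", rot, geom.rho_p)
    rho_q_w = np.einsum("nij,nj->ni", rot, geom.rho_q)

    r = np.empty((n, 2))
    rdot = np.empty((n, 2))
    r[0] = state.y[0:2]
    rdot[0] = state.ydot[0:2]
    for i in range(1, n):
        r[i] = r[i - 1] + rho_q_w[i - 1] - rho_p_w[i]
        rdot[i] = (rdot[i - 1]
                   + omega[i - 1] * (I_TILDE @ rho_q_w[i - 1])
                   - omega[i] * (I_TILDE @ rho_p_w[i]))
    return phi, omega, r, rdot


@dataclass
class MuscleGeometryOut:
    """Spring vectors for every (unit, side) muscle slot, head to tail.

    ``index[k]`` is ``(unit_index, side)``; deformation is relative to the
    geometry's common rest length (positive = contracted).
    """

    index: list[tuple[int, str]]
    s: np.ndarray  # (n_springs, 2)
    length: np.ndarray  # (n_springs,)
    deformation: np.ndarray  # (n_springs,)
    length_rate: np.ndarray  # (n_springs,)
    direction: np.ndarray  # (n_springs, 2)

    def slot(self, unit_index: int, side: str) -> int:
        return self.index.index((unit_index, side))


def muscle_geometry(state: BodyState, geom: BodyGeometry) -> MuscleGeometryOut:
    """Spring vector, length, deformation and lengthening rate per muscle slot."""
    n = geom.n_segments
    phi, omega, r, rdot = segment_kinematics(state, geom)
    rot = _rotations(phi)

    index = geom.spring_table()
    n_sp = len(index)
    s = np.empty((n_sp, 2))
    sdot = np.empty((n_sp, 2))
    for k, (u, side) in enumerate(index):
        a, b = u - 1, u  # 0-based segments the spring joins
        b_off = geom.b_d if side == "dorsal" else geom.b_v
        off_a = rot[a] @ (geom.rho_p[a] + b_off[a])
        off_b = rot[b] @ (geom.rho_p[b] + b_off[b])
        s[k] = (r[b] + off_b) - (r[a] + off_a)
        va = rdot[a] + omega[a] * (I_TILDE @ off_a)
        vb = rdot[b] + omega[b] * (I_TILDE @ off_b)
        sdot[k] = vb - va

    length = np.linalg.norm(s, axis=1)
    if np.any(length <= 0):
        k = int(np.argmin(length))
        raise DegenerateGeometryError(
            f"muscle slot {index[k]} has coincident attachment points"
        )
    direction = s / length[:, None]
    length_rate = np.einsum("ki,ki->k", sdot, s) / length
    deformation = geom.rest_length - length
    return MuscleGeometryOut(index, s, length, deformation, length_rate, direction)


def active_muscle_force(v_m: float, l: float, muscle: MuscleSpec) -> float:
    """Printed contractile scalar w_m * S(v_m) * (L_min - l).

    Negative whenever ``l > L_min``; the force assembly applies it so the
    anchors are pulled together (tension ``-active``).
    """
    if l <= 0:
        raise DegenerateGeometryError("muscle length must be > 0")
    gate = float(sigmoid_activation(v_m, muscle.activation_threshold,
                                    muscle.activation_slope))
    return muscle.contraction_gain * gate * (muscle.min_length - l)


def passive_muscle_force(
    l: float, length_rate: float, s: np.ndarray, muscle: MuscleSpec
) -> tuple[float, float]:
    """Elastic and damping scalars: k(|s| - L) and c (sdot.s)/|s|."""
    elastic = muscle.spring_constant * (l - muscle.rest_length)
    damping = muscle.damping_constant * length_rate
    return elastic, damping


def drag_force(
    velocity: np.ndarray, tangent: np.ndarray, env: EnvironmentParams
) -> tuple[np.ndarray, np.ndarray]:
    """Normal and tangential resistive components (C_N v_perp, C_T v_par).

    Both enter the force assembly with a minus sign, so drag opposes motion.
    """
    tangent = np.asarray(tangent, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    v_par = (velocity @ tangent) * tangent
    v_perp = velocity - v_par
    return env.drag_normal * v_perp, env.drag_tangent * v_par


def recursive_kinematics(state: BodyState, geom: BodyGeometry):
    """Segment generalised velocities and the velocity map ``v = G ydot``.

    Returns ``(v, G, ghat)`` where v stacks [rdot_i, omega_i] per segment
    (3 rows each), G is the (3n x dof) lower block-triangular Jacobian and
    ghat the acceleration bias, so vdot = G yddot + ghat.
    """
    n, dof = geom.n_segments, geom.dof
    phi = np.cumsum(state.y[2:])
    omega = np.cumsum(state.ydot[2:])
    rot = _rotations(phi)
    rho_p_w = np.einsum("nij,nj->ni", rot, geom.rho_p)
    rho_q_w = np.einsum("nij,nj->ni", rot, geom.rho_q)

    G = np.zeros((3 * n, dof))
    ghat = np.zeros(3 * n)
    G[0:3, 0:3] = np.eye(3)
    for i in range(1, n):
        T = np.eye(3)
        T[0:2, 2] = I_TILDE @ (rho_q_w[i - 1] - rho_p_w[i])
        rows, prev = slice(3 * i, 3 * i + 3), slice(3 * (i - 1), 3 * i)
        G[rows] = T @ G[prev]
        G[3 * i: 3 * i + 2, i + 2] += -(I_TILDE @ rho_p_w[i])
        G[3 * i + 2, i + 2] += 1.0
        beta = np.zeros(3)
        beta[0:2] = -rho_q_w[i - 1] * omega[i - 1] ** 2 + rho_p_w[i] * omega[i] ** 2
        ghat[rows] = T @ ghat[prev] + beta
    v = G @ state.ydot
    return v, G, ghat


def segment_forces(
    state: BodyState,
    geom: BodyGeometry,
    env: EnvironmentParams,
    tensions: np.ndarray,
    spring_geom: MuscleGeometryOut | None = None,
) -> np.ndarray:
    """Per-segment generalised forces [Fx, Fy, torque] (shape (n, 3)).

    ``tensions[k]`` is the scalar tension of spring slot k (positive pulls
    the two anchors together); drag acts at the centroids with no torque.
    """
    n = geom.n_segments
    phi, omega, r, rdot = segment_kinematics(state, geom)
    rot = _rotations(phi)
    if spring_geom is None:
        spring_geom = muscle_geometry(state, geom)

    f = np.zeros((n, 3))
    for k, (u, side) in enumerate(spring_geom.index):
        a, b = u - 1, u
        b_off = geom.b_d if side == "dorsal" else geom.b_v
        arm_a = rot[a] @ (geom.rho_p[a] + b_off[a])
        arm_b = rot[b] @ (geom.rho_p[b] + b_off[b])
        force_on_a = tensions[k] * spring_geom.direction[k]
        f[a, 0:2] += force_on_a
        f[a, 2] += arm_a[0] * force_on_a[1] - arm_a[1] * force_on_a[0]
        f[b, 0:2] -= force_on_a
        f[b, 2] -= arm_b[0] * force_on_a[1] - arm_b[1] * force_on_a[0]
    for i in range(n):
        tangent = rot[i] @ np.array([1.0, 0.0])
        f_perp, f_par = drag_force(rdot[i], tangent, env)
        f[i, 0:2] += -f_perp - f_par
    return f


def spring_tensions(
    spring_geom: MuscleGeometryOut,
    muscle_map: dict[tuple[int, str], MuscleSpec],
    muscle_potentials: dict[str, float],
    passive_k: float,
    passive_c: float,
    passive_rest: float,
) -> np.ndarray:
    """Scalar tension per spring slot (positive pulls anchors together).

    Slots with an innervated muscle use that muscle's constants and gain an
    active contractile term; bare slots are passive body elasticity.
    """
    tensions = np.empty(len(spring_geom.index))
    for k, (u, side) in enumerate(spring_geom.index):
        l = spring_geom.length[k]
        ldot = spring_geom.length_rate[k]
        spec = muscle_map.get((u, side))
        if spec is None:
            tensions[k] = passive_k * (l - passive_rest) + passive_c * ldot
        else:
            elastic = spec.spring_constant * (l - spec.rest_length)
            damping = spec.damping_constant * ldot
            active = active_muscle_force(muscle_potentials[spec.id], l, spec)
            tensions[k] = elastic + damping - active
    return tensions


def assemble_generalized_dynamics(
    state: BodyState, geom: BodyGeometry, forces: np.ndarray
):
    """Project the Newton-Euler equations onto the generalised coordinates.

    Returns ``(Z, z)`` with Z symmetric positive definite for positive
    masses and inertias.
    """
    n, dof = geom.n_segments, geom.dof
    forces = np.asarray(forces, dtype=float)
    if forces.shape != (n, 3):
        raise ValueError(f"forces must have shape {(n, 3)}")
    _, G, ghat = recursive_kinematics(state, geom)
    Z = np.zeros((dof, dof))
    z = np.zeros(dof)
    for i in range(n):
        rows = slice(3 * i, 3 * i + 3)
        Gi = G[rows]
        Mi = np.diag([geom.masses[i], geom.masses[i], geom.inertias[i]])
        Z += Gi.T @ Mi @ Gi
        z += Gi.T @ (forces[i] - Mi @ ghat[rows])
    return Z, z


def solve_accelerations(Z: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Solve Z yddot = z (Z SPD); regularise and warn if ill-conditioned."""
    try:
        yddot = scipy.linalg.solve(Z, z, assume_a="pos")
    except np.linalg.LinAlgError:
        yddot = None
    if yddot is None or not np.all(np.isfinite(yddot)):
        jitter = 1e-12 * np.trace(Z) / len(z)
        log.warning("generalised mass matrix ill-conditioned; "
                    "regularising with jitter %.3e", jitter)
        yddot = scipy.linalg.solve(Z + jitter * np.eye(len(z)), z, assume_a="pos")
    residual = np.linalg.norm(Z @ yddot - z)
    scale = np.linalg.norm(z)
    if scale > 0 and residual / scale > 1e-10:
        log.warning("acceleration solve residual %.3e above tolerance", residual / scale)
    return yddot


def body_accelerations(
    state: BodyState,
    geom: BodyGeometry,
    env: EnvironmentParams,
    muscle_specs: Sequence[MuscleSpec] = (),
    muscle_potentials: dict[str, float] | None = None,
    passive_k: float | None = None,
    passive_c: float | None = None,
) -> np.ndarray:
    """Full mechanical right-hand side: yddot for the current state.

    Convenience composition of the steps above; the coupled simulator uses
    the fused kernel instead.  Bare spring slots default to the mean muscle
    spring/damping constants (uniform passive body elasticity).
    """
    spring_geom = muscle_geometry(state, geom)
    muscle_map = {(m.unit_index, m.side): m for m in muscle_specs}
    if passive_k is None:
        passive_k = float(np.mean([m.spring_constant for m in muscle_specs])) \
            if muscle_specs else 1.0
    if passive_c is None:
        passive_c = float(np.mean([m.damping_constant for m in muscle_specs])) \
            if muscle_specs else 0.01
    tensions = spring_tensions(
        spring_geom, muscle_map, muscle_potentials or {},
        passive_k, passive_c, geom.rest_length,
    )
    forces = segment_forces(state, geom, env, tensions, spring_geom)
    Z, z = assemble_generalized_dynamics(state, geom, forces)
    return solve_accelerations(Z, z)
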