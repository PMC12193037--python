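"""Independent symbolic oracle for the articulated-chain dynamics.

Derives the equations of motion of an n-segment planar chain from the
Lagrangian (kinetic energy in generalised coordinates, forces through
virtual work, optional elastic springs through a potential), entirely with
sympy differentiation -- no velocity recursion, no Jacobian assembly -- so
it shares nothing with the implementation under test beyond the geometry
definition.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp


def _rot(a):
    return sp.Matrix([[sp.cos(a), -sp.sin(a)], [sp.sin(a), sp.cos(a)]])


@lru_cache(maxsize=8)
def _chain_functions(n: int, with_springs: bool):
    """Build lambdified (M, C, Qgrad) for an n-segment chain.

    Geometry enters as symbols so one derivation serves any parameter set:
    masses m_i, inertias J_i, joint offsets (scalars: rods along local x with
    rho_p = (-h/2, 0), rho_q = (h/2, 0)) and, with springs, lateral arms w_i
    and spring constants/rest length.
    """
    dof = n + 2
    y = sp.Matrix(sp.symbols(f"y0:{dof}", real=True))
    yd = sp.Matrix(sp.symbols(f"yd0:{dof}", real=True))
    m = sp.symbols(f"m0:{n}", positive=True)
    J = sp.symbols(f"J0:{n}", positive=True)
    h = sp.Symbol("h", positive=True)

    rho_p = sp.Matrix([-h / 2, 0])
    rho_q = sp.Matrix([h / 2, 0])

    phi = [sum(y[2: 2 + i + 1]) for i in range(n)]
    r = [sp.Matrix([y[0], y[1]])]
    for i in range(1, n):
        r.append(r[i - 1] + _rot(phi[i - 1]) * rho_q - _rot(phi[i]) * rho_p)

    def d_dt(expr):
        return sum(sp.diff(expr, y[k]) * yd[k] for k in range(dof))

    rdot = [sp.Matrix([d_dt(ri[0]), d_dt(ri[1])]) for ri in r]
    om = [sum(yd[2: 2 + i + 1]) for i in range(n)]

    T = sum(m[i] / 2 * (rdot[i].T * rdot[i])[0, 0] + J[i] / 2 * om[i] ** 2
            for i in range(n))

    M = sp.Matrix(dof, dof, lambda a, b: sp.diff(T, yd[a], yd[b]))
    # Coriolis/centrifugal bias: d/dt(dT/dyd) - dT/dy with yddot excluded
    C = sp.Matrix([
        sum(sp.diff(sp.diff(T, yd[k]), y[l]) * yd[l] for l in range(dof))
        - sp.diff(T, y[k])
        for k in range(dof)
    ])

    # generalised force of unit external force/torque on each segment:
    # columns are dQ/d(Fx_i), dQ/d(Fy_i), dQ/d(tau_i)
    B = sp.zeros(dof, 3 * n)
    for i in range(n):
        for k in range(dof):
            B[k, 3 * i] = sp.diff(r[i][0], y[k])
            B[k, 3 * i + 1] = sp.diff(r[i][1], y[k])
            B[k, 3 * i + 2] = sp.diff(phi[i], y[k])

    syms = [*y, *yd, *m, *J, h]
    if not with_springs:
        funcs = (sp.lambdify(syms, M, "numpy"),
                 sp.lambdify(syms, C, "numpy"),
                 sp.lambdify(syms, B, "numpy"))
        return funcs

    # elastic dorsoventral springs via a potential: spring (u, side) joins
    # the lateral points P_u + w*e_y and P_{u+1} + w*e_y (body frames)
    w = sp.Symbol("w", positive=True)
    kk = sp.Symbol("k", positive=True)
    L0 = sp.Symbol("L0", positive=True)
    V = 0
    for u in range(n - 1):
        for sign in (+1, -1):
            b = sp.Matrix([0, sign * w])
            pa = r[u] + _rot(phi[u]) * (rho_p + b)
            pb = r[u + 1] + _rot(phi[u + 1]) * (rho_p + b)
            length = sp.sqrt(((pb - pa).T * (pb - pa))[0, 0])
            V += kk / 2 * (length - L0) ** 2
    Qspring = sp.Matrix([-sp.diff(V, y[k]) for k in range(dof)])
    syms2 = syms + [w, kk, L0]
    funcs = (sp.lambdify(syms, M, "numpy"),
             sp.lambdify(syms, C, "numpy"),
             sp.lambdify(syms, B, "numpy"),
             sp.lambdify(syms2, Qspring, "numpy"))
    return funcs


def chain_accelerations(
    y: np.ndarray,
    yd: np.ndarray,
    masses: np.ndarray,
    inertias: np.ndarray,
    seg_length: float,
    forces: np.ndarray | None = None,
    spring: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Oracle yddot for an equal-rod chain.

    ``forces`` is (n, 3) of external [Fx, Fy, tau] per segment (world frame,
    about the centroid); ``spring=(half_width, k, rest_length)`` adds the
    dorsoventral elastic spring pairs.
    """
    n = len(masses)
    with_springs = spring is not None
    funcs = _chain_functions(n, with_springs)
    args = [*y, *yd, *masses, *inertias, seg_length]
    M = np.asarray(funcs[0](*args), dtype=float)
    C = np.asarray(funcs[1](*args), dtype=float).ravel()
    Q = -C
    if forces is not None:
        B = np.asarray(funcs[2](*args), dtype=float)
        Q = Q + B @ np.asarray(forces, dtype=float).ravel()
    if with_springs:
        Qs = np.asarray(funcs[3](*args, *spring), dtype=float).ravel()
        Q = Q + Qs
    return np.linalg.solve(M, Q)
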