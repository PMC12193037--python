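"""Fused numerical kernel for the coupled neuromechanical system.

The circuit, body geometry and environment are lowered to flat arrays once,
then a numba-compiled right-hand side evaluates membrane currents, muscle
geometry, spring tensions, drag and the Jourdain-projected multibody
equations in a single pass, and a compiled fixed-step RK4 loop integrates
whole trajectories without returning to Python.  The readable numpy modules
(:mod:`wormloop.neural`, :mod:`wormloop.mechanics`) define the semantics;
tests assert that this kernel reproduces them to machine precision.

State layout: ``[x (N membrane potentials), y (dof), ydot (dof)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .circuit import CircuitConfig
from .geometry import BodyGeometry, EnvironmentParams


@dataclass
class CompiledModel:
    """Flat-array form of (circuit, geometry, environment) for the kernel."""

    config: CircuitConfig
    geom: BodyGeometry
    env: EnvironmentParams

    n_neurons: int = 0
    n_muscles: int = 0
    n_seg: int = 0
    # membrane node arrays
    cap: np.ndarray = field(default=None)
    leak_g: np.ndarray = field(default=None)
    e_leak: np.ndarray = field(default=None)
    i_ext: np.ndarray = field(default=None)
    # chemical synapses
    ce_pre: np.ndarray = field(default=None)
    ce_post: np.ndarray = field(default=None)
    ce_w: np.ndarray = field(default=None)
    ce_erev: np.ndarray = field(default=None)
    ce_vx: np.ndarray = field(default=None)
    ce_th: np.ndarray = field(default=None)
    # gap junctions
    gj_a: np.ndarray = field(default=None)
    gj_b: np.ndarray = field(default=None)
    gj_w: np.ndarray = field(default=None)
    # feedback connections
    fb_slot: np.ndarray = field(default=None)
    fb_rest: np.ndarray = field(default=None)
    fb_tgt: np.ndarray = field(default=None)
    fb_pos: np.ndarray = field(default=None)
    fb_w: np.ndarray = field(default=None)
    fb_vx: np.ndarray = field(default=None)
    fb_th: np.ndarray = field(default=None)
    e_ca: float = 0.0
    e_k: float = 0.0
    # springs (one per (unit, side) slot; both sides always present)
    sp_seg_a: np.ndarray = field(default=None)
    sp_seg_b: np.ndarray = field(default=None)
    sp_off_a: np.ndarray = field(default=None)  # body-frame anchor offsets
    sp_off_b: np.ndarray = field(default=None)
    sp_k: np.ndarray = field(default=None)
    sp_c: np.ndarray = field(default=None)
    sp_rest: np.ndarray = field(default=None)
    sp_node: np.ndarray = field(default=None)  # innervating muscle node or -1
    sp_wm: np.ndarray = field(default=None)
    sp_lmin: np.ndarray = field(default=None)
    sp_avx: np.ndarray = field(default=None)
    sp_ath: np.ndarray = field(default=None)
    #: spring slot of each circuit muscle (for recording deformations)
    muscle_slot: np.ndarray = field(default=None)
    muscle_rest: np.ndarray = field(default=None)
    # geometry
    mass: np.ndarray = field(default=None)
    inertia: np.ndarray = field(default=None)
    rho_p: np.ndarray = field(default=None)
    rho_q: np.ndarray = field(default=None)
    drag_n: float = 0.0
    drag_t: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.n_neurons + self.n_muscles

    @property
    def dof(self) -> int:
        return self.n_seg + 2

    @property
    def state_dim(self) -> int:
        return self.n_nodes + 2 * self.dof

    @property
    def n_springs(self) -> int:
        return len(self.sp_k)

    def kernel_args(self) -> tuple:
        return (
            self.n_neurons, self.cap, self.leak_g, self.e_leak, self.i_ext,
            self.ce_pre, self.ce_post, self.ce_w, self.ce_erev, self.ce_vx,
            self.ce_th,
            self.gj_a, self.gj_b, self.gj_w,
            self.fb_slot, self.fb_rest, self.fb_tgt, self.fb_pos, self.fb_w,
            self.fb_vx, self.fb_th, self.e_ca, self.e_k,
            self.sp_seg_a, self.sp_seg_b, self.sp_off_a, self.sp_off_b,
            self.sp_k, self.sp_c, self.sp_rest, self.sp_node, self.sp_wm,
            self.sp_lmin, self.sp_avx, self.sp_ath,
            self.mass, self.inertia, self.rho_p, self.rho_q,
            self.drag_n, self.drag_t,
        )


def lower(
    config: CircuitConfig,
    geom: BodyGeometry | None = None,
    env: EnvironmentParams | None = None,
) -> CompiledModel:
    """Lower a validated circuit onto a body into kernel arrays.

    Circuit unit indices are mapped onto the geometry's spring slots so the
    lowest unit of the circuit takes the first slot.  Spring slots with no
    innervating muscle become passive body elasticity, with spring/damping
    constants set to the mean of the circuit's muscles.
    """
    config.validate()
    units = sorted({m.unit_index for m in config.muscles})
    if geom is None:
        n_seg = units[-1] - units[0] + 2
        geom = BodyGeometry.default(n_segments=n_seg)
    if env is None:
        env = EnvironmentParams()
    unit_offset = units[0] - 1  # circuit unit u -> geometry unit u - offset

    m = CompiledModel(config=config, geom=geom, env=env)
    p, q = len(config.neurons), len(config.muscles)
    m.n_neurons, m.n_muscles, m.n_seg = p, q, geom.n_segments

    nodes = [*config.neurons, *config.muscles]
    m.cap = np.array([n.capacitance for n in nodes])
    m.leak_g = np.array([n.leak_conductance for n in nodes])
    m.e_leak = np.array([n.e_leak for n in nodes])
    m.i_ext = np.array([n.i_external for n in config.neurons] + [0.0] * q)

    index = {nid: i for i, nid in enumerate(config.node_ids)}
    syn = config.chemical_synapses
    m.ce_pre = np.array([index[s.pre] for s in syn], dtype=np.int64)
    m.ce_post = np.array([index[s.post] for s in syn], dtype=np.int64)
    m.ce_w = np.array([s.weight for s in syn])
    m.ce_erev = np.array(
        [config.e_ca if s.reversal == "E_Ca" else config.e_k for s in syn]
    )
    m.ce_vx = np.array([s.threshold for s in syn])
    m.ce_th = np.array([s.slope for s in syn])

    m.gj_a = np.array([index[g.a] for g in config.gap_junctions], dtype=np.int64)
    m.gj_b = np.array([index[g.b] for g in config.gap_junctions], dtype=np.int64)
    m.gj_w = np.array([g.weight for g in config.gap_junctions])

    spring_index = {
        (u + unit_offset, side): slot
        for slot, (u, side) in enumerate(geom.spring_table())
    }
    for mus in config.muscles:
        if (mus.unit_index, mus.side) not in spring_index:
            raise ValueError(
                f"muscle {mus.id} (unit {mus.unit_index}) does not fit geometry "
                f"with {geom.n_units} units"
            )
    muscle_by_id = {mus.id: mus for mus in config.muscles}

    fbs = config.feedbacks
    m.fb_slot = np.array(
        [spring_index[(muscle_by_id[f.source_muscle].unit_index,
                       muscle_by_id[f.source_muscle].side)] for f in fbs],
        dtype=np.int64,
    )
    m.fb_rest = np.array([muscle_by_id[f.source_muscle].rest_length for f in fbs])
    m.fb_tgt = np.array([index[f.target_neuron] for f in fbs], dtype=np.int64)
    m.fb_pos = np.array([1 if f.polarity == "positive" else 0 for f in fbs],
                        dtype=np.int64)
    m.fb_w = np.array([f.weight for f in fbs])
    m.fb_vx = np.array([f.threshold for f in fbs])
    m.fb_th = np.array([f.slope for f in fbs])
    m.e_ca, m.e_k = config.e_ca, config.e_k

    n_sp = 2 * geom.n_units
    m.sp_seg_a = np.empty(n_sp, dtype=np.int64)
    m.sp_seg_b = np.empty(n_sp, dtype=np.int64)
    m.sp_off_a = np.empty((n_sp, 2))
    m.sp_off_b = np.empty((n_sp, 2))
    mean_k = float(np.mean([mu.spring_constant for mu in config.muscles]))
    mean_c = float(np.mean([mu.damping_constant for mu in config.muscles]))
    m.sp_k = np.full(n_sp, mean_k)
    m.sp_c = np.full(n_sp, mean_c)
    m.sp_rest = np.full(n_sp, geom.rest_length)
    m.sp_node = np.full(n_sp, -1, dtype=np.int64)
    m.sp_wm = np.zeros(n_sp)
    m.sp_lmin = np.full(n_sp, 0.5 * geom.rest_length)
    m.sp_avx = np.zeros(n_sp)
    m.sp_ath = np.ones(n_sp)
    for slot, (u, side) in enumerate(geom.spring_table()):
        a = u - 1
        b_off = geom.b_d if side == "dorsal" else geom.b_v
        m.sp_seg_a[slot], m.sp_seg_b[slot] = a, a + 1
        m.sp_off_a[slot] = geom.rho_p[a] + b_off[a]
        m.sp_off_b[slot] = geom.rho_p[a + 1] + b_off[a + 1]
    for mus in config.muscles:
        slot = spring_index[(mus.unit_index, mus.side)]
        m.sp_k[slot] = mus.spring_constant
        m.sp_c[slot] = mus.damping_constant
        m.sp_rest[slot] = mus.rest_length
        m.sp_node[slot] = index[mus.id]
        m.sp_wm[slot] = mus.contraction_gain
        m.sp_lmin[slot] = mus.min_length
        m.sp_avx[slot] = mus.activation_threshold
        m.sp_ath[slot] = mus.activation_slope

    m.muscle_slot = np.array(
        [spring_index[(mus.unit_index, mus.side)] for mus in config.muscles],
        dtype=np.int64,
    )
    m.muscle_rest = np.array([mus.rest_length for mus in config.muscles])

    m.mass = geom.masses.copy()
    m.inertia = geom.inertias.copy()
    m.rho_p = geom.rho_p.copy()
    m.rho_q = geom.rho_q.copy()
    m.drag_n = env.drag_normal
    m.drag_t = env.drag_tangent

    return m


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs(
    state, out,
    p, cap, leak_g, e_leak, i_ext,
    ce_pre, ce_post, ce_w, ce_erev, ce_vx, ce_th,
    gj_a, gj_b, gj_w,
    fb_slot, fb_rest, fb_tgt, fb_pos, fb_w, fb_vx, fb_th, e_ca, e_k,
    sp_seg_a, sp_seg_b, sp_off_a, sp_off_b,
    sp_k, sp_c, sp_rest, sp_node, sp_wm, sp_lmin, sp_avx, sp_ath,
    mass, inertia, rho_p, rho_q, drag_n, drag_t,
):
    n = mass.shape[0]
    dof = n + 2
    n_nodes = cap.shape[0]
    n_sp = sp_k.shape[0]
    x = state[:n_nodes]
    y = state[n_nodes:n_nodes + dof]
    yd = state[n_nodes + dof:]

    # --- segment kinematics -------------------------------------------
    phi = np.empty(n)
    om = np.empty(n)
    acc = 0.0
    accw = 0.0
    for i in range(n):
        acc += y[2 + i]
        accw += yd[2 + i]
        phi[i] = acc
        om[i] = accw
    cph = np.cos(phi)
    sph = np.sin(phi)
    rho_pw = np.empty((n, 2))
    rho_qw = np.empty((n, 2))
    for i in range(n):
        rho_pw[i, 0] = cph[i] * rho_p[i, 0] - sph[i] * rho_p[i, 1]
        rho_pw[i, 1] = sph[i] * rho_p[i, 0] + cph[i] * rho_p[i, 1]
        rho_qw[i, 0] = cph[i] * rho_q[i, 0] - sph[i] * rho_q[i, 1]
        rho_qw[i, 1] = sph[i] * rho_q[i, 0] + cph[i] * rho_q[i, 1]
    r = np.empty((n, 2))
    rd = np.empty((n, 2))
    r[0, 0], r[0, 1] = y[0], y[1]
    rd[0, 0], rd[0, 1] = yd[0], yd[1]
    for i in range(1, n):
        r[i, 0] = r[i - 1, 0] + rho_qw[i - 1, 0] - rho_pw[i, 0]
        r[i, 1] = r[i - 1, 1] + rho_qw[i - 1, 1] - rho_pw[i, 1]
        rd[i, 0] = rd[i - 1, 0] - om[i - 1] * rho_qw[i - 1, 1] + om[i] * rho_pw[i, 1]
        rd[i, 1] = rd[i - 1, 1] + om[i - 1] * rho_qw[i - 1, 0] - om[i] * rho_pw[i, 0]

    # --- spring geometry ----------------------------------------------
    lengths = np.empty(n_sp)
    ldots = np.empty(n_sp)
    sdir = np.empty((n_sp, 2))
    off_a = np.empty((n_sp, 2))
    off_b = np.empty((n_sp, 2))
    for kk in range(n_sp):
        a = sp_seg_a[kk]
        b = sp_seg_b[kk]
        oax = cph[a] * sp_off_a[kk, 0] - sph[a] * sp_off_a[kk, 1]
        oay = sph[a] * sp_off_a[kk, 0] + cph[a] * sp_off_a[kk, 1]
        obx = cph[b] * sp_off_b[kk, 0] - sph[b] * sp_off_b[kk, 1]
        oby = sph[b] * sp_off_b[kk, 0] + cph[b] * sp_off_b[kk, 1]
        off_a[kk, 0], off_a[kk, 1] = oax, oay
        off_b[kk, 0], off_b[kk, 1] = obx, oby
        sx = r[b, 0] + obx - r[a, 0] - oax
        sy = r[b, 1] + oby - r[a, 1] - oay
        l = np.sqrt(sx * sx + sy * sy)
        vax = rd[a, 0] - om[a] * oay
        vay = rd[a, 1] + om[a] * oax
        vbx = rd[b, 0] - om[b] * oby
        vby = rd[b, 1] + om[b] * obx
        lengths[kk] = l
        ldots[kk] = ((vbx - vax) * sx + (vby - vay) * sy) / l
        sdir[kk, 0] = sx / l
        sdir[kk, 1] = sy / l

    # --- membrane currents --------------------------------------------
    cur = np.zeros(n_nodes)
    for e in range(ce_pre.shape[0]):
        s = 1.0 / (1.0 + np.exp(-(x[ce_pre[e]] - ce_vx[e]) / ce_th[e]))
        cur[ce_post[e]] += ce_w[e] * s * (ce_erev[e] - x[ce_post[e]])
    for e in range(gj_a.shape[0]):
        d = gj_w[e] * (x[gj_b[e]] - x[gj_a[e]])
        cur[gj_a[e]] += d
        cur[gj_b[e]] -= d
    for e in range(fb_slot.shape[0]):
        delta = fb_rest[e] - lengths[fb_slot[e]]
        s = 1.0 / (1.0 + np.exp(-(delta - fb_vx[e]) / fb_th[e]))
        t = fb_tgt[e]
        if fb_pos[e] == 1:
            if delta >= 0.0:
                cur[t] += fb_w[e] * s * (e_ca - x[t])
            else:
                cur[t] += fb_w[e] * (1.0 - s) * (e_k - x[t])
        else:
            if delta >= 0.0:
                cur[t] += fb_w[e] * s * (e_k - x[t])
            else:
                cur[t] += fb_w[e] * (1.0 - s) * (e_ca - x[t])
    for i in range(n_nodes):
        out[i] = (i_ext[i] + cur[i] + leak_g[i] * (e_leak[i] - x[i])) / cap[i]

    # --- forces --------------------------------------------------------
    f = np.zeros((n, 3))
    for kk in range(n_sp):
        tension = sp_k[kk] * (lengths[kk] - sp_rest[kk]) + sp_c[kk] * ldots[kk]
        node = sp_node[kk]
        if node >= 0:
            gate = 1.0 / (1.0 + np.exp(-(x[node] - sp_avx[kk]) / sp_ath[kk]))
            tension += sp_wm[kk] * gate * (lengths[kk] - sp_lmin[kk])
        a = sp_seg_a[kk]
        b = sp_seg_b[kk]
        fx = tension * sdir[kk, 0]
        fy = tension * sdir[kk, 1]
        f[a, 0] += fx
        f[a, 1] += fy
        f[a, 2] += off_a[kk, 0] * fy - off_a[kk, 1] * fx
        f[b, 0] -= fx
        f[b, 1] -= fy
        f[b, 2] += -(off_b[kk, 0] * fy - off_b[kk, 1] * fx)
    for i in range(n):
        tx, ty = cph[i], sph[i]
        vpar = rd[i, 0] * tx + rd[i, 1] * ty
        vparx, vpary = vpar * tx, vpar * ty
        vperx, vpery = rd[i, 0] - vparx, rd[i, 1] - vpary
        f[i, 0] -= drag_n * vperx + drag_t * vparx
        f[i, 1] -= drag_n * vpery + drag_t * vpary

    # --- Jourdain projection: Z yddot = z ------------------------------
    G = np.zeros((3 * n, dof))
    ghat = np.zeros(3 * n)
    G[0, 0] = 1.0
    G[1, 1] = 1.0
    G[2, 2] = 1.0
    for i in range(1, n):
        txv = -(rho_qw[i - 1, 1] - rho_pw[i, 1])
        tyv = rho_qw[i - 1, 0] - rho_pw[i, 0]
        base = 3 * i
        prev = 3 * (i - 1)
        ncol = i + 3
        for cidx in range(ncol):
            G[base, cidx] = G[prev, cidx] + txv * G[prev + 2, cidx]
            G[base + 1, cidx] = G[prev + 1, cidx] + tyv * G[prev + 2, cidx]
            G[base + 2, cidx] = G[prev + 2, cidx]
        G[base, i + 2] += rho_pw[i, 1]
        G[base + 1, i + 2] += -rho_pw[i, 0]
        G[base + 2, i + 2] += 1.0
        bx = -rho_qw[i - 1, 0] * om[i - 1] ** 2 + rho_pw[i, 0] * om[i] ** 2
        by = -rho_qw[i - 1, 1] * om[i - 1] ** 2 + rho_pw[i, 1] * om[i] ** 2
        ghat[base] = ghat[prev] + txv * ghat[prev + 2] + bx
        ghat[base + 1] = ghat[prev + 1] + tyv * ghat[prev + 2] + by
        ghat[base + 2] = ghat[prev + 2]

    Z = np.zeros((dof, dof))
    zv = np.zeros(dof)
    for i in range(n):
        base = 3 * i
        mi = mass[i]
        Ji = inertia[i]
        ncol = min(i + 3, dof)
        fx = f[i, 0] - mi * ghat[base]
        fy = f[i, 1] - mi * ghat[base + 1]
        tq = f[i, 2] - Ji * ghat[base + 2]
        for a_ in range(ncol):
            ga0 = G[base, a_]
            ga1 = G[base + 1, a_]
            ga2 = G[base + 2, a_]
            zv[a_] += ga0 * fx + ga1 * fy + ga2 * tq
            for b_ in range(a_, ncol):
                Z[a_, b_] += mi * (ga0 * G[base, b_] + ga1 * G[base + 1, b_]) \
                    + Ji * ga2 * G[base + 2, b_]
    for a_ in range(dof):
        for b_ in range(a_ + 1, dof):
            Z[b_, a_] = Z[a_, b_]

    yddot = np.linalg.solve(Z, zv)
    for i in range(dof):
        out[n_nodes + i] = yd[i]
        out[n_nodes + dof + i] = yddot[i]


@njit(cache=True)
def _rk4_run(
    state0, dt, n_steps, stride,
    p, cap, leak_g, e_leak, i_ext,
    ce_pre, ce_post, ce_w, ce_erev, ce_vx, ce_th,
    gj_a, gj_b, gj_w,
    fb_slot, fb_rest, fb_tgt, fb_pos, fb_w, fb_vx, fb_th, e_ca, e_k,
    sp_seg_a, sp_seg_b, sp_off_a, sp_off_b,
    sp_k, sp_c, sp_rest, sp_node, sp_wm, sp_lmin, sp_avx, sp_ath,
    mass, inertia, rho_p, rho_q, drag_n, drag_t,
):
    dim = state0.shape[0]
    n_rec = n_steps // stride + 1
    rec = np.empty((n_rec, dim))
    times = np.empty(n_rec)
    state = state0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    rec[0] = state
    times[0] = 0.0
    idx = 1
    ok = True
    bad_step = -1
    args = (
        p, cap, leak_g, e_leak, i_ext,
        ce_pre, ce_post, ce_w, ce_erev, ce_vx, ce_th,
        gj_a, gj_b, gj_w,
        fb_slot, fb_rest, fb_tgt, fb_pos, fb_w, fb_vx, fb_th, e_ca, e_k,
        sp_seg_a, sp_seg_b, sp_off_a, sp_off_b,
        sp_k, sp_c, sp_rest, sp_node, sp_wm, sp_lmin, sp_avx, sp_ath,
        mass, inertia, rho_p, rho_q, drag_n, drag_t,
    )
    for step in range(1, n_steps + 1):
        _rhs(state, k1, *args)
        for i in range(dim):
            tmp[i] = state[i] + 0.5 * dt * k1[i]
        _rhs(tmp, k2, *args)
        for i in range(dim):
            tmp[i] = state[i] + 0.5 * dt * k2[i]
        _rhs(tmp, k3, *args)
        for i in range(dim):
            tmp[i] = state[i] + dt * k3[i]
        _rhs(tmp, k4, *args)
        for i in range(dim):
            state[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if step % stride == 0:
            finite = True
            for i in range(dim):
                if not np.isfinite(state[i]):
                    finite = False
                    break
            if not finite:
                ok = False
                bad_step = step
                rec[idx] = state
                times[idx] = step * dt
                idx += 1
                break
            rec[idx] = state
            times[idx] = step * dt
            idx += 1
    return times[:idx], rec[:idx], ok, bad_step


@njit(cache=True)
def _measure_springs(states, n_nodes, sp_seg_a, sp_seg_b, sp_off_a, sp_off_b,
                     mass, rho_p, rho_q):
    """Spring lengths, centroid and head position for recorded snapshots."""
    n_rec = states.shape[0]
    n = mass.shape[0]
    n_sp = sp_seg_a.shape[0]
    lengths = np.empty((n_rec, n_sp))
    centroid = np.empty((n_rec, 2))
    head = np.empty((n_rec, 2))
    total_mass = mass.sum()
    for t in range(n_rec):
        y = states[t, n_nodes:n_nodes + n + 2]
        phi = np.empty(n)
        acc = 0.0
        for i in range(n):
            acc += y[2 + i]
            phi[i] = acc
        cph = np.cos(phi)
        sph = np.sin(phi)
        r = np.empty((n, 2))
        r[0, 0], r[0, 1] = y[0], y[1]
        for i in range(1, n):
            qx = cph[i - 1] * rho_q[i - 1, 0] - sph[i - 1] * rho_q[i - 1, 1]
            qy = sph[i - 1] * rho_q[i - 1, 0] + cph[i - 1] * rho_q[i - 1, 1]
            px = cph[i] * rho_p[i, 0] - sph[i] * rho_p[i, 1]
            py = sph[i] * rho_p[i, 0] + cph[i] * rho_p[i, 1]
            r[i, 0] = r[i - 1, 0] + qx - px
            r[i, 1] = r[i - 1, 1] + qy - py
        cx = 0.0
        cy = 0.0
        for i in range(n):
            cx += mass[i] * r[i, 0]
            cy += mass[i] * r[i, 1]
        centroid[t, 0] = cx / total_mass
        centroid[t, 1] = cy / total_mass
        head[t, 0] = r[0, 0]
        head[t, 1] = r[0, 1]
        for kk in range(n_sp):
            a = sp_seg_a[kk]
            b = sp_seg_b[kk]
            oax = cph[a] * sp_off_a[kk, 0] - sph[a] * sp_off_a[kk, 1]
            oay = sph[a] * sp_off_a[kk, 0] + cph[a] * sp_off_a[kk, 1]
            obx = cph[b] * sp_off_b[kk, 0] - sph[b] * sp_off_b[kk, 1]
            oby = sph[b] * sp_off_b[kk, 0] + cph[b] * sp_off_b[kk, 1]
            sx = r[b, 0] + obx - r[a, 0] - oax
            sy = r[b, 1] + oby - r[a, 1] - oay
            lengths[t, kk] = np.sqrt(sx * sx + sy * sy)
    return lengths, centroid, head


def rhs(model: CompiledModel, state: np.ndarray) -> np.ndarray:
    """Single right-hand-side evaluation (compiled); mostly for tests."""
    out = np.empty_like(state)
    _rhs(np.asarray(state, dtype=float), out, *model.kernel_args())
    return out


def integrate(model: CompiledModel, state0: np.ndarray, dt: float,
              n_steps: int, stride: int = 10):
    """RK4-integrate ``n_steps`` steps, recording every ``stride`` steps.

    Returns ``(times, states, ok, bad_step)``; ``ok=False`` flags a
    non-finite state detected at recording resolution.
    """
    return _rk4_run(np.asarray(state0, dtype=float), float(dt), int(n_steps),
                    int(stride), *model.kernel_args())


def measure(model: CompiledModel, states: np.ndarray):
    """Per-snapshot spring lengths, mass centroid and head position."""
    return _measure_springs(
        np.asarray(states, dtype=float), model.n_nodes,
        model.sp_seg_a, model.sp_seg_b, model.sp_off_a, model.sp_off_b,
        model.mass, model.rho_p, model.rho_q,
    )
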