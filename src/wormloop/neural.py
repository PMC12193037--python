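"""Membrane-potential dynamics of the neuron/muscle network.

Every node is a graded-potential (non-spiking) leaky membrane obeying
Kirchhoff's current law:

    neuron i:  C_n dv/dt = I_external + I_synapse + I_feedback + g_n (E_leak - v)
    muscle j:  C_m dv/dt = I_synapse + g_m (E_leak - v)

Chemical synapses inject ``w * S(v_pre) * (E_rev - v_post)`` where ``S`` is a
sigmoid of the presynaptic potential and ``E_rev`` is the calcium
(excitatory) or potassium (inhibitory) reversal potential; gap junctions
inject ``w * (v_other - v_self)``.  Muscle deformation closes the loop
through feedback currents gated by a sigmoid on the deformation scale:
for a contracted muscle (delta > 0) negative feedback opens the potassium
channel (hyperpolarising) while positive feedback opens the calcium channel.
Muscles receive no external or feedback currents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import ChemicalSynapse, CircuitConfig, FeedbackConnection


@dataclass
class IonParams:
    """Calcium / potassium reversal potentials (mV)."""

    e_ca: float
    e_k: float

    def __post_init__(self) -> None:
        if not self.e_ca > self.e_k:
            raise ValueError(f"requires E_Ca > E_K, got {self.e_ca} <= {self.e_k}")

    @classmethod
    def from_config(cls, config: CircuitConfig) -> "IonParams":
        return cls(config.e_ca, config.e_k)


@dataclass
class NeuralState:
    """Membrane potentials ordered [neurons..., muscles...] (mV)."""

    x: np.ndarray

    @classmethod
    def resting(cls, config: CircuitConfig) -> "NeuralState":
        x = np.array(
            [n.e_leak for n in config.neurons] + [m.e_leak for m in config.muscles]
        )
        return cls(x)


def sigmoid_activation(x: float, v_x: float, theta_x: float):
    """Sigmoid gate 1 / (1 + exp(-(x - V_x) / theta_x)); strictly increasing."""
    if theta_x <= 0:
        raise ValueError(f"slope theta_x must be > 0, got {theta_x}")
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - v_x) / theta_x))


def gap_junction_current(v_self: float, v_other: float, w_gap: float) -> float:
    """Electrical coupling current into the ``self`` node."""
    return w_gap * (v_other - v_self)


def chemical_synapse_current(
    v_pre: float, v_post: float, synapse: ChemicalSynapse, ions: IonParams
) -> float:
    e_rev = ions.e_ca if synapse.reversal == "E_Ca" else ions.e_k
    s = sigmoid_activation(v_pre, synapse.threshold, synapse.slope)
    return synapse.weight * s * (e_rev - v_post)


def feedback_current(
    delta: float, v_target: float, fb: FeedbackConnection, ions: IonParams
) -> float:
    """Deformation-gated feedback current into the target neuron.

    The piecewise channel assignment (the delta = 0 boundary takes the
    contracted branch):

    ==========  ==========  =======================================
    polarity    delta >= 0  delta < 0
    ==========  ==========  =======================================
    positive    Ca channel, S(delta)      K channel, 1 - S(delta)
    negative    K channel,  S(delta)      Ca channel, 1 - S(delta)
    ==========  ==========  =======================================
    """
    s = float(sigmoid_activation(delta, fb.threshold, fb.slope))
    if fb.polarity == "positive":
        if delta >= 0:
            return fb.weight * s * (ions.e_ca - v_target)
        return fb.weight * (1.0 - s) * (ions.e_k - v_target)
    if delta >= 0:
        return fb.weight * s * (ions.e_k - v_target)
    return fb.weight * (1.0 - s) * (ions.e_ca - v_target)


def membrane_derivatives(
    state: NeuralState,
    deformations: np.ndarray,
    config: CircuitConfig,
    ions: IonParams | None = None,
) -> np.ndarray:
    """Right-hand side of the membrane equations for all nodes (mV/s).

    ``deformations`` holds delta (um) per muscle, ordered as
    ``config.muscles``.
    """
    if ions is None:
        ions = IonParams.from_config(config)
    x = np.asarray(state.x, dtype=float)
    p, q = len(config.neurons), len(config.muscles)
    if x.shape != (p + q,):
        raise ValueError(f"state has shape {x.shape}, circuit has {p + q} nodes")
    deformations = np.asarray(deformations, dtype=float)
    if deformations.shape != (q,):
        raise ValueError(
            f"deformations has shape {deformations.shape}, circuit has {q} muscles"
        )

    index = {nid: i for i, nid in enumerate(config.node_ids)}
    muscle_pos = {m.id: j for j, m in enumerate(config.muscles)}
    currents = np.zeros(p + q)

    for syn in config.chemical_synapses:
        i, j = index[syn.pre], index[syn.post]
        currents[j] += chemical_synapse_current(x[i], x[j], syn, ions)
    for gj in config.gap_junctions:
        i, j = index[gj.a], index[gj.b]
        currents[i] += gap_junction_current(x[i], x[j], gj.weight)
        currents[j] += gap_junction_current(x[j], x[i], gj.weight)
    for fb in config.feedbacks:
        j = index[fb.target_neuron]
        delta = deformations[muscle_pos[fb.source_muscle]]
        currents[j] += feedback_current(delta, x[j], fb, ions)

    dxdt = np.empty(p + q)
    for i, n in enumerate(config.neurons):
        total = n.i_external + currents[i] + n.leak_conductance * (n.e_leak - x[i])
        dxdt[i] = total / n.capacitance
    for j, m in enumerate(config.muscles):
        i = p + j
        total = currents[i] + m.leak_conductance * (m.e_leak - x[i])
        dxdt[i] = total / m.capacitance
    return dxdt
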