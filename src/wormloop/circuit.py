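"""Motor-circuit construction for the C. elegans forward-locomotion model.

The body wall of the worm is divided into 12 dorsoventral muscle units
(one dorsal and one ventral muscle each) spanning 13 rigid body segments;
unit ``i`` anchors on segments ``i`` and ``i+1``.  Neurons are graded-potential
nodes (premotor interneurons, excitatory/inhibitory/sensory motoneurons)
wired to muscles by chemical synapses, to each other by chemical synapses and
gap junctions, and fed back from muscles through deformation-gated feedback
connections (negative: the muscle a motoneuron innervates; positive:
anterior same-side muscles, the model's proprioceptive pathway).

Builders cover every circuit scale used in the study: the two-node
motoneuron-muscle loop, the four-neuron dorsoventral functional unit, two
gap-junction-coupled units (head-body or body-body), and the simplified
whole-worm connectome (42 neurons, 24 muscles).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError

NEURON_CLASSES = (
    "premotor",
    "excitatory_motoneuron",
    "inhibitory_motoneuron",
    "sensory_motoneuron",
)
SIDES = ("dorsal", "ventral", "none")

#: Default ionic / membrane constants (mV).  These are configuration inputs
#: with documented defaults, not asserted biological constants.
DEFAULT_E_LEAK = -60.0
DEFAULT_E_CA = 60.0
DEFAULT_E_K = -90.0

#: Whole worm length is normalised to 1000 um and split over 13 rods, so a
#: muscle's rest length is 1000/13 um.
WORM_LENGTH_UM = 1000.0
N_SEGMENTS = 13
N_UNITS = 12
REST_LENGTH_UM = WORM_LENGTH_UM / N_SEGMENTS


@dataclass
class NeuronSpec:
    """A graded-potential neuron node.

    ``capacitance`` and ``leak_conductance`` are dimensionless multiples of
    the reference membrane capacity and conductance; potentials are mV and
    time is seconds, so the membrane time constant is ``C/g`` seconds.
    """

    id: str
    neuron_class: str
    side: str = "none"
    unit_index: int | None = None
    capacitance: float = 0.05
    leak_conductance: float = 1.0
    e_leak: float = DEFAULT_E_LEAK
    i_external: float = 0.0

    def validate(self) -> None:
        if self.neuron_class not in NEURON_CLASSES:
            raise ConfigurationError(
                f"neuron {self.id}: unknown class {self.neuron_class!r}"
            )
        if self.side not in SIDES:
            raise ConfigurationError(f"neuron {self.id}: unknown side {self.side!r}")
        if not self.capacitance > 0:
            raise ConfigurationError(f"neuron {self.id}: capacitance must be > 0")
        if self.leak_conductance < 0:
            raise ConfigurationError(f"neuron {self.id}: leak_conductance must be >= 0")
        if self.unit_index is not None and not 1 <= self.unit_index <= N_UNITS:
            raise ConfigurationError(
                f"neuron {self.id}: unit_index {self.unit_index} outside [1, {N_UNITS}]"
            )


@dataclass
class MuscleSpec:
    """A body-wall muscle: a membrane node plus an actuated damped spring.

    The spring spans segments ``unit_index`` and ``unit_index + 1``.
    ``activation_threshold``/``activation_slope`` gate the contractile force
    as a sigmoid of the muscle membrane potential (thresholds differ from the
    synaptic ones and are fitted by the optimizer).
    """

    id: str
    side: str
    unit_index: int
    capacitance: float = 0.2
    leak_conductance: float = 1.0
    e_leak: float = DEFAULT_E_LEAK
    rest_length: float = REST_LENGTH_UM
    min_length: float = 0.65 * REST_LENGTH_UM
    contraction_gain: float = 10.0
    spring_constant: float = 5.0
    damping_constant: float = 0.05
    activation_threshold: float = -30.0
    activation_slope: float = 5.0

    def validate(self) -> None:
        if self.side not in ("dorsal", "ventral"):
            raise ConfigurationError(f"muscle {self.id}: side must be dorsal/ventral")
        if not 1 <= self.unit_index <= N_UNITS:
            raise ConfigurationError(
                f"muscle {self.id}: unit_index {self.unit_index} outside [1, {N_UNITS}]"
            )
        if not 0 < self.min_length < self.rest_length:
            raise ConfigurationError(
                f"muscle {self.id}: need 0 < min_length < rest_length"
            )
        if not self.capacitance > 0:
            raise ConfigurationError(f"muscle {self.id}: capacitance must be > 0")
        if self.spring_constant < 0 or self.damping_constant < 0:
            raise ConfigurationError(f"muscle {self.id}: k and c must be >= 0")
        if self.activation_slope <= 0:
            raise ConfigurationError(f"muscle {self.id}: activation_slope must be > 0")


@dataclass
class ChemicalSynapse:
    """Directed graded synapse; current = w * S(v_pre) * (E_rev - v_post)."""

    kind = "chemical"

    pre: str
    post: str
    weight: float
    reversal: str = "E_Ca"  # excitatory; "E_K" is inhibitory
    threshold: float = -30.0  # V_x, mV
    slope: float = 5.0  # theta_x, mV

    def validate(self) -> None:
        if self.weight < 0:
            raise ConfigurationError(f"synapse {self.pre}->{self.post}: weight < 0")
        if self.reversal not in ("E_Ca", "E_K"):
            raise ConfigurationError(
                f"synapse {self.pre}->{self.post}: reversal must be E_Ca or E_K"
            )
        if self.slope <= 0:
            raise ConfigurationError(f"synapse {self.pre}->{self.post}: slope <= 0")


@dataclass
class GapJunction:
    """Symmetric electrical coupling, stored once per pair."""

    kind = "gap"

    a: str
    b: str
    weight: float

    def validate(self) -> None:
        if self.a == self.b:
            raise ConfigurationError(f"gap junction {self.a}--{self.b}: self-coupling")
        if self.weight < 0:
            raise ConfigurationError(f"gap junction {self.a}--{self.b}: weight < 0")


@dataclass
class FeedbackConnection:
    """Deformation-gated current from a muscle to a neuron.

    ``threshold``/``slope`` are on the deformation scale (um).  Negative
    feedback opens the potassium channel for a contracted muscle (delta > 0);
    positive feedback opens the calcium channel instead.
    """

    kind = "feedback"

    source_muscle: str
    target_neuron: str
    polarity: str  # "negative" | "positive"
    weight: float
    threshold: float = 2.0  # um
    slope: float = 1.0  # um

    def validate(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ConfigurationError(
                f"feedback {self.source_muscle}->{self.target_neuron}: "
                f"polarity must be negative/positive"
            )
        if self.weight < 0:
            raise ConfigurationError(
                f"feedback {self.source_muscle}->{self.target_neuron}: weight < 0"
            )
        if self.slope <= 0:
            raise ConfigurationError(
                f"feedback {self.source_muscle}->{self.target_neuron}: slope <= 0"
            )


@dataclass
class CircuitConfig:
    """The full wiring diagram of one model circuit."""

    name: str
    neurons: list[NeuronSpec] = field(default_factory=list)
    muscles: list[MuscleSpec] = field(default_factory=list)
    chemical_synapses: list[ChemicalSynapse] = field(default_factory=list)
    gap_junctions: list[GapJunction] = field(default_factory=list)
    feedbacks: list[FeedbackConnection] = field(default_factory=list)
    e_ca: float = DEFAULT_E_CA
    e_k: float = DEFAULT_E_K

    # -- bookkeeping -------------------------------------------------------
    @property
    def neuron_ids(self) -> list[str]:
        return [n.id for n in self.neurons]

    @property
    def muscle_ids(self) -> list[str]:
        return [m.id for m in self.muscles]

    @property
    def node_ids(self) -> list[str]:
        """Membrane nodes ordered [neurons..., muscles...] (state layout)."""
        return self.neuron_ids + self.muscle_ids

    @property
    def n_nodes(self) -> int:
        return len(self.neurons) + len(self.muscles)

    def neuron(self, nid: str) -> NeuronSpec:
        for n in self.neurons:
            if n.id == nid:
                return n
        raise LookupError(f"no neuron {nid!r} in circuit {self.name!r}")

    def muscle(self, mid: str) -> MuscleSpec:
        for m in self.muscles:
            if m.id == mid:
                return m
        raise LookupError(f"no muscle {mid!r} in circuit {self.name!r}")

    @property
    def unit_map(self) -> dict[int, tuple[str | None, str | None, tuple[int, int]]]:
        """unit index -> (dorsal muscle id, ventral muscle id, segment pair)."""
        out: dict[int, tuple[str | None, str | None, tuple[int, int]]] = {}
        units = sorted({m.unit_index for m in self.muscles})
        for u in units:
            dorsal = [m.id for m in self.muscles if m.unit_index == u and m.side == "dorsal"]
            ventral = [m.id for m in self.muscles if m.unit_index == u and m.side == "ventral"]
            out[u] = (dorsal[0] if dorsal else None,
                      ventral[0] if ventral else None,
                      (u, u + 1))
        return out

    def edges(self) -> list[ChemicalSynapse | GapJunction | FeedbackConnection]:
        return [*self.chemical_synapses, *self.gap_junctions, *self.feedbacks]

    # -- validation --------------------------------------------------------
    def validate(self) -> "CircuitConfig":
        ids = self.node_ids
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"circuit {self.name!r}: duplicate node ids")
        if not self.e_ca > self.e_k:
            raise ConfigurationError(f"circuit {self.name!r}: requires E_Ca > E_K")
        neuron_ids = set(self.neuron_ids)
        muscle_ids = set(self.muscle_ids)
        for n in self.neurons:
            n.validate()
        for m in self.muscles:
            m.validate()
        for u, (d, v, _) in self.unit_map.items():
            nd = sum(1 for m in self.muscles if m.unit_index == u and m.side == "dorsal")
            nv = sum(1 for m in self.muscles if m.unit_index == u and m.side == "ventral")
            if nd > 1 or nv > 1:
                raise ConfigurationError(
                    f"circuit {self.name!r}: unit {u} has more than one muscle per side"
                )
        for s in self.chemical_synapses:
            s.validate()
            if s.pre not in neuron_ids:
                raise ConfigurationError(
                    f"synapse {s.pre}->{s.post}: presynaptic node must be a neuron"
                )
            if s.post not in neuron_ids | muscle_ids:
                raise ConfigurationError(f"synapse {s.pre}->{s.post}: unknown post node")
        for g in self.gap_junctions:
            g.validate()
            for end in (g.a, g.b):
                if end not in neuron_ids | muscle_ids:
                    raise ConfigurationError(f"gap junction {g.a}--{g.b}: unknown node {end}")
        for f in self.feedbacks:
            f.validate()
            if f.source_muscle not in muscle_ids:
                raise ConfigurationError(
                    f"feedback {f.source_muscle}->{f.target_neuron}: source must be a muscle"
                )
            if f.target_neuron not in neuron_ids:
                raise ConfigurationError(
                    f"feedback {f.source_muscle}->{f.target_neuron}: target must be a neuron"
                )
        return self

    def copy(self) -> "CircuitConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

def _get(params: Mapping[str, float], key: str) -> float:
    try:
        return float(params[key])
    except KeyError:
        raise ConfigurationError(f"missing parameter {key!r}") from None


def _opt(params: Mapping[str, float], key: str, default: float) -> float:
    return float(params.get(key, default))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_two_node_loop(params: Mapping[str, float]) -> CircuitConfig:
    """One motoneuron driving one muscle, closed by negative feedback.

    The motoneuron (an SMD- or B-type cell) excites the muscle through a
    chemical synapse; muscle deformation feeds a hyperpolarising current back
    to the motoneuron.  A constant external current triggers activity.
    """
    n = NeuronSpec(
        id="MN",
        neuron_class="excitatory_motoneuron",
        side="dorsal",
        unit_index=1,
        capacitance=_get(params, "C_n"),
        leak_conductance=_get(params, "g_n"),
        e_leak=_opt(params, "E_leak", DEFAULT_E_LEAK),
        i_external=_get(params, "I_ext"),
    )
    m = MuscleSpec(
        id="MUS",
        side="dorsal",
        unit_index=1,
        capacitance=_get(params, "C_m"),
        leak_conductance=_get(params, "g_m"),
        e_leak=_opt(params, "E_leak", DEFAULT_E_LEAK),
        rest_length=_opt(params, "L", REST_LENGTH_UM),
        min_length=_opt(params, "L_min", 0.65 * REST_LENGTH_UM),
        contraction_gain=_get(params, "w_m"),
        spring_constant=_get(params, "k"),
        damping_constant=_get(params, "c"),
        activation_threshold=_get(params, "act_Vx"),
        activation_slope=_get(params, "act_theta"),
    )
    syn = ChemicalSynapse(
        pre="MN", post="MUS",
        weight=_get(params, "w_che"),
        reversal="E_Ca",
        threshold=_get(params, "syn_Vx"),
        slope=_get(params, "syn_theta"),
    )
    fb = FeedbackConnection(
        source_muscle="MUS", target_neuron="MN",
        polarity="negative",
        weight=_get(params, "w_f"),
        threshold=_get(params, "fb_Vx"),
        slope=_get(params, "fb_theta"),
    )
    cfg = CircuitConfig(
        name="two_node_loop",
        neurons=[n], muscles=[m],
        chemical_synapses=[syn], feedbacks=[fb],
        e_ca=_opt(params, "E_Ca", DEFAULT_E_CA),
        e_k=_opt(params, "E_K", DEFAULT_E_K),
    )
    return cfg.validate()


def _unit_names(style: str, unit_index: int) -> dict[str, str]:
    """Node names for one dorsoventral unit (body VB/DB/VD/DD or head SMD/RME)."""
    i = unit_index
    if style == "head":
        return {
            "ED": "SMDD", "EV": "SMDV", "ID": "RMED", "IV": "RMEV",
            "MD": f"DM{i}", "MV": f"VM{i}",
        }
    return {
        "ED": f"DB{i}", "EV": f"VB{i}", "ID": f"DD{i}", "IV": f"VD{i}",
        "MD": f"DM{i}", "MV": f"VM{i}",
    }


def build_functional_unit(
    params: Mapping[str, float],
    input_ratio: float = 1.0,
    unit_index: int = 1,
    style: str = "body",
) -> CircuitConfig:
    """The dorsoventral switching unit: two negative feedback loops that
    compete through inhibitory cross-coupling.

    Excitatory motoneurons (DB/VB-like, or SMDD/SMDV in the ``head`` style)
    contract their own-side muscle and excite the contralateral inhibitory
    motoneuron (DD/VD-like or RMED/RMEV), which relaxes the opposite muscle;
    the inhibitors also inhibit each other.  Premotor drive is a constant
    current ``u1`` to the ventral excitor and ``u2 = input_ratio * u1`` to the
    dorsal one; dorsoventral asymmetry of drive and of the
    motoneuron-to-muscle weights is what enables alternation.
    """
    if input_ratio <= 0:
        raise ValueError(f"input_ratio must be > 0, got {input_ratio}")
    nm = _unit_names(style, unit_index)
    u1 = _get(params, "u1")
    u2 = input_ratio * u1
    e_leak = _opt(params, "E_leak", DEFAULT_E_LEAK)
    C_n, g_n = _get(params, "C_n"), _get(params, "g_n")

    exc_class = "sensory_motoneuron" if style == "head" else "excitatory_motoneuron"
    neurons = [
        NeuronSpec(nm["ED"], exc_class, "dorsal", unit_index, C_n, g_n, e_leak, u2),
        NeuronSpec(nm["EV"], exc_class, "ventral", unit_index, C_n, g_n, e_leak, u1),
        NeuronSpec(nm["ID"], "inhibitory_motoneuron", "dorsal", unit_index,
                   C_n, g_n, e_leak, 0.0),
        NeuronSpec(nm["IV"], "inhibitory_motoneuron", "ventral", unit_index,
                   C_n, g_n, e_leak, 0.0),
    ]

    def muscle(mid: str, side: str) -> MuscleSpec:
        return MuscleSpec(
            id=mid, side=side, unit_index=unit_index,
            capacitance=_get(params, "C_m"),
            leak_conductance=_get(params, "g_m"),
            e_leak=e_leak,
            rest_length=_opt(params, "L", REST_LENGTH_UM),
            min_length=_opt(params, "L_min", 0.65 * REST_LENGTH_UM),
            contraction_gain=_get(params, "w_m"),
            spring_constant=_get(params, "k"),
            damping_constant=_get(params, "c"),
            activation_threshold=_get(params, "act_Vx"),
            activation_slope=_get(params, "act_theta"),
        )

    muscles = [muscle(nm["MD"], "dorsal"), muscle(nm["MV"], "ventral")]

    Vx, th = _get(params, "syn_Vx"), _get(params, "syn_theta")

    def syn(pre: str, post: str, w: float, reversal: str) -> ChemicalSynapse:
        return ChemicalSynapse(pre, post, w, reversal, Vx, th)

    synapses = [
        # excitatory motoneuron -> own-side muscle
        syn(nm["ED"], nm["MD"], _get(params, "w_eM_d"), "E_Ca"),
        syn(nm["EV"], nm["MV"], _get(params, "w_eM_v"), "E_Ca"),
        # excitatory -> contralateral inhibitory motoneuron
        syn(nm["ED"], nm["IV"], _get(params, "w_eI_d"), "E_Ca"),
        syn(nm["EV"], nm["ID"], _get(params, "w_eI_v"), "E_Ca"),
        # inhibitory motoneuron -> own-side muscle
        syn(nm["ID"], nm["MD"], _get(params, "w_iM_d"), "E_K"),
        syn(nm["IV"], nm["MV"], _get(params, "w_iM_v"), "E_K"),
        # reciprocal inhibition between inhibitory motoneurons
        syn(nm["ID"], nm["IV"], _get(params, "w_ii"), "E_K"),
        syn(nm["IV"], nm["ID"], _get(params, "w_ii"), "E_K"),
    ]

    feedbacks = [
        FeedbackConnection(nm["MD"], nm["ED"], "negative",
                           _get(params, "w_nf_d"),
                           _get(params, "nf_Vx"), _get(params, "nf_theta")),
        FeedbackConnection(nm["MV"], nm["EV"], "negative",
                           _get(params, "w_nf_v"),
                           _get(params, "nf_Vx"), _get(params, "nf_theta")),
    ]

    cfg = CircuitConfig(
        name=f"functional_unit_{style}_{unit_index}",
        neurons=neurons, muscles=muscles,
        chemical_synapses=synapses, feedbacks=feedbacks,
        e_ca=_opt(params, "E_Ca", DEFAULT_E_CA),
        e_k=_opt(params, "E_K", DEFAULT_E_K),
    )
    return cfg.validate()


#: Coupling keys accepted by :func:`build_coupled_units`, by region.
_COUPLING_KEYS = {
    "body_body": {"muscle_muscle", "inhibitory_inhibitory", "excitatory_excitatory",
                  "positive_feedback", "pf_Vx", "pf_theta"},
    "head_body": {"muscle_muscle", "inhibitory_inhibitory", "smdv_vd", "smdv_vb",
                  "positive_feedback", "pf_Vx", "pf_theta"},
}


def build_coupled_units(
    unit_a: CircuitConfig,
    unit_b: CircuitConfig,
    coupling: Mapping[str, float],
    region: str = "body_body",
) -> CircuitConfig:
    """Couple two adjacent functional units with gap junctions and
    anterior-muscle positive feedback.

    ``unit_a`` is anterior to ``unit_b`` (consecutive unit indices).  Gap
    junctions join same-side muscles and same-side motoneurons; in the
    head-body region the SMDV additionally couples to the posterior unit's
    VD and VB.  The anterior muscles provide positive (proprioceptive)
    feedback to the posterior excitatory motoneurons of the same side.
    """
    if region not in _COUPLING_KEYS:
        raise ConfigurationError(f"unknown region {region!r}")
    unknown = set(coupling) - _COUPLING_KEYS[region]
    if unknown:
        raise ConfigurationError(
            f"unknown coupling key(s) {sorted(unknown)} for region {region!r}"
        )
    ua, ub = unit_a.validate(), unit_b.validate()
    ia = max(m.unit_index for m in ua.muscles)
    ib = min(m.unit_index for m in ub.muscles)
    if ib != ia + 1:
        raise ConfigurationError(
            f"units must be adjacent: got unit indices {ia} and {ib}"
        )

    cfg = CircuitConfig(
        name=f"coupled_units_{region}",
        neurons=[*copy.deepcopy(ua.neurons), *copy.deepcopy(ub.neurons)],
        muscles=[*copy.deepcopy(ua.muscles), *copy.deepcopy(ub.muscles)],
        chemical_synapses=[*copy.deepcopy(ua.chemical_synapses),
                           *copy.deepcopy(ub.chemical_synapses)],
        gap_junctions=[*copy.deepcopy(ua.gap_junctions),
                       *copy.deepcopy(ub.gap_junctions)],
        feedbacks=[*copy.deepcopy(ua.feedbacks), *copy.deepcopy(ub.feedbacks)],
        e_ca=ua.e_ca, e_k=ua.e_k,
    )

    def side_nodes(unit: CircuitConfig, cls: str, side: str) -> list[str]:
        return [n.id for n in unit.neurons if n.neuron_class == cls and n.side == side]

    def pair_up(ids_a: Sequence[str], ids_b: Sequence[str], w: float) -> None:
        for a, b in zip(ids_a, ids_b):
            if w > 0:
                cfg.gap_junctions.append(GapJunction(a, b, w))

    w_mm = float(coupling.get("muscle_muscle", 0.0))
    for side in ("dorsal", "ventral"):
        ma = [m.id for m in ua.muscles if m.side == side]
        mb = [m.id for m in ub.muscles if m.side == side]
        pair_up(ma, mb, w_mm)

    w_ii = float(coupling.get("inhibitory_inhibitory", 0.0))
    for side in ("dorsal", "ventral"):
        pair_up(side_nodes(ua, "inhibitory_motoneuron", side),
                side_nodes(ub, "inhibitory_motoneuron", side), w_ii)

    exc_a = {"body_body": "excitatory_motoneuron", "head_body": "sensory_motoneuron"}
    if region == "body_body":
        w_ee = float(coupling.get("excitatory_excitatory", 0.0))
        for side in ("dorsal", "ventral"):
            pair_up(side_nodes(ua, "excitatory_motoneuron", side),
                    side_nodes(ub, "excitatory_motoneuron", side), w_ee)
    else:
        smdv = side_nodes(ua, "sensory_motoneuron", "ventral")
        vd = side_nodes(ub, "inhibitory_motoneuron", "ventral")
        vb = side_nodes(ub, "excitatory_motoneuron", "ventral")
        if smdv and vd:
            pair_up(smdv, vd, float(coupling.get("smdv_vd", 0.0)))
        if smdv and vb:
            pair_up(smdv, vb, float(coupling.get("smdv_vb", 0.0)))

    # anterior muscle -> posterior same-side excitatory motoneuron (positive)
    w_pf = float(coupling.get("positive_feedback", 0.0))
    pf_Vx = float(coupling.get("pf_Vx", 1.0))
    pf_theta = float(coupling.get("pf_theta", 1.0))
    for side in ("dorsal", "ventral"):
        ma = [m.id for m in ua.muscles if m.side == side]
        eb = side_nodes(ub, "excitatory_motoneuron", side)
        for m_id in ma:
            for n_id in eb:
                cfg.feedbacks.append(
                    FeedbackConnection(m_id, n_id, "positive", w_pf, pf_Vx, pf_theta)
                )
    return cfg.validate()


def build_simplified_worm(
    params: Mapping[str, float], include_rmd: bool = False
) -> CircuitConfig:
    """The simplified whole-worm connectome: 42 neurons and 24 muscles.

    Units 1-3 (head) are driven by an SMDD/SMDV + RMED/RMEV subcircuit under
    the RIB premotor interneuron; units 4-12 each hold a DB/VB excitatory and
    DD/VD inhibitory motoneuron quartet under AVB.  Negative feedback closes
    each motoneuron-muscle loop; positive feedback arrives from the anterior
    two same-side muscles; chain gap junctions couple adjacent muscles and
    adjacent motoneurons along the body.

    ``include_rmd`` adds RMDD/RMDV to the head subcircuit (off by default,
    which reproduces the 42-neuron count).
    """
    e_leak = _opt(params, "E_leak", DEFAULT_E_LEAK)
    C_n, g_n = _get(params, "C_n"), _get(params, "g_n")

    neurons: list[NeuronSpec] = [
        NeuronSpec("AVB", "premotor", "none", None, C_n, g_n, e_leak,
                   _get(params, "I_avb")),
        NeuronSpec("RIB", "premotor", "none", None, C_n, g_n, e_leak,
                   _get(params, "I_rib")),
        NeuronSpec("SMDD", "sensory_motoneuron", "dorsal", 1, C_n, g_n, e_leak, 0.0),
        NeuronSpec("SMDV", "sensory_motoneuron", "ventral", 1, C_n, g_n, e_leak, 0.0),
        NeuronSpec("RMED", "inhibitory_motoneuron", "dorsal", 1, C_n, g_n, e_leak, 0.0),
        NeuronSpec("RMEV", "inhibitory_motoneuron", "ventral", 1, C_n, g_n, e_leak, 0.0),
    ]
    if include_rmd:
        neurons += [
            NeuronSpec("RMDD", "sensory_motoneuron", "dorsal", 2, C_n, g_n, e_leak, 0.0),
            NeuronSpec("RMDV", "sensory_motoneuron", "ventral", 2, C_n, g_n, e_leak, 0.0),
        ]
    for i in range(4, 13):
        neurons += [
            NeuronSpec(f"DB{i}", "excitatory_motoneuron", "dorsal", i,
                       C_n, g_n, e_leak, 0.0),
            NeuronSpec(f"VB{i}", "excitatory_motoneuron", "ventral", i,
                       C_n, g_n, e_leak, 0.0),
            NeuronSpec(f"DD{i}", "inhibitory_motoneuron", "dorsal", i,
                       C_n, g_n, e_leak, 0.0),
            NeuronSpec(f"VD{i}", "inhibitory_motoneuron", "ventral", i,
                       C_n, g_n, e_leak, 0.0),
        ]

    def muscle(mid: str, side: str, unit: int) -> MuscleSpec:
        return MuscleSpec(
            id=mid, side=side, unit_index=unit,
            capacitance=_get(params, "C_m"),
            leak_conductance=_get(params, "g_m"),
            e_leak=e_leak,
            rest_length=_opt(params, "L", REST_LENGTH_UM),
            min_length=_opt(params, "L_min", 0.65 * REST_LENGTH_UM),
            contraction_gain=_get(params, "w_m"),
            spring_constant=_get(params, "k"),
            damping_constant=_get(params, "c"),
            activation_threshold=_get(params, "act_Vx"),
            activation_slope=_get(params, "act_theta"),
        )

    muscles = []
    for i in range(1, 13):
        muscles += [muscle(f"DM{i}", "dorsal", i), muscle(f"VM{i}", "ventral", i)]

    Vx, th = _get(params, "syn_Vx"), _get(params, "syn_theta")

    def syn(pre: str, post: str, w: float, reversal: str = "E_Ca") -> ChemicalSynapse:
        return ChemicalSynapse(pre, post, w, reversal, Vx, th)

    synapses: list[ChemicalSynapse] = [
        syn("RIB", "SMDD", _get(params, "w_rib_d")),
        syn("RIB", "SMDV", _get(params, "w_rib_v")),
        syn("SMDD", "RMEV", _get(params, "w_eI_d")),
        syn("SMDV", "RMED", _get(params, "w_eI_v")),
        syn("RMED", "RMEV", _get(params, "w_ii"), "E_K"),
        syn("RMEV", "RMED", _get(params, "w_ii"), "E_K"),
    ]
    for i in range(1, 4):  # head muscles, units 1-3
        synapses += [
            syn("SMDD", f"DM{i}", _get(params, "w_eM_d")),
            syn("SMDV", f"VM{i}", _get(params, "w_eM_v")),
            syn("RMED", f"DM{i}", _get(params, "w_iM_d"), "E_K"),
            syn("RMEV", f"VM{i}", _get(params, "w_iM_v"), "E_K"),
        ]
    for i in range(4, 13):  # body units
        synapses += [
            syn("AVB", f"DB{i}", _get(params, "w_avb_d")),
            syn("AVB", f"VB{i}", _get(params, "w_avb_v")),
            syn(f"DB{i}", f"DM{i}", _get(params, "w_eM_d")),
            syn(f"VB{i}", f"VM{i}", _get(params, "w_eM_v")),
            syn(f"DB{i}", f"VD{i}", _get(params, "w_eI_d")),
            syn(f"VB{i}", f"DD{i}", _get(params, "w_eI_v")),
            syn(f"DD{i}", f"DM{i}", _get(params, "w_iM_d"), "E_K"),
            syn(f"VD{i}", f"VM{i}", _get(params, "w_iM_v"), "E_K"),
            syn(f"DD{i}", f"VD{i}", _get(params, "w_ii"), "E_K"),
            syn(f"VD{i}", f"DD{i}", _get(params, "w_ii"), "E_K"),
        ]

    gaps: list[GapJunction] = []
    w_mm = _get(params, "w_gap_mm")
    for i in range(1, 12):
        if w_mm > 0:
            gaps += [GapJunction(f"DM{i}", f"DM{i+1}", w_mm),
                     GapJunction(f"VM{i}", f"VM{i+1}", w_mm)]
    w_ee = _get(params, "w_gap_ee")
    w_gii = _get(params, "w_gap_ii")
    for i in range(4, 12):
        if w_ee > 0:
            gaps += [GapJunction(f"DB{i}", f"DB{i+1}", w_ee),
                     GapJunction(f"VB{i}", f"VB{i+1}", w_ee)]
        if w_gii > 0:
            gaps += [GapJunction(f"DD{i}", f"DD{i+1}", w_gii),
                     GapJunction(f"VD{i}", f"VD{i+1}", w_gii)]
    w_head = _get(params, "w_gap_head")
    if w_head > 0:
        gaps += [GapJunction("SMDV", "VD4", w_head),
                 GapJunction("SMDV", "VB4", w_head)]

    feedbacks: list[FeedbackConnection] = []
    nf_Vx, nf_th = _get(params, "nf_Vx"), _get(params, "nf_theta")
    pf_Vx, pf_th = _get(params, "pf_Vx"), _get(params, "pf_theta")
    w_nf_head = _get(params, "w_nf_head")
    for i in range(1, 4):  # head loops close on SMD
        feedbacks += [
            FeedbackConnection(f"DM{i}", "SMDD", "negative", w_nf_head, nf_Vx, nf_th),
            FeedbackConnection(f"VM{i}", "SMDV", "negative", w_nf_head, nf_Vx, nf_th),
        ]
    w_pf_head = _get(params, "w_pf_head")
    for i in (1, 2):  # anterior two head muscles -> SMD (positive)
        if w_pf_head > 0:
            feedbacks += [
                FeedbackConnection(f"DM{i}", "SMDD", "positive", w_pf_head, pf_Vx, pf_th),
                FeedbackConnection(f"VM{i}", "SMDV", "positive", w_pf_head, pf_Vx, pf_th),
            ]
    w_nf_d, w_nf_v = _get(params, "w_nf_d"), _get(params, "w_nf_v")
    w_pf = _get(params, "w_pf")
    for i in range(4, 13):
        feedbacks += [
            FeedbackConnection(f"DM{i}", f"DB{i}", "negative", w_nf_d, nf_Vx, nf_th),
            FeedbackConnection(f"VM{i}", f"VB{i}", "negative", w_nf_v, nf_Vx, nf_th),
        ]
        # positive feedback from the anterior two same-side body muscles;
        # the first body units truncate to the muscles that exist behind the head
        for back in (1, 2):
            j = i - back
            if j >= 4 and w_pf > 0:
                feedbacks += [
                    FeedbackConnection(f"DM{j}", f"DB{i}", "positive", w_pf, pf_Vx, pf_th),
                    FeedbackConnection(f"VM{j}", f"VB{i}", "positive", w_pf, pf_Vx, pf_th),
                ]

    cfg = CircuitConfig(
        name="simplified_worm",
        neurons=neurons, muscles=muscles,
        chemical_synapses=synapses, gap_junctions=gaps, feedbacks=feedbacks,
        e_ca=_opt(params, "E_Ca", DEFAULT_E_CA),
        e_k=_opt(params, "E_K", DEFAULT_E_K),
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# surgery
# ---------------------------------------------------------------------------

def match(**attrs) -> Callable[[object], bool]:
    """Build an edge predicate matching by attribute equality.

    ``match(kind="feedback", polarity="negative")`` selects all negative
    feedback connections; ``kind`` is one of chemical/gap/feedback.
    """

    def predicate(edge: object) -> bool:
        for key, want in attrs.items():
            if getattr(edge, key, None) != want:
                return False
        return True

    return predicate


def modify_connection(
    config: CircuitConfig,
    selector: Callable[[object], bool],
    scale: float,
) -> CircuitConfig:
    """Return a copy of ``config`` with matched edge weights multiplied by
    ``scale`` (``scale=0`` ablates).  The original is untouched."""
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    new = config.copy()
    n_hit = 0
    for edge in new.edges():
        if selector(edge):
            edge.weight = edge.weight * scale
            n_hit += 1
    if n_hit == 0:
        raise LookupError("selector matched no connection")
    return new


# ---------------------------------------------------------------------------
# anatomy table
# ---------------------------------------------------------------------------

def unit_muscle_map() -> pd.DataFrame:
    """The 12-unit partition of the 95 body-wall muscle cells.

    The four muscle quadrants project to two rows (dorsal, ventral) in the
    2-D model; cells sit in staggered pairs so each unit groups two
    consecutive cells per side (e.g. vBWM01/vBWM02 in unit 1).  Units are
    ordered head to tail; unit ``i`` spans body segments ``i`` and ``i+1``.
    """
    rows = []
    for u in range(1, N_UNITS + 1):
        c1, c2 = 2 * u - 1, 2 * u
        rows.append(
            {
                "unit": u,
                "dorsal_cells": f"dBWM{c1:02d}/dBWM{c2:02d}",
                "ventral_cells": f"vBWM{c1:02d}/vBWM{c2:02d}",
                "dorsal_muscle": f"DM{u}",
                "ventral_muscle": f"VM{u}",
                "segments": (u, u + 1),
            }
        )
    return pd.DataFrame(rows)
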