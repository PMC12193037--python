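"""Standard fitting problems: one per circuit scale used in the study.

Each factory wires a genome layout to the matching circuit builder and
fitness targets (1 Hz rhythm; the whole-worm problem adds the 126 um/s
velocity term).  The worm genome decodes ``u1``/``input_ratio`` into the
AVB/RIB premotor synapse weights so drive asymmetry is one gene everywhere.
"""

from __future__ import annotations

from typing import Mapping

from . import params as P
from .circuit import (
    CircuitConfig,
    build_coupled_units,
    build_functional_unit,
    build_simplified_worm,
    build_two_node_loop,
)
from .evolve import EAProblem, FitnessSpec


def _unit_builder(params: Mapping[str, float], unit_index: int = 1,
                  style: str = "body") -> CircuitConfig:
    return build_functional_unit(
        params, input_ratio=params["input_ratio"],
        unit_index=unit_index, style=style,
    )


def _coupling_dict(params: Mapping[str, float], region: str) -> dict[str, float]:
    common = {
        "muscle_muscle": params["w_gap_mm"],
        "inhibitory_inhibitory": params["w_gap_ii"],
        "positive_feedback": params["w_pf"],
        "pf_Vx": params["pf_Vx"],
        "pf_theta": params["pf_theta"],
    }
    if region == "body_body":
        common["excitatory_excitatory"] = params["w_gap_ee"]
    else:
        common["smdv_vd"] = params["w_gap_head"]
        common["smdv_vb"] = params["w_gap_head"]
    return common


def _coupled_builder(params: Mapping[str, float], region: str) -> CircuitConfig:
    style_a = "head" if region == "head_body" else "body"
    unit_a = _unit_builder(params, unit_index=1, style=style_a)
    unit_b = _unit_builder(params, unit_index=2, style="body")
    return build_coupled_units(unit_a, unit_b, _coupling_dict(params, region),
                               region=region)


def _worm_builder(params: Mapping[str, float]) -> CircuitConfig:
    # premotor drive asymmetry lives in the AVB/RIB synapse weights
    # (w_avb_d vs w_avb_v, w_rib_d vs w_rib_v)
    return build_simplified_worm(params)


def two_node_problem(fitness: FitnessSpec | None = None) -> EAProblem:
    # fitness on the second half of the 10 s evaluation, for the same
    # reason as the multi-unit fits: scoring from 20% burn-in lets the EA
    # reward transients whose steady-state frequency is off-target
    return EAProblem(
        layout=P.TWO_NODE_LAYOUT,
        builder=build_two_node_loop,
        fitness=fitness or FitnessSpec(burn_in=0.5),
        aliases=dict(P.TWO_NODE_ALIASES),
    )


#: Multi-unit fits analyse the second half of a longer run so decaying
#: transients cannot score as rhythm, and average two perturbation seeds.
_STEADY_FITNESS = dict(horizon=16.0, burn_in=0.5)


def functional_unit_problem(fitness: FitnessSpec | None = None) -> EAProblem:
    return EAProblem(
        layout=P.FUNCTIONAL_UNIT_LAYOUT,
        builder=_unit_builder,
        fitness=fitness or FitnessSpec(**_STEADY_FITNESS),
        n_seeds=2,
    )


def coupled_units_problem(region: str = "body_body",
                          fitness: FitnessSpec | None = None) -> EAProblem:
    if region not in ("body_body", "head_body"):
        raise ValueError(f"unknown region {region!r}")
    return EAProblem(
        layout=P.COUPLED_UNITS_LAYOUT,
        builder=lambda p: _coupled_builder(p, region),
        fitness=fitness or FitnessSpec(**_STEADY_FITNESS),
        n_seeds=2,
    )


def worm_problem(fitness: FitnessSpec | None = None,
                 include_velocity: bool = True) -> EAProblem:
    return EAProblem(
        layout=P.WORM_LAYOUT,
        builder=_worm_builder,
        fitness=fitness or FitnessSpec(**_STEADY_FITNESS),
        include_velocity=include_velocity,
        n_seeds=2,
    )


PROBLEM_FACTORIES = {
    "two_node": two_node_problem,
    "functional_unit": functional_unit_problem,
    "coupled_body": lambda **kw: coupled_units_problem("body_body", **kw),
    "coupled_head": lambda **kw: coupled_units_problem("head_body", **kw),
    "simplified_worm": worm_problem,
}
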