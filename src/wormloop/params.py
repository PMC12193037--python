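"""Free-parameter layouts and bounds for the fitted circuits.

The optimizer works on real-valued genomes; each gene is a named model
parameter with finite bounds.  Membrane capacities and conductances are
dimensionless multiples of reference values (potentials mV, time s), the
deformation-scale thresholds are um, and the drag/spring/damping constants
set the mechanical time scales.  Bounds are wide enough to contain both
oscillating and silent regimes; none of the printed values below is a
fitted result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Gene:
    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"gene {self.name}: bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"gene {self.name}: lower must be < upper")


GenomeLayout = tuple[Gene, ...]

#: Membrane, synapse and mechanics genes shared by every circuit.
_MEMBRANE_GENES = (
    Gene("C_n", 0.005, 0.2),   # neuron capacity multiple (tau = C/g seconds)
    Gene("g_n", 0.2, 2.0),
    Gene("C_m", 0.02, 0.5),    # muscle membranes are slower than neurons
    Gene("g_m", 0.2, 2.0),
    Gene("syn_Vx", -50.0, 0.0),
    Gene("syn_theta", 1.0, 10.0),
    Gene("act_Vx", -50.0, 0.0),
    Gene("act_theta", 1.0, 10.0),
    Gene("w_m", 0.5, 50.0),
    Gene("k", 0.5, 50.0),
    Gene("c", 0.001, 1.0),
    Gene("C_N", 0.05, 5.0),
    Gene("C_T", 0.02, 2.0),
)

_NEG_FEEDBACK_GENES = (
    Gene("nf_Vx", 0.0, 10.0),
    Gene("nf_theta", 0.2, 3.0),
)

TWO_NODE_LAYOUT: GenomeLayout = _MEMBRANE_GENES + _NEG_FEEDBACK_GENES + (
    Gene("I_ext", 0.0, 100.0),
    Gene("w_che", 0.0, 5.0),
    Gene("w_f", 0.0, 5.0),
)
# the two-node builder reads fb_Vx/fb_theta; alias onto the shared genes
TWO_NODE_ALIASES = {"fb_Vx": "nf_Vx", "fb_theta": "nf_theta"}

_UNIT_WEIGHT_GENES = (
    Gene("w_eM_d", 0.0, 5.0),
    Gene("w_eM_v", 0.0, 5.0),
    Gene("w_eI_d", 0.0, 5.0),
    Gene("w_eI_v", 0.0, 5.0),
    Gene("w_iM_d", 0.0, 5.0),
    Gene("w_iM_v", 0.0, 5.0),
    Gene("w_ii", 0.0, 5.0),
    Gene("w_nf_d", 0.0, 5.0),
    Gene("w_nf_v", 0.0, 5.0),
)

FUNCTIONAL_UNIT_LAYOUT: GenomeLayout = _MEMBRANE_GENES + _NEG_FEEDBACK_GENES + (
    Gene("u1", 0.0, 100.0),
    # dorsal premotor drive relative to ventral, u2/u1
    Gene("input_ratio", 0.05, 3.0),
) + _UNIT_WEIGHT_GENES

#: Coupling genes for two adjacent units (gap junctions + proprioception).
COUPLING_GENES = (
    Gene("w_gap_mm", 0.0, 2.0),
    Gene("w_gap_ii", 0.0, 2.0),
    Gene("w_gap_ee", 0.0, 2.0),
    Gene("w_gap_head", 0.0, 2.0),
    Gene("w_pf", 0.0, 3.0),
    # the positive-feedback threshold sits below the negative one
    Gene("pf_Vx", 0.0, 5.0),
    Gene("pf_theta", 0.2, 3.0),
)

COUPLED_UNITS_LAYOUT: GenomeLayout = FUNCTIONAL_UNIT_LAYOUT + COUPLING_GENES

# the 13-segment body has lighter rods (same total mass), so the whole-worm
# fit may need slower membranes than the 2-3 segment subcircuits
_MEMBRANE_GENES_WORM = tuple(
    {"C_n": Gene("C_n", 0.005, 0.5), "C_m": Gene("C_m", 0.02, 1.5)}.get(g.name, g)
    for g in _MEMBRANE_GENES
)

WORM_LAYOUT: GenomeLayout = _MEMBRANE_GENES_WORM + _NEG_FEEDBACK_GENES + \
    _UNIT_WEIGHT_GENES + COUPLING_GENES + (
    Gene("I_avb", 0.0, 100.0),
    Gene("I_rib", 0.0, 100.0),
    Gene("w_rib_d", 0.0, 5.0),
    Gene("w_rib_v", 0.0, 5.0),
    Gene("w_avb_d", 0.0, 5.0),
    Gene("w_avb_v", 0.0, 5.0),
    Gene("w_nf_head", 0.0, 5.0),
    Gene("w_pf_head", 0.0, 3.0),
)


def layout_names(layout: GenomeLayout) -> list[str]:
    return [g.name for g in layout]


def decode(layout: GenomeLayout, vector: np.ndarray,
           aliases: dict[str, str] | None = None) -> dict[str, float]:
    """Genome vector -> named parameter dict (with alias expansion)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(layout),):
        raise ValueError(f"genome has {vector.shape}, layout needs {len(layout)}")
    params = {g.name: float(v) for g, v in zip(layout, vector)}
    for alias, src in (aliases or {}).items():
        params[alias] = params[src]
    return params


def encode(layout: GenomeLayout, params: dict[str, float]) -> np.ndarray:
    return np.array([float(params[g.name]) for g in layout])


def in_bounds(layout: GenomeLayout, vector: np.ndarray) -> bool:
    vector = np.asarray(vector, dtype=float)
    lo = np.array([g.lower for g in layout])
    hi = np.array([g.upper for g in layout])
    return bool(np.all(vector >= lo) and np.all(vector <= hi))


def clip(layout: GenomeLayout, vector: np.ndarray) -> np.ndarray:
    lo = np.array([g.lower for g in layout])
    hi = np.array([g.upper for g in layout])
    return np.clip(np.asarray(vector, dtype=float), lo, hi)


def random_genome(layout: GenomeLayout, rng: np.random.Generator) -> np.ndarray:
    lo = np.array([g.lower for g in layout])
    hi = np.array([g.upper for g in layout])
    return lo + (hi - lo) * rng.random(len(layout))
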