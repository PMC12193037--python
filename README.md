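# wormloop

A neuromechanical model of *Caenorhabditis elegans* rhythmic forward
locomotion, built around motoneuron–muscle feedback loops rather than
central pattern generators.  The package is for computational
neuroscientists and systems biologists who want to simulate, fit and
dissect closed sensorimotor circuits: it couples graded-potential neural
dynamics to a 2-D articulated multibody body, fits the unknown parameters
with a genetic algorithm against behavioural targets, and computes the
oscillation statistics (frequency, amplitude, synchrony, sensitivity) used
to characterise the circuit.

## The model

Neurons and muscles are single-compartment graded-potential nodes obeying
Kirchhoff's current law,

    C_n dv_n/dt = I_ext + I_syn + I_fb + g_n (E_leak − v_n)
    C_m dv_m/dt = I_syn + g_m (E_leak − v_m)

with sigmoidal chemical synapses `w_che · S(v_pre) · (E_Ca/K − v_post)`,
ohmic gap junctions `w_gap · (v_j − v_i)`, and deformation-gated feedback
currents from muscles to motoneurons: for muscle deformation `δ = L − l`,
negative feedback opens the potassium channel of its motoneuron when the
muscle is contracted (`w_f · S(δ) · (E_K − v)` for δ ≥ 0), positive
(proprioceptive) feedback opens the calcium channel instead.

The body is 13 T-shaped rigid rods joined by 12 dorsoventral muscle-spring
pairs.  Per-rod Newton–Euler equations are projected onto the generalised
coordinates `y = [r₁, θ₁, …, θ₁₃]` through the velocity map `v = G ẏ`
(Jourdain's variational principle), giving `Z ÿ = z` with
`Z = Σ GᵢᵀMᵢGᵢ`.  Muscles produce a tension
`k(l−L) + c l̇ + w_m S(v_m)(l−L_min)`; the environment applies
low-Reynolds resistive drag `−C_N v⊥ − C_T v∥` per segment.

Free parameters are fitted by a seeded genetic algorithm minimising

    F1 = Σ_i [ max(0, 1 − TV_i/(4·A·fre_a·T)) + |1 − fre_i/fre_a| ],
    F2 = |1 − V/V_a|,

the rhythm (target `fre_a = 1 Hz`, amplitude threshold `A = 0.5 um`) and
forward-velocity (target `V_a = 126 um/s`) objectives measured from
swimming in viscous oil.  Circuits at four scales are built in code: a
two-node motoneuron–muscle loop, the four-neuron dorsoventral functional
unit, two gap-junction-coupled units, and a simplified whole-worm
connectome (42 neurons, 24 muscles).  See `docs/methods.md` for the full
model account.

## Worked example

Simulate the committed fitted two-node loop and measure its rhythm:

```python
from wormloop import analysis, fixtures

result = fixtures.simulate_fixture("two_node", duration=20.0, seed=0)
trace = analysis.Trace(result.deformation[:, 0], result.dt_output)
print(f"frequency {analysis.estimate_frequency(trace):.3f} Hz")
print(f"amplitude {analysis.estimate_amplitude(trace):.2f} um")

# the rhythm needs the negative feedback loop: ablate it
silent = fixtures.simulate_scaled_feedback("two_node", nf_scale=0.0,
                                           duration=20.0, seed=0)
t2 = analysis.Trace(silent.deformation[:, 0], silent.dt_output)
print(f"after ablation: frequency {analysis.estimate_frequency(t2):.3f} Hz")
```

prints

```
frequency 1.012 Hz
amplitude 9.83 um
after ablation: frequency 0.000 Hz
```

— the muscle deformation oscillates at the behavioural 1 Hz target, and
removing the muscle-to-motoneuron negative feedback connection silences it.
The same surgery/sweep machinery drives the larger experiments, e.g.
`wormloop sweep --fixture coupled_body --axis gap.muscle_muscle` for the
synchronisation-by-gap-junction analysis or
`wormloop reproduce fig5_worm` for the whole-worm swimming summary.

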