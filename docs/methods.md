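# Methods

## Model overview

`wormloop` models rhythmic forward locomotion of *C. elegans* as a closed
sensorimotor loop between a graded-potential motor circuit and a planar
articulated body, with no intrinsically oscillating (pacemaker) neuron
anywhere in the network.  Rhythm arises from negative feedback: a motoneuron
excites a muscle, the muscle contracts, and the contraction signal
(deformation, not muscle voltage) feeds a hyperpolarising current back to the
motoneuron.  The membrane and mechanical lags around this loop set the
period.  Positive (proprioceptive) feedback from anterior muscles and gap
junctions between neighbouring muscles and motoneurons couple the repeated
units along the body and shape robustness and synchrony rather than rhythm
generation.

## Membrane dynamics

Every neuron and muscle is a single isopotential compartment obeying
Kirchhoff's current law:

    C dv/dt = I_external + I_synapse + I_feedback + g (E_leak − v)     (neurons)
    C dv/dt = I_synapse + g (E_leak − v)                               (muscles)

* Chemical synapses: `w · S(v_pre) · (E_rev − v_post)` with the sigmoid gate
  `S(x) = 1 / (1 + exp(−(x − V_x)/θ_x))`.  Excitatory synapses reverse at
  the calcium potential, inhibitory at the potassium potential.
* Gap junctions: `w · (v_other − v_self)`, applied antisymmetrically so the
  pair conserves current exactly.
* Deformation feedback (the model's sensory pathway): gated by a sigmoid of
  muscle deformation `δ = L − l` (um scale).  For a contracted muscle
  (δ ≥ 0) negative feedback opens the potassium channel (weight `S(δ)`),
  positive feedback the calcium channel; for a stretched muscle the channel
  assignments swap with weight `1 − S(δ)`.  The δ = 0 boundary takes the
  contracted branch; the piecewise form is discontinuous there unless
  V_x = 0, which we treat as a modelling feature of the form — fitted
  thresholds keep the discontinuity small relative to operating deflections.
* Muscles receive no external or feedback currents; muscle–muscle gap
  junctions enter through their synaptic current term.

Units: potentials in mV, time in s, lengths in um.  Capacitances and
conductances are dimensionless multiples of reference values, so `C/g` is
the membrane time constant in seconds.  Defaults (configuration inputs, not
asserted constants): `E_leak = −60 mV`, `E_Ca = +60 mV`, `E_K = −90 mV`.

## Body mechanics

The body is 13 rigid T-shaped rods (total length 1000 um, equal segments of
1000/13 ≈ 76.9 um) joined by revolute joints, actuated by 12 dorsoventral
pairs of damped springs (the muscles).  A muscle of unit *i* anchors at the
anterior joints of segments *i* and *i+1*, offset laterally by the
attachment half-width, so its rest length equals the segment length.

Generalised coordinates are `y = [r1, θ1, …, θ13]` (centroid of segment 1,
the absolute orientation of segment 1, then relative joint angles,
counterclockwise positive).  Segment velocities follow from a recursion over
adjacent rods, giving the linear maps `v = G ẏ` and `v̇ = G ÿ + ĝ` with G
lower block-triangular.  Jourdain's variational principle projects the
per-rod Newton–Euler equations through G:

    Z ÿ = z,   Z = Σ GᵢᵀMᵢGᵢ,   z = Σ Gᵢᵀ(fᵢ − Mᵢĝᵢ)

Z is symmetric positive definite for positive masses and inertias; the
system is solved directly each step (residual < 1e−10, with a logged
diagonal regularisation fallback that does not trigger for sane geometry).

Forces per muscle spring are combined into one scalar tension (positive
pulls the anchors together),

    tension = k (l − L) + c dl/dt + w_m S(v_muscle) (l − L_min),

applied along the unit spring vector with opposite signs at the two anchor
points (Newton's third law), plus the torque of each anchor force about its
segment centroid.  The contractile term saturates as the muscle approaches
its minimum length `L_min` (default 0.65 L).  Environmental drag is
low-Reynolds resistive force at each centroid, `−C_N v⊥ − C_T v∥` about the
segment axis, with no drag torque; with drag off, total linear momentum is
conserved to integration tolerance (verified in tests).

Geometry defaults: uniform density (per-segment mass `1/13` of a unit total
mass), rod inertia from the rectangle formula, and a constant attachment
half-width of 25 um so the straight pose leaves every muscle exactly at rest
length.  A spindle-shaped taper is available (`tapered=True`); it introduces
sub-um rest-pose deformations.  Spring slots on a side without an
innervated muscle (e.g. the ventral side of the two-node loop) carry passive
viscoelasticity with the mean fitted muscle `k` and `c` — body elasticity is
assumed uniform.

## Circuits

* **Two-node loop** — one motoneuron, one muscle, one excitatory synapse,
  one negative feedback, constant external drive; mounted on a two-segment
  body.
* **Functional unit** — the dorsoventral switch: DB/VB-like excitors driving
  their own-side muscle and the contralateral inhibitor (DD/VD- or
  RME-like), inhibitors relaxing their own-side muscle and inhibiting each
  other, one negative feedback per side.  Premotor drive is `u1` (ventral)
  and `u2 = input_ratio · u1` (dorsal).  Because bending shortens one side
  exactly as it stretches the other, any oscillation is dorsoventrally
  antiphase in deformation; the circuit asymmetries decide whether
  oscillation exists at all.
* **Coupled units** — two adjacent units joined by muscle–muscle and
  motoneuron–motoneuron gap junctions (head–body uses SMDV–VD4/VB4 instead
  of the excitatory chain), plus positive feedback from anterior muscles to
  posterior same-side excitors.
* **Simplified worm** — 42 neurons / 24 muscles: AVB and RIB premotor
  interneurons (constant external drive — triggers, not oscillators), an
  SMDD/SMDV + RMED/RMEV head subcircuit for units 1–3, and a DB/VB/DD/VD
  quartet per body unit 4–12, with chain gap junctions, per-unit negative
  feedback and positive feedback from the two anterior same-side muscles
  (truncated where no anterior body muscle exists; head units source their
  positive feedback from head muscles 1–2).  RMDD/RMDV can be added with a
  flag but are off by default, matching the 42-neuron count.

## Integration

The joint state (membrane potentials, coordinates, rates) advances by
fixed-step classical RK4, default `dt = 0.5 ms`, output stride 10 (5 ms
samples).  Deformations are recomputed inside every derivative evaluation —
no operator splitting.  The system is smooth and non-stiff at fitted
parameters; halving dt changes the two-node frequency by < 1% (tested).
Fixed stepping keeps runs bit-reproducible for the optimizer.  Randomness
enters only through the initial 1 mV Gaussian potential perturbation and
the GA, both seeded.

## Parameter fitting

Free parameters (synapse/junction/feedback weights, sigmoid thresholds and
slopes on both voltage and deformation scales, membrane C and g multiples,
contraction gain, spring and damping constants, drag coefficients, drive
currents) are fitted by a seeded real-coded genetic algorithm: tournament
selection (size 3), blend crossover (rate 0.9), per-gene Gaussian mutation
(rate 0.1, σ = 10% of the gene range), one elite.  Failed or non-finite
simulations score a large finite penalty (1e6) rather than aborting.

The fitness per muscle is an amplitude-deficit term
`max(0, 1 − TV/(4·A·fre_a·T))` (TV = total variation of the deformation
over the analysed window; a sinusoid of amplitude A at the target frequency
makes it exactly zero; the functional form is pluggable) plus the frequency
error `|1 − fre/fre_a|` with targets `fre_a = 1 Hz`, amplitude threshold
`A = 0.5 um`.  Whole-worm fits add `|1 − V/V_a|` with `V_a = 126 um/s`,
the forward centroid velocity projected on the mean anterior heading.  The
committed whole-worm fixture was produced in two stages: a rhythm-dominated
fit, continued under an objective weighting the velocity deficit by the
muscle count — the plain sum lets the 24 per-muscle rhythm terms dwarf the
single velocity term, which stalls amplitude growth along the body (the
recorded provenance of each fixture names its objective and
population/generation sizes).

Evaluation horizons: 10 s for the two-node loop; 16 s for the multi-unit
circuits, the latter averaged over two seeded initial perturbations.  In
every case the fitness statistics are computed on the second half of the
evaluation window.  The longer late-window evaluation exists
because a 10 s window lets slowly decaying transients masquerade as rhythm;
analysing seconds 8–16 over two initial conditions selects parameter sets
whose oscillation is a genuine attractor.  Committed fixtures were
additionally verified to hold frequency and amplitude out to 40 s across
several perturbation seeds.

## Analysis statistics

* **Frequency**: dominant mean-removed periodogram peak, refined by mean-
  crossing counting normalised by the first-to-last crossing span; traces
  whose post-burn-in peak-to-peak range is below the oscillation floor
  (1% of muscle rest length, ≈ 0.77 um) or with fewer than 3 cycles report
  0 Hz.  "Stable oscillation" means frequency > 0 under this rule.
* **Amplitude**: half the mean peak-to-trough excursion over detected
  cycles; offset-invariant; 0 for flat traces.
* **Deformation difference**: mean over all unordered trace pairs of the
  time-averaged squared difference (the overline read as a time average);
  for two coupled units the reported disparity averages the dorsal and
  ventral same-side pair statistics so the designed dorsoventral antiphase
  does not swamp the between-unit signal.
* **Sensitivity**: `S = (Δf/f)/(Δx/x)` for a 1% parameter increase, f being
  the mean per-muscle frequency or amplitude, re-measured from a fresh
  simulation on the second half of a long run (so the re-equilibration
  transient after the bump stays out of the window); undefined (flagged)
  when the baseline is zero.
* **Phase portraits**: post-burn-in (motoneuron potential, deformation)
  orbits summarised by extent and convex-hull area.
* Scalar summaries over muscles use the mean across muscles.  Analyses
  discard the first 20% of each run by default.

## What the model does and does not capture

The simulated conditions correspond to swimming in viscous fluid (resistive
drag, 1 Hz target rhythm, 126 um/s target speed).  Not modelled: action
potentials in muscle (graded potentials only), ion-channel kinetics,
3-D mechanics, substrate contact/crawling, self-intersection, hydrodynamic
interactions beyond resistive-force theory, and the full 302-neuron
connectome.  Passing tests therefore demonstrate properties of this closed
feedback-loop model under the stated drive and drag, not a quantitative
reconstruction of any individual recording.

## Problem sizes used in checks

Automated checks use desk-scale runs: GA fits of the two-node loop at
population ≤ 32 for ≤ 30 generations with 10 s evaluations; fixture
simulations of 15–40 s; sweeps of 5–6 grid points; whole-worm property
checks on the committed fitted parameter set rather than re-optimisation
(the multi-unit fits were produced once at population 24–32 over 25–40
generations and committed as fixtures).
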