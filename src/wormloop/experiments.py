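"""Scripted reproductions of the circuit-level experiments.

Every function works on a committed fitted fixture, performs wiring surgery
or parameter sweeps through the public circuit API, and returns a tidy
DataFrame, so the shell interface and the test suite share one code path.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis as A
from . import fixtures as FX
from .circuit import match
from .evolve import forward_velocity

DEFAULT_BURN_IN = 0.2


def _freq_amp(result, burn_in: float = DEFAULT_BURN_IN) -> tuple[float, float]:
    return (A.mean_frequency(result, burn_in), A.mean_amplitude(result, burn_in))


def unit_pair_difference(result, burn_in: float = DEFAULT_BURN_IN) -> float:
    """Deformation disparity between adjacent units (same-side pairs).

    The fig4_coupling statistic: the time-averaged squared difference between
    the two units' dorsal deformations and between their ventral ones,
    averaged.
    """
    sl = result.burn_slice(burn_in)
    dt = result.dt_output
    units = sorted({int(mid[2:]) for mid in result.muscle_ids})
    vals = []
    for side in ("DM", "VM"):
        traces = [A.Trace(result.delta(f"{side}{u}")[sl], dt) for u in units]
        vals.append(A.deformation_difference(traces))
    return float(np.mean(vals))


def gap_junction_sweep(
    name: str = "coupled_body",
    key: str = "muscle_muscle",
    scales: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    duration: float = 20.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Synchronisation vs gap-junction strength between two coupled units.

    ``key`` picks which junction population is scaled (muscle_muscle scales
    the muscle-muscle junctions; inhibitory/excitatory scale the motoneuron
    chains).  Runs start from seeded perturbed states so the units begin
    out of phase.
    """
    selectors = {
        "muscle_muscle": lambda cfg: match(kind="gap"),  # refined below
    }
    rows = []
    config = FX.fixture_config(name)
    muscle_ids = set(config.muscle_ids)
    inhib = {n.id for n in config.neurons if n.neuron_class == "inhibitory_motoneuron"}
    excit = {n.id for n in config.neurons
             if n.neuron_class in ("excitatory_motoneuron", "sensory_motoneuron")}

    def selector(edge):
        if getattr(edge, "kind", None) != "gap":
            return False
        if key == "muscle_muscle":
            return edge.a in muscle_ids and edge.b in muscle_ids
        if key == "inhibitory_inhibitory":
            return edge.a in inhib and edge.b in inhib
        if key == "excitatory_excitatory":
            return edge.a in excit and edge.b in excit
        raise KeyError(f"unknown junction population {key!r}")

    for s in scales:
        result = FX.simulate_modified(name, [(selector, s)], duration, seed)
        freq, amp = _freq_amp(result)
        rows.append({
            "scale": s,
            "deformation_difference": unit_pair_difference(result),
            "frequency": freq,
            "amplitude": amp,
        })
    return pd.DataFrame(rows)


def feedback_sweep(
    name: str,
    polarity: str = "negative",
    scales: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    duration: float = 20.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Frequency/amplitude as one feedback population is scaled (w/w_opt)."""
    rows = []
    for s in scales:
        kwargs = {"nf_scale": s} if polarity == "negative" else {"pf_scale": s}
        result = FX.simulate_scaled_feedback(name, duration=duration, seed=seed,
                                             **kwargs)
        freq, amp = _freq_amp(result)
        rows.append({"scale": s, "frequency": freq, "amplitude": amp,
                     "oscillating": freq > 0})
    return pd.DataFrame(rows)


def asymmetry_sweep(
    ratios: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    axis: str = "input",
    duration: float = 20.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Dorsoventral switching vs asymmetry on the fitted functional unit.

    ``axis='input'`` sweeps the premotor drive ratio u2/u1; ``axis='eM'``
    sweeps the dorsal/ventral ratio of excitatory motoneuron-to-muscle
    weights (w_d/w_v) with the ventral side held at its fitted value.
    Alternation is summarised by the zero-lag correlation of the two
    deformations (negative = antiphase) and the mean amplitude.
    """
    params = FX.fixture_params("functional_unit")
    rows = []
    for ratio in ratios:
        p = dict(params)
        if axis == "input":
            p["input_ratio"] = ratio
        elif axis == "eM":
            p["w_eM_d"] = ratio * p["w_eM_v"]
        elif axis == "iM":
            p["w_iM_d"] = ratio * p["w_iM_v"]
        elif axis == "nf":
            p["w_nf_d"] = ratio * p["w_nf_v"]
        else:
            raise KeyError(f"unknown asymmetry axis {axis!r}")
        problem = FX.fixture_problem("functional_unit")
        result = problem.simulate(p, seed=seed, duration=duration)
        sl = result.burn_slice(DEFAULT_BURN_IN)
        dt = result.dt_output
        d = A.Trace(result.delta("DM1")[sl], dt)
        v = A.Trace(result.delta("VM1")[sl], dt)
        freq, amp = _freq_amp(result)
        corr = A.zero_lag_correlation(d, v) if amp > 0 else np.nan
        rows.append({"ratio": ratio, "frequency": freq, "amplitude": amp,
                     "dv_correlation": corr, "oscillating": freq > 0})
    return pd.DataFrame(rows)


def stability_grid(
    name: str = "coupled_body",
    pf_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0),
    nf_levels: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    duration: float = 15.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Average percentage of stable oscillation per negative-feedback level."""
    rows = []
    for nf in nf_levels:
        pct = A.stable_oscillation_fraction(
            lambda pf, nf_=nf: FX.simulate_scaled_feedback(
                name, nf_scale=nf_, pf_scale=pf, duration=duration, seed=seed
            ),
            pf_grid, nf,
        )
        rows.append({"nf_level": nf, "stable_percent": pct})
    return pd.DataFrame(rows)


def sensitivity_report(
    name: str = "simplified_worm",
    perturbation: float = 0.01,
    duration: float = 40.0,
    seed: int = 1,
    parameters: Sequence[str] | None = None,
    burn_in: float = 0.5,
) -> pd.DataFrame:
    """Normalised sensitivity of frequency and amplitude to each parameter.

    Measured on the second half of a long run: sensitivity quantifies how
    the steady rhythm shifts with a parameter, so the re-equilibration
    transient right after the bump must stay out of the analysed window.
    """
    problem = FX.fixture_problem(name)
    params = FX.fixture_params(name)
    cache: dict = {}

    def sim(p):
        key = tuple(sorted(p.items()))
        if key not in cache:
            cache[key] = problem.simulate(p, seed=seed, duration=duration)
        return cache[key]
    names = list(parameters) if parameters else [g.name for g in problem.layout]
    feedback_genes = {"w_nf_d", "w_nf_v", "w_nf_head", "w_pf", "w_pf_head",
                      "w_f", "nf_Vx", "nf_theta", "pf_Vx", "pf_theta"}
    rows = []
    for pid in names:
        row = {"parameter": pid,
               "is_feedback": pid in feedback_genes}
        for metric in ("frequency", "amplitude"):
            try:
                row[f"S_{metric}"] = A.sensitivity(
                    sim, params, pid, metric, perturbation, burn_in
                )
            except ZeroDivisionError:
                row[f"S_{metric}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def worm_summary(duration: float = 20.0, seed: int = 1,
                 burn_in: float = DEFAULT_BURN_IN) -> dict:
    """Whole-worm locomotion summary from the fitted fixture.

    Reports the travelling-wave structure (mean phase lag of unit i+1
    behind unit i, from cross-correlation of adjacent dorsal deformations),
    the VB7/DB7 antiphase correlation, forward velocity and rhythm stats.
    """
    result = FX.simulate_fixture("simplified_worm", duration=duration, seed=seed)
    sl = result.burn_slice(burn_in)
    dt = result.dt_output
    freq, amp = _freq_amp(result, burn_in)

    lags = []
    # phase lag is circular in the period; searching +-T/2 makes the
    # reported lag unambiguous (a -0.9T peak is the same relation as +0.1T)
    max_lag = int(round(0.5 / max(freq, 0.25) / dt))
    for u in range(4, 12):
        a = A.Trace(result.delta(f"DM{u}")[sl], dt)
        b = A.Trace(result.delta(f"DM{u+1}")[sl], dt)
        lag_idx, corr = A.cross_correlation(a, b, max_lag)
        lags.append(float(lag_idx[np.nanargmax(corr)]) * dt)
    vb = A.Trace(result.potential("VB7")[sl], dt)
    db = A.Trace(result.potential("DB7")[sl], dt)
    return {
        "frequency": freq,
        "amplitude": amp,
        "velocity": forward_velocity(result, burn_in),
        "mean_adjacent_lag": float(np.mean(lags)),
        "adjacent_lags": lags,
        "vb_db_correlation": A.zero_lag_correlation(vb, db),
        "displacement": float(np.linalg.norm(result.centroid[-1]
                                             - result.centroid[0])),
    }
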