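"""Oscillation statistics derived from simulated traces.

Frequency is the dominant mean-removed periodogram peak refined by
zero-crossing counting; amplitude is half the mean peak-to-trough excursion
over detected cycles.  A trace counts as oscillating only if its
post-burn-in peak-to-peak range clears a floor (default 1% of the muscle
rest length for deformation traces) and at least three cycles are detected;
sub-floor traces report 0 Hz / 0 amplitude rather than noise-driven values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.signal

from .circuit import REST_LENGTH_UM

#: Peak-to-peak floor (um) below which a deformation trace is "not oscillating".
OSCILLATION_FLOOR = 0.01 * REST_LENGTH_UM
MIN_CYCLES = 3


@dataclass
class Trace:
    """Uniformly sampled scalar time series."""

    values: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("trace needs >= 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def tail(self, burn_in: float) -> np.ndarray:
        if not 0 <= burn_in < 1:
            raise ValueError("burn_in fraction must be in [0, 1)")
        return self.values[int(np.floor(burn_in * len(self.values))):]


def _zero_crossings(v: np.ndarray) -> np.ndarray:
    sign = np.sign(v)
    sign[sign == 0] = 1
    return np.flatnonzero(sign[1:] != sign[:-1])


def estimate_frequency(
    trace: Trace, burn_in: float = 0.2, floor: float = OSCILLATION_FLOOR
) -> float:
    """Dominant oscillation frequency (Hz); 0 for flat / sub-floor traces."""
    v = trace.tail(burn_in)
    if len(v) < 4:
        raise ValueError("trace too short after burn-in")
    v = v - np.mean(v)
    if np.ptp(v) < floor:
        return 0.0
    freqs, power = scipy.signal.periodogram(v, fs=1.0 / trace.dt)
    if len(power) < 2:
        return 0.0
    peak = float(freqs[1:][np.argmax(power[1:])])
    if peak <= 0:
        return 0.0
    # refine: mean crossings happen twice per cycle; normalising by the
    # first-to-last crossing span avoids window-edge bias
    crossings = _zero_crossings(v)
    if len(crossings) < 2 * MIN_CYCLES:
        return 0.0
    span = (crossings[-1] - crossings[0]) * trace.dt
    if span <= 0:
        return peak
    f_cross = (len(crossings) - 1) / 2.0 / span
    # crossings are robust to spectral leakage but biased by noise; keep the
    # periodogram peak unless the two disagree by more than half a bin
    if abs(f_cross - peak) <= max(2.0 / (len(v) * trace.dt), 0.1 * peak):
        return f_cross
    # disagreement: either the crossings are noise-inflated or the signal is
    # a non-sinusoidal (e.g. relaxation) waveform with cycle-length jitter,
    # where windowed spectral power smears away from the cycle rate.  Decide
    # by counting prominent cycles directly: if the peak-interval rate
    # corroborates the crossing rate, the crossings are clean and the cycle
    # rate is the dominant frequency.
    prom = 0.25 * np.ptp(v)
    peaks_idx, _ = scipy.signal.find_peaks(v, prominence=prom)
    if len(peaks_idx) >= MIN_CYCLES + 1:
        f_peaks = (len(peaks_idx) - 1) / (
            (peaks_idx[-1] - peaks_idx[0]) * trace.dt
        )
        if abs(f_peaks - f_cross) <= 0.15 * f_cross:
            return f_cross
    return peak


def estimate_amplitude(
    trace: Trace, burn_in: float = 0.2, floor: float = OSCILLATION_FLOOR
) -> float:
    """Half the mean peak-to-trough excursion; offset-invariant; 0 when flat."""
    v = trace.tail(burn_in)
    if np.ptp(v) < floor:
        return 0.0
    span = np.ptp(v)
    peaks, _ = scipy.signal.find_peaks(v, prominence=0.25 * span)
    troughs, _ = scipy.signal.find_peaks(-v, prominence=0.25 * span)
    if len(peaks) < 2 or len(troughs) < 2:
        return float(span / 2.0)
    return float((np.mean(v[peaks]) - np.mean(v[troughs])) / 2.0)


def is_oscillating(
    trace: Trace, burn_in: float = 0.2, floor: float = OSCILLATION_FLOOR
) -> bool:
    return estimate_frequency(trace, burn_in, floor) > 0.0


def deformation_difference(traces: Sequence[Trace]) -> float:
    """Mean over all unordered pairs of the time-averaged squared difference.

    Zero iff all traces coincide on the grid; identical-frequency antiphase
    sinusoids of amplitude a give 2 a^2.
    """
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    n = len(traces[0].values)
    for tr in traces:
        if len(tr.values) != n or tr.dt != traces[0].dt:
            raise ValueError("traces must share one time grid")
    total = 0.0
    count = 0
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            total += float(np.mean((traces[i].values - traces[j].values) ** 2))
            count += 1
    return total / count


def cross_correlation(a: Trace, b: Trace, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of ``a`` against ``b`` shifted by each lag.

    Returns ``(lags, corr)`` over lags in [-max_lag, max_lag] (samples).
    A zero-variance overlap yields NaN at that lag.
    """
    if len(a.values) != len(b.values) or a.dt != b.dt:
        raise ValueError("traces must share one time grid")
    va, vb = a.values, b.values
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag < 0:
            x, y = va[-lag:], vb[:lag] if lag else vb
        elif lag > 0:
            x, y = va[:-lag], vb[lag:]
        else:
            x, y = va, vb
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            corr[k] = np.nan
        else:
            corr[k] = float(np.corrcoef(x, y)[0, 1])
    return lags, corr


def zero_lag_correlation(a: Trace, b: Trace) -> float:
    _, corr = cross_correlation(a, b, 0)
    return float(corr[0])


@dataclass
class PhasePortrait:
    """Post-burn-in (potential, deformation) orbit with extent summaries."""

    v: np.ndarray
    delta: np.ndarray
    v_extent: float
    delta_extent: float
    area: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.v, self.delta])


def phase_portrait(v_trace: Trace, delta_trace: Trace,
                   burn_in: float = 0.2) -> PhasePortrait:
    """Orbit of motoneuron potential against muscle deformation.

    ``area`` is the convex-hull area of the orbit (zero for a fixed point),
    a robust proxy for the inner-circle-to-outer-loop trajectory changes
    driven by feedback strength.
    """
    if len(v_trace.values) != len(delta_trace.values):
        raise ValueError("traces must share one time grid")
    v = v_trace.tail(burn_in)
    d = delta_trace.tail(burn_in)
    v_ext, d_ext = float(np.ptp(v)), float(np.ptp(d))
    pts = np.column_stack([v, d])
    if v_ext < 1e-12 or d_ext < 1e-12:
        area = 0.0
    else:
        from scipy.spatial import ConvexHull

        area = float(ConvexHull(pts).volume)  # 2-D hull: volume == area
    return PhasePortrait(v, d, v_ext, d_ext, area)


# ---------------------------------------------------------------------------
# model-level statistics (work on a "simulate" closure so they stay agnostic
# of how the parameterisation maps to circuits)
# ---------------------------------------------------------------------------

def muscle_traces(result, burn_in: float = 0.0) -> list[Trace]:
    """Deformation traces (one per muscle) from a simulation result."""
    return [
        Trace(result.deformation[:, j], result.dt_output, label=mid)
        for j, mid in enumerate(result.muscle_ids)
    ]


def mean_frequency(result, burn_in: float = 0.2) -> float:
    """Mean per-muscle deformation frequency (Hz; non-oscillating muscles
    count 0)."""
    freqs = [estimate_frequency(tr, burn_in) for tr in muscle_traces(result)]
    return float(np.mean(freqs)) if freqs else 0.0


def mean_amplitude(result, burn_in: float = 0.2) -> float:
    amps = [estimate_amplitude(tr, burn_in) for tr in muscle_traces(result)]
    return float(np.mean(amps)) if amps else 0.0


def sensitivity(
    simulate: Callable[[dict], object],
    params: dict,
    parameter_id: str,
    metric: str = "frequency",
    perturbation: float = 0.01,
    burn_in: float = 0.2,
) -> float:
    """Normalised sensitivity S = (df/f) / (dx/x) for a 1% (default) bump.

    ``simulate`` maps a parameter dict to a SimulationResult.  Raises
    ``ZeroDivisionError`` when the baseline metric is 0 (flagged undefined).
    """
    measure = {"frequency": mean_frequency, "amplitude": mean_amplitude}[metric]
    base = measure(simulate(dict(params)), burn_in)
    if base == 0:
        raise ZeroDivisionError(
            f"baseline {metric} is zero; sensitivity undefined"
        )
    bumped = dict(params)
    if bumped[parameter_id] == 0:
        return 0.0  # a zero parameter cannot be perturbed multiplicatively
    bumped[parameter_id] = bumped[parameter_id] * (1.0 + perturbation)
    new = measure(simulate(bumped), burn_in)
    return float(((new - base) / base) / perturbation)


def stable_oscillation_fraction(
    simulate: Callable[[float, float], object],
    pf_grid: Sequence[float],
    nf_level: float,
    burn_in: float = 0.2,
) -> float:
    """Percentage of positive-feedback strengths sustaining oscillation.

    ``simulate(pf_scale, nf_scale)`` runs the model with the feedback
    weights scaled relative to their fitted values; a grid point counts when
    the mean fraction of oscillating muscles (frequency > 0 above the floor)
    is above one half.
    """
    if len(pf_grid) == 0:
        raise ValueError("pf_grid must be non-empty")
    hits = 0.0
    for pf in pf_grid:
        result = simulate(pf, nf_level)
        traces = muscle_traces(result)
        osc = [1.0 if is_oscillating(tr, burn_in) else 0.0 for tr in traces]
        hits += float(np.mean(osc))
    return 100.0 * hits / len(pf_grid)
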