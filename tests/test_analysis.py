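"""Oscillation statistics on synthetic traces with known answers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormloop import analysis as A
from wormloop.analysis import (
    Trace,
    cross_correlation,
    deformation_difference,
    estimate_amplitude,
    estimate_frequency,
    phase_portrait,
    sensitivity,
    stable_oscillation_fraction,
)

DT = 1e-3


def sine(freq=1.0, amp=1.0, duration=20.0, phase=0.0, offset=0.0, dt=DT):
    t = np.arange(0.0, duration, dt)
    return Trace(offset + amp * np.sin(2 * np.pi * freq * t + phase), dt)


class TestFrequency:
    def test_unit_sinusoid(self):
        assert estimate_frequency(sine(1.0)) == pytest.approx(1.0, abs=0.05)

    def test_constant_trace_reports_zero(self):
        t = Trace(np.full(1000, 2.5), DT)
        assert estimate_frequency(t) == 0.0

    def test_noisy_sinusoid(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 20.0, DT)
        tr = Trace(np.sin(2 * np.pi * 0.7 * t) + 0.1 * rng.standard_normal(len(t)),
                   DT)
        assert estimate_frequency(tr) == pytest.approx(0.7, abs=0.05)

    def test_offset_and_shift_invariance(self):
        base = estimate_frequency(sine(1.3))
        assert estimate_frequency(sine(1.3, offset=40.0)) == pytest.approx(base,
                                                                           abs=0.02)
        assert estimate_frequency(sine(1.3, phase=1.1)) == pytest.approx(base,
                                                                         abs=0.02)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            estimate_frequency(Trace(np.zeros(4), DT), burn_in=0.5)

    def test_jittered_relaxation_waveform_reports_cycle_rate(self):
        # plateau-and-dip cycles with jittered lengths smear spectral power
        # away from the cycle rate; the estimator must report how often the
        # signal actually cycles, not the displaced periodogram peak
        rng = np.random.default_rng(11)
        parts = []
        n_cycles = 18
        for _ in range(n_cycles):
            period = 1.0 + 0.15 * rng.uniform(-1.0, 1.0)
            n = int(round(period / DT))
            ph = np.linspace(0.0, 1.0, n, endpoint=False)
            cyc = np.where(ph < 0.75, 7.0, -21.0 * np.sin(
                np.pi * (ph - 0.75) / 0.25))
            parts.append(cyc)
        v = np.concatenate(parts)
        expected = n_cycles / (len(v) * DT)
        got = estimate_frequency(Trace(v, DT), burn_in=0.0)
        assert got == pytest.approx(expected, rel=0.1)


class TestAmplitude:
    def test_sinusoid_amplitude(self):
        assert estimate_amplitude(sine(1.0, amp=3.0)) == pytest.approx(3.0,
                                                                       rel=0.02)

    def test_constant_trace(self):
        assert estimate_amplitude(Trace(np.ones(1000), DT)) == 0.0

    def test_offset_invariance(self):
        a = estimate_amplitude(sine(1.0, amp=2.0))
        b = estimate_amplitude(sine(1.0, amp=2.0, offset=100.0))
        assert b == pytest.approx(a, rel=1e-6)


class TestDeformationDifference:
    def test_identical_traces_zero(self):
        tr = sine(1.0)
        assert deformation_difference([tr, Trace(tr.values.copy(), DT)]) == 0.0

    def test_antiphase_closed_form(self):
        a = 2.0
        # whole number of periods so the time average is exact
        t1 = sine(1.0, amp=a, duration=10.0)
        t2 = Trace(-t1.values, DT)
        assert deformation_difference([t1, t2]) == pytest.approx(2 * a**2,
                                                                 rel=1e-3)

    def test_three_traces_match_brute_force(self):
        rng = np.random.default_rng(3)
        traces = [Trace(rng.standard_normal(500), DT) for _ in range(3)]
        got = deformation_difference(traces)
        pairs = [(0, 1), (0, 2), (1, 2)]
        want = np.mean([
            np.mean((traces[i].values - traces[j].values) ** 2)
            for i, j in pairs
        ])
        assert got == pytest.approx(want, rel=1e-12)

    @given(st.permutations([0, 1, 2, 3]))
    @settings(deadline=None, max_examples=10)
    def test_permutation_invariant(self, perm):
        rng = np.random.default_rng(11)
        traces = [Trace(rng.standard_normal(200), DT) for _ in range(4)]
        base = deformation_difference(traces)
        assert deformation_difference([traces[i] for i in perm]) == \
            pytest.approx(base, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            deformation_difference([sine(1.0, duration=2.0),
                                    sine(1.0, duration=3.0)])


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_one(self):
        tr = sine(1.0)
        lags, corr = cross_correlation(tr, tr, 5)
        assert corr[lags == 0][0] == pytest.approx(1.0)

    def test_antiphase_is_minus_one(self):
        tr = sine(1.0)
        neg = Trace(-tr.values, DT)
        _, corr = cross_correlation(tr, neg, 0)
        assert corr[0] == pytest.approx(-1.0)

    def test_shift_recovers_lag(self):
        shift = 150
        rng = np.random.default_rng(5)
        base = np.convolve(rng.standard_normal(4000), np.ones(50) / 50, "same")
        a = Trace(base[:-shift], DT)
        b = Trace(base[shift:], DT)  # b leads: b[t] = a[t + shift]
        lags, corr = cross_correlation(a, b, 300)
        assert lags[np.nanargmax(corr)] == pytest.approx(-shift, abs=5)

    def test_values_bounded(self):
        rng = np.random.default_rng(9)
        a = Trace(rng.standard_normal(500), DT)
        b = Trace(rng.standard_normal(500), DT)
        _, corr = cross_correlation(a, b, 50)
        assert np.all(np.abs(corr[~np.isnan(corr)]) <= 1.0 + 1e-12)

    def test_zero_variance_flagged(self):
        a = Trace(np.ones(100), DT)
        b = Trace(np.arange(100.0), DT)
        _, corr = cross_correlation(a, b, 0)
        assert np.isnan(corr[0])


class TestPhasePortrait:
    def test_fixed_point_has_zero_area(self):
        v = Trace(np.full(500, -40.0), DT)
        d = Trace(np.full(500, 1.0), DT)
        pp = phase_portrait(v, d)
        assert pp.area == 0.0 and pp.v_extent == 0.0

    def test_circular_orbit_area(self):
        t = np.arange(0.0, 10.0, DT)
        r = 2.0
        v = Trace(r * np.cos(2 * np.pi * t), DT)
        d = Trace(r * np.sin(2 * np.pi * t), DT)
        pp = phase_portrait(v, d, burn_in=0.0)
        assert pp.area == pytest.approx(np.pi * r**2, rel=0.02)


class TestSensitivity:
    def test_linear_metric_has_unit_sensitivity(self):
        # synthetic harness: "simulation" whose mean frequency is c * x
        class FakeResult:
            def __init__(self, f):
                t = np.arange(0.0, 20.0, DT)
                vals = 5.0 * np.sin(2 * np.pi * f * t)
                self.deformation = vals[:, None]
                self.muscle_ids = ["m"]
                self.t = t

            @property
            def dt_output(self):
                return DT

        s = sensitivity(lambda p: FakeResult(0.5 * p["x"]), {"x": 2.0}, "x",
                        metric="frequency")
        assert s == pytest.approx(1.0, abs=0.1)

    def test_untouched_parameter_has_zero_sensitivity(self):
        class FakeResult:
            def __init__(self):
                t = np.arange(0.0, 20.0, DT)
                self.deformation = 5.0 * np.sin(2 * np.pi * t)[:, None]
                self.muscle_ids = ["m"]
                self.t = t

            @property
            def dt_output(self):
                return DT

        s = sensitivity(lambda p: FakeResult(), {"x": 2.0, "dead": 1.0},
                        "dead", metric="frequency")
        assert s == 0.0

    def test_zero_baseline_flagged(self):
        class Flat:
            def __init__(self):
                self.t = np.arange(0.0, 20.0, DT)
                self.deformation = np.zeros((len(self.t), 1))
                self.muscle_ids = ["m"]

            @property
            def dt_output(self):
                return DT

        with pytest.raises(ZeroDivisionError):
            sensitivity(lambda p: Flat(), {"x": 1.0}, "x")


class TestStableOscillationFraction:
    def make_result(self, oscillates):
        class R:
            def __init__(self):
                t = np.arange(0.0, 20.0, DT)
                v = (5.0 * np.sin(2 * np.pi * t) if oscillates
                     else np.zeros(len(t)))
                self.deformation = v[:, None]
                self.muscle_ids = ["m"]
                self.t = t

            @property
            def dt_output(self):
                return DT

        return R()

    def test_single_oscillating_point_is_hundred_percent(self):
        pct = stable_oscillation_fraction(
            lambda pf, nf: self.make_result(True), [1.0], 1.0)
        assert pct == 100.0

    def test_silent_grid_is_zero(self):
        pct = stable_oscillation_fraction(
            lambda pf, nf: self.make_result(False), [0.5, 1.0, 2.0], 0.0)
        assert pct == 0.0
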