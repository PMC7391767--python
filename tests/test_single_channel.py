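"""Idealization, dwell-time kinetics and Brønsted Φ analysis."""

import numpy as np
import pytest

import patchkit as pk
from patchkit.single_channel import CLOSED, OPEN, DwellEvent
from patchkit.synthetic import render_events

FS = 10_000.0
DT = 1.0 / FS


def _events_from_durations(durations, first_state=CLOSED):
    """Alternating event list from a duration sequence."""
    events, t, state = [], 0.0, first_state
    for d in durations:
        events.append(DwellEvent(state, t, d))
        t += d
        state = OPEN if state == CLOSED else CLOSED
    return events


class TestDetectLevels:
    def test_noise_free_two_level_exact(self):
        trace = np.array([0.0] * 500 + [1.0] * 300 + [0.0] * 200)
        fit = pk.detect_levels(trace)
        assert fit.n_levels == 2
        assert fit.baseline_mean == pytest.approx(0.0, abs=1e-12)
        assert fit.open_mean == pytest.approx(1.0, abs=1e-12)
        assert fit.unitary_current == pytest.approx(1.0, abs=1e-12)

    def test_conductance_from_voltage(self):
        trace = np.array([0.0] * 500 + [0.8] * 500)
        fit = pk.detect_levels(trace, voltage=80.0)
        assert fit.conductance == pytest.approx(10.0, rel=1e-9)  # pS

    def test_noisy_unitary_current(self):
        tr = pk.simulate_two_state_trace(50, 25, 30.0, noise_sd=0.1, seed=2)
        assert len(tr.true_events) >= 500
        fit = pk.detect_levels(tr.samples)
        assert fit.unitary_current == pytest.approx(1.0, abs=0.05)

    def test_single_level_reported_not_invented(self):
        rng = np.random.default_rng(0)
        fit = pk.detect_levels(rng.normal(0.0, 0.1, 5000))
        assert fit.n_levels == 1
        assert fit.unitary_current is None


class TestIdealize:
    def test_constant_trace_single_closed_event(self):
        rec = pk.idealize_half_amplitude(np.zeros(1000), FS, 0.0, 1.0, 0.32e-3)
        assert len(rec.events) == 1
        assert rec.events[0].state == CLOSED
        assert rec.events[0].duration == pytest.approx(0.1)

    def test_noise_free_ground_truth_recovered(self):
        rng = np.random.default_rng(4)
        dead = 0.32e-3
        for _ in range(5):
            durs = 2 * dead + rng.exponential(5e-3, size=61)
            events = _events_from_durations(durs)
            trace = render_events(events, FS)
            rec = pk.idealize_half_amplitude(trace, FS, 0.0, 1.0, dead)
            assert len(rec.events) == len(events)
            for i, (got, true) in enumerate(zip(rec.events, events)):
                assert got.state == true.state
                # edge events additionally lose up to half a sample to the
                # rounding of the total record length
                slack = 2 * DT if i in (0, len(events) - 1) else DT
                assert abs(got.duration - true.duration) <= slack + 1e-12

    def test_dead_time_absorbs_short_opening(self):
        # one 0.2 ms opening inside a long closure: 0.32 ms dead time removes
        # the opening and merges its flanking closures (2 fewer events)
        durs = [20e-3, 5e-3, 30e-3, 0.2e-3, 25e-3, 6e-3, 20e-3]
        trace = render_events(_events_from_durations(durs), FS)
        rec0 = pk.idealize_half_amplitude(trace, FS, 0.0, 1.0, dead_time=0.0)
        rec = pk.idealize_half_amplitude(trace, FS, 0.0, 1.0, dead_time=0.32e-3)
        assert len(rec0.events) == 7
        assert len(rec.events) == 5

    def test_dead_time_monotonicity(self):
        tr = pk.simulate_two_state_trace(80, 40, 10.0, noise_sd=0.1, seed=6)
        counts = []
        for dead in (0.0, 0.2e-3, 0.32e-3, 1e-3, 3e-3):
            rec = pk.idealize_half_amplitude(tr.samples, FS, 0.0, 1.0, dead)
            counts.append(len(rec.events))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotent(self):
        tr = pk.simulate_two_state_trace(50, 12.5, 10.0, noise_sd=0.15, seed=8)
        rec = pk.idealize_half_amplitude(tr.samples, FS, 0.0, 1.0, 0.32e-3)
        again = pk.idealize_half_amplitude(rec.reconstruct(), FS, 0.0, 1.0, 0.32e-3)
        assert [(e.state, e.duration) for e in again.events] == \
               [(e.state, e.duration) for e in rec.events]

    def test_subresolution_dead_time_warns(self):
        with pytest.warns(UserWarning, match="sample period"):
            pk.idealize_half_amplitude(np.zeros(100), FS, 0.0, 1.0, dead_time=0.5 * DT)

    def test_equal_levels_rejected(self):
        with pytest.raises(ValueError):
            pk.idealize_half_amplitude(np.zeros(100), FS, 1.0, 1.0)


class TestRatesAndPo:
    def test_edge_events_excluded_and_too_few_rejected(self):
        # interior events: one open, two closed -> not enough open dwells
        durs = [5e-3, 10e-3, 8e-3, 30e-3, 6e-3]
        events = _events_from_durations(durs, first_state=OPEN)
        rec = pk.IdealizedRecord(events, 0.0, sum(durs), 0.5, FS)
        with pytest.raises(ValueError):
            pk.estimate_rates(rec)

    def test_exponential_mle_closed_form(self):
        # interior closed dwells {10, 30} ms -> opening rate exactly 1/0.02 = 50/s
        durs = [5e-3, 8e-3, 10e-3, 6e-3, 30e-3, 7e-3, 9e-3]
        events = _events_from_durations(durs, first_state=CLOSED)
        rec = pk.IdealizedRecord(events, 0.0, sum(durs), 0.5, FS)
        rates = pk.estimate_rates(rec)
        assert rates.opening_rate == pytest.approx(50.0, rel=1e-12)
        assert rates.closing_rate == pytest.approx(1 / np.mean([8e-3, 6e-3, 7e-3]),
                                                   rel=1e-12)
        assert rates.k_eq == pytest.approx(rates.opening_rate / rates.closing_rate,
                                           rel=1e-12)

    def test_recovery_from_simulation(self):
        tr = pk.simulate_two_state_trace(50, 12.5, 110.0, noise_sd=0.15, seed=13)
        rec = pk.idealize_half_amplitude(tr.samples, FS, 0.0, 1.0, 0.32e-3)
        rates = pk.estimate_rates(rec)
        assert rates.n_closed_events >= 900
        assert rates.opening_rate == pytest.approx(50.0, rel=0.10)
        assert rates.closing_rate == pytest.approx(12.5, rel=0.10)

    def test_open_probability_cases(self):
        all_open = pk.IdealizedRecord([DwellEvent(OPEN, 0.0, 1.0)], 0.0, 1.0, 0.5, FS)
        assert pk.open_probability(all_open) == 1.0
        alternating = pk.IdealizedRecord(
            _events_from_durations([0.01] * 10), 0.0, 0.1, 0.5, FS)
        assert pk.open_probability(alternating) == pytest.approx(0.5)

    def test_po_matches_true_open_fraction(self):
        tr = pk.simulate_two_state_trace(50, 12.5, 60.0, noise_sd=0.0,
                                         filter_cutoff=None, seed=14)
        rec = pk.idealize_half_amplitude(tr.samples, FS, 0.0, 1.0, 0.0)
        true_po = sum(e.duration for e in tr.true_events if e.state == OPEN) / 60.0
        n_events = len(tr.true_events)
        assert pk.open_probability(rec) == pytest.approx(true_po,
                                                         abs=n_events * DT / 60.0)


class TestBronsted:
    def test_phi_one_when_closing_rate_constant(self):
        s = pk.simulate_mutant_series(50, 12.5, 1.0, [-0.5, 0, 0.5, 1.0])
        res = pk.fit_bronsted([(m, b / a, b) for m, b, a in s.members])
        assert res.phi == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_phi_zero_when_opening_rate_constant(self):
        s = pk.simulate_mutant_series(50, 12.5, 0.0, [-0.5, 0, 0.5, 1.0])
        res = pk.fit_bronsted([(m, b / a, b) for m, b, a in s.members])
        assert res.phi == pytest.approx(0.0, abs=1e-12)

    def test_exact_series_slope(self):
        s = pk.simulate_mutant_series(50, 12.5, 0.7, [-0.6, -0.3, 0, 0.3])
        res = pk.fit_bronsted([(m, b / a, b) for m, b, a in s.members])
        assert res.phi == pytest.approx(0.700, abs=1e-12)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            pk.fit_bronsted([("a", 1.0, 10.0), ("b", 2.0, 20.0)])
        with pytest.raises(ValueError, match="degenerate"):
            pk.fit_bronsted([("a", 2.0, 10.0), ("b", 2.0, 20.0), ("c", 2.0, 30.0)])
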