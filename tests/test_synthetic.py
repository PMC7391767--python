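"""Generator correctness: ground-truth invariants, moments and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import patchkit as pk
from patchkit.single_channel import CLOSED, OPEN


class TestTwoStateTrace:
    def test_absorbing_closed_state(self):
        tr = pk.simulate_two_state_trace(0.0, 20.0, duration=1.0, noise_sd=0.0,
                                         filter_cutoff=None, seed=0)
        assert len(tr.true_events) == 1
        assert tr.true_events[0].state == CLOSED
        assert tr.true_events[0].duration == pytest.approx(1.0)
        assert np.all(tr.samples == 0.0)

    def test_stationary_occupancy(self):
        # long run: fraction open ~ beta/(alpha+beta) = 0.8, with the
        # Monte-Carlo s.e. taken from block means of the trace itself
        tr = pk.simulate_two_state_trace(50.0, 12.5, duration=200.0,
                                         noise_sd=0.0, filter_cutoff=None, seed=7)
        open_frac = sum(e.duration for e in tr.true_events if e.state == OPEN) / 200.0
        blocks = np.array_split(tr.samples, 20)
        se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(20)
        assert abs(open_frac - 0.8) < 3 * se

    def test_dwell_means_converge(self):
        tr = pk.simulate_two_state_trace(50.0, 12.5, duration=150.0,
                                         noise_sd=0.0, filter_cutoff=None, seed=3)
        closed = [e.duration for e in tr.true_events[1:-1] if e.state == CLOSED]
        opened = [e.duration for e in tr.true_events[1:-1] if e.state == OPEN]
        assert len(closed) + len(opened) >= 2000
        assert np.mean(closed) == pytest.approx(1 / 50.0, rel=0.05)
        assert np.mean(opened) == pytest.approx(1 / 12.5, rel=0.05)

    def test_same_seed_bit_identical(self):
        a = pk.simulate_two_state_trace(50.0, 12.5, 5.0, noise_sd=0.1, seed=42)
        b = pk.simulate_two_state_trace(50.0, 12.5, 5.0, noise_sd=0.1, seed=42)
        assert np.array_equal(a.samples, b.samples)
        assert a.true_events == b.true_events

    def test_sample_count_and_duration_partition(self):
        tr = pk.simulate_two_state_trace(30.0, 30.0, 1.234, sampling_rate=10_000,
                                         seed=5)
        assert tr.samples.size == round(1.234 * 10_000)
        total = sum(e.duration for e in tr.true_events)
        assert total == pytest.approx(1.234, abs=1e-4)

    @pytest.mark.parametrize("kwargs", [
        dict(opening_rate=-1.0, closing_rate=1.0, duration=1.0),
        dict(opening_rate=1.0, closing_rate=-1.0, duration=1.0),
        dict(opening_rate=1.0, closing_rate=1.0, duration=0.0),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pk.simulate_two_state_trace(**kwargs, seed=0)

    @given(beta=st.floats(1.0, 200.0), alpha=st.floats(1.0, 200.0),
           seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_events_alternate_and_partition(self, beta, alpha, seed):
        tr = pk.simulate_two_state_trace(beta, alpha, 2.0, noise_sd=0.0,
                                         filter_cutoff=None, seed=seed)
        states = [e.state for e in tr.true_events]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert tr.true_events[0].state == CLOSED
        assert sum(e.duration for e in tr.true_events) == pytest.approx(2.0, abs=1e-4)


class TestMacroscopicPatch:
    def test_binomial_moments(self):
        x = pk.simulate_macroscopic_patch(100, 0.81, 1.0, 200_000, seed=11)
        true_mean, true_var = 81.0, 100 * 0.81 * 0.19
        se_mean = np.sqrt(true_var / x.size)
        assert abs(x.mean() - true_mean) < 3 * se_mean
        se_var = true_var * np.sqrt(2.0 / x.size)  # rough large-n scale
        assert abs(x.var(ddof=1) - true_var) < 6 * se_var

    def test_deterministic_extremes(self):
        assert np.all(pk.simulate_macroscopic_patch(50, 1.0, 2.0, 100, seed=0) == 100.0)
        assert np.all(pk.simulate_macroscopic_patch(50, 0.0, 2.0, 100, seed=0) == 0.0)

    def test_p_open_validated(self):
        with pytest.raises(ValueError):
            pk.simulate_macroscopic_patch(10, 1.5, 1.0, 10, seed=0)


class TestDoseResponse:
    def test_hill_midpoint_and_saturation(self):
        ds = pk.simulate_dose_response(975.8, 4.263, 1.74,
                                       [185.39981022845954], 0.0, 1, seed=0)
        po_max = 4.263 / 5.263
        # at c = EC50 exactly the noise-free response is Po_max/2
        ec50 = ds.truth["ec50"]
        ds2 = pk.simulate_dose_response(975.8, 4.263, 1.74, [ec50, 1e9], 0.0, 1, seed=0)
        assert ds2.responses[0, 0] == pytest.approx(po_max / 2, rel=1e-12)
        assert ds2.responses[0, 1] == pytest.approx(po_max, rel=1e-6)

    def test_implied_ec50_of_wt_constants(self):
        ds = pk.simulate_dose_response(975.8, 4.263, 1.74, [100.0], seed=0)
        assert ds.truth["ec50"] == pytest.approx(185.4, abs=0.05)

    def test_determinism_and_clipping(self):
        conc = np.geomspace(1, 1000, 8)
        a = pk.simulate_dose_response(100, 1.0, 1.5, conc, 0.3, 5, seed=9)
        b = pk.simulate_dose_response(100, 1.0, 1.5, conc, 0.3, 5, seed=9)
        assert np.array_equal(a.responses, b.responses)
        assert np.all(a.responses >= 0)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError):
            pk.simulate_dose_response(100, 1.0, 1.5, [], seed=0)


class TestMutantSeries:
    def test_phi_one_keeps_closing_rate(self):
        s = pk.simulate_mutant_series(50, 12.5, 1.0, [-0.5, 0, 0.5])
        assert all(a == pytest.approx(12.5) for _, _, a in s.members)

    def test_phi_zero_keeps_opening_rate(self):
        s = pk.simulate_mutant_series(50, 12.5, 0.0, [-0.5, 0, 0.5])
        assert all(b == pytest.approx(50.0) for _, b, _ in s.members)

    def test_exact_collinearity_closed_form_slope(self):
        s = pk.simulate_mutant_series(50, 12.5, 0.7, [-0.6, -0.3, 0, 0.3])
        logk = np.log10([b / a for _, b, a in s.members])
        logb = np.log10([b for _, b, _ in s.members])
        slope = np.polyfit(logk, logb, 1)[0]
        assert slope == pytest.approx(0.700, abs=1e-12)

    def test_phi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.simulate_mutant_series(50, 12.5, 1.2, [0.0])


class TestEmissionSpectrum:
    def test_symmetric_mode_on_grid(self):
        grid = np.arange(420.0, 601.0, 1.0)
        spec = pk.simulate_emission_spectrum(480.3, 18, 0.0, 1000, 50, 0.0, grid)
        assert grid[np.argmax(spec.intensities)] == 480.0

    def test_zero_amplitude_is_flat(self):
        grid = np.arange(420.0, 601.0, 1.0)
        spec = pk.simulate_emission_spectrum(480, 18, 0.3, 0.0, 50, 0.0, grid)
        assert np.allclose(spec.intensities, 50.0)

    def test_skewed_mode_located_at_peak(self):
        # dense evaluation of the generating form: mode must sit at `peak`
        dense = np.arange(400.0, 620.0, 0.01)
        spec = pk.simulate_emission_spectrum(480, 18, 0.3, 1000, 0, 0.0, dense)
        assert dense[np.argmax(spec.intensities)] == pytest.approx(480.0, abs=0.01)

    def test_width_validated(self):
        with pytest.raises(ValueError):
            pk.simulate_emission_spectrum(480, -1, 0.3, 1, 0, 0, [1, 2, 3])
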