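"""Single-channel and macroscopic current-record analysis."""

import numpy as np
import pytest
from scipy import stats

import granchan as gc
from granchan.channel_records import (IVSeries, chord_conductance, compare_groups,
                                      current_change_rate, estimate_channel_count,
                                      fit_exponential_inactivation, fit_linear_iv,
                                      idealize_half_amplitude,
                                      mean_unitary_current, percent_change)


class TestLinearIV:
    def test_bilayer_macroscopic_fit(self):
        # two-point line through (−40.5 mV, 0) and (0, 24.3 pA):
        # 600 pS slope reversing at −40.5 mV
        fit = fit_linear_iv(IVSeries([(-40.5, 0.0), (0.0, 24.3)]))
        assert fit.slope_pS == pytest.approx(600.0)
        assert fit.erev_mV == pytest.approx(-40.5)

    def test_exact_on_collinear_data(self, rng):
        v = np.linspace(-70, 70, 15)
        g, erev = 0.11, -49.0   # nS, mV
        fit = fit_linear_iv(IVSeries(list(zip(v, g * (v - erev)))))
        assert fit.slope_pS == pytest.approx(110.0, rel=1e-9)
        assert fit.erev_mV == pytest.approx(-49.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_voltage_shift_equivariance(self, rng):
        v = np.linspace(-60, 60, 9)
        i = 0.2 * (v + 20) + rng.normal(0, 0.5, v.size)
        base = fit_linear_iv(IVSeries(list(zip(v, i))))
        shifted = fit_linear_iv(IVSeries(list(zip(v + 15, i))))
        assert shifted.slope_pS == pytest.approx(base.slope_pS, rel=1e-9)
        assert shifted.erev_mV == pytest.approx(base.erev_mV + 15, rel=1e-6)

    def test_horizontal_series_has_no_reversal(self):
        with pytest.raises(ValueError, match="reversal"):
            fit_linear_iv(IVSeries([(-40.0, 5.0), (0.0, 5.0), (40.0, 5.0)]))

    def test_chord_conductance_of_the_bilayer_record(self):
        # 24.3 pA driven by 40.5 mV from reversal
        assert chord_conductance(24.3, 0.0, -40.5) == pytest.approx(600.0)


class TestIdealization:
    def test_noiseless_square_wave_recovers_exact_transitions(self):
        x = np.zeros(1000)
        x[100:300] = 5.4
        x[600:900] = 5.4
        segs = idealize_half_amplitude(x, amplitude_pA=5.4, baseline_pA=0.0)
        assert [(s.level, s.start, s.n_samples) for s in segs] == [
            (0, 0, 100), (1, 100, 200), (0, 300, 300), (1, 600, 300), (0, 900, 100)]

    def test_all_closed_trace_is_one_segment(self):
        segs = idealize_half_amplitude(np.zeros(500), amplitude_pA=5.4,
                                       baseline_pA=0.0)
        assert len(segs) == 1 and segs[0].level == 0 and segs[0].n_samples == 500

    def test_brief_crossings_are_merged(self):
        x = np.zeros(100)
        x[50] = 10.0            # single-sample glitch
        segs = idealize_half_amplitude(x, amplitude_pA=5.4, baseline_pA=0.0,
                                       min_dwell_samples=2)
        assert len(segs) == 1 and segs[0].level == 0

    def test_state_accuracy_at_snr5_vs_generator_truth(self):
        params = gc.ChannelSimParams(noise_sd_pA=5.39 / 5, seed=1,
                                     voltage_protocol=((0.0, 20.0),))
        trace, n_open = gc.make_channel_trace(params)
        segs = idealize_half_amplitude(trace.samples_pA, amplitude_pA=5.39,
                                       baseline_pA=0.0)
        state = np.zeros(trace.samples_pA.size, dtype=int)
        for s in segs:
            state[s.start:s.start + s.n_samples] = s.level
        assert (state == np.clip(n_open, 0, 1)).mean() >= 0.99

    def test_min_dwell_below_one_rejected(self):
        with pytest.raises(ValueError):
            idealize_half_amplitude(np.zeros(10), amplitude_pA=1.0,
                                    baseline_pA=0.0, min_dwell_samples=0)


class TestUnitaryCurrent:
    def test_alternating_noiseless_levels(self):
        x = np.tile([0.0] * 10 + [5.4] * 10, 20)
        segs = idealize_half_amplitude(x, amplitude_pA=5.4, baseline_pA=0.0)
        est = mean_unitary_current(x, segs)
        assert est.mean_i_pA == pytest.approx(5.4)
        assert est.n_events == 20

    def test_baseline_offset_invariance(self):
        x = np.tile([0.0] * 10 + [5.4] * 10, 20)
        segs = idealize_half_amplitude(x, amplitude_pA=5.4, baseline_pA=0.0)
        est0 = mean_unitary_current(x, segs)
        est1 = mean_unitary_current(x + 17.0, segs)
        assert est1.mean_i_pA == pytest.approx(est0.mean_i_pA)

    def test_recovery_of_generator_amplitude(self):
        i_true = 10.2
        params = gc.ChannelSimParams(unitary_conductance_pS=196.0,
                                     reversal_mV=-10.2 / 0.196, seed=1,
                                     noise_sd_pA=i_true / 5,
                                     voltage_protocol=((0.0, 20.0),))
        trace, _ = gc.make_channel_trace(params)
        segs = idealize_half_amplitude(trace.samples_pA, amplitude_pA=i_true,
                                       baseline_pA=0.0)
        est = mean_unitary_current(trace.samples_pA, segs)
        se = est.sd_pA / np.sqrt(est.n_events)
        assert abs(est.mean_i_pA - i_true) < max(2 * se, 0.05)

    def test_low_bias_across_many_seeded_traces(self):
        # the idealize -> estimate chain should recover the generator
        # amplitude with < 2% bias at SNR 5
        i_true, ests = 5.39, []
        for seed in range(40):
            params = gc.ChannelSimParams(noise_sd_pA=i_true / 5, seed=seed,
                                         voltage_protocol=((0.0, 6.0),))
            trace, _ = gc.make_channel_trace(params)
            segs = idealize_half_amplitude(trace.samples_pA, amplitude_pA=i_true,
                                           baseline_pA=0.0)
            open_present = any(s.level == 1 for s in segs)
            if open_present:
                ests.append(mean_unitary_current(trace.samples_pA, segs).mean_i_pA)
        assert abs(np.mean(ests) - i_true) / i_true < 0.02

    def test_no_openings_raises(self):
        segs = idealize_half_amplitude(np.zeros(100), amplitude_pA=5.0,
                                       baseline_pA=0.0)
        with pytest.raises(ValueError, match="opening"):
            mean_unitary_current(np.zeros(100), segs)


class TestChannelCountAndPercent:
    def test_bilayer_channel_count(self):
        # ~600 pS chord conductance with ~110 pS unitary channels
        assert estimate_channel_count(600.0, 110.0) == 5

    @pytest.mark.parametrize("macro,unit,n", [(0.0, 110.0, 0), (280.0, 140.0, 2)])
    def test_simple_counts(self, macro, unit, n):
        assert estimate_channel_count(macro, unit) == n

    def test_integer_multiples_recovered_exactly(self):
        for k in range(0, 12):
            assert estimate_channel_count(k * 137.0, 137.0) == k

    def test_nonpositive_unitary_rejected(self):
        with pytest.raises(ValueError):
            estimate_channel_count(600.0, 0.0)

    def test_unitary_current_increase_on_cis_chloride_addition(self):
        # 5.4 -> 10.2 pA is an 89% increase
        assert percent_change(5.4, 10.2) == pytest.approx(88.9, abs=0.1)
        assert round(percent_change(5.4, 10.2)) == 89

    def test_further_increase_on_trans_bromide(self):
        assert percent_change(10.2, 13.4) == pytest.approx(31.4, abs=0.05)

    def test_no_change_is_zero_percent(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_round_trip(self, rng):
        for _ in range(25):
            before, after = rng.uniform(-50, 50, 2)
            if before == 0:
                continue
            pct = percent_change(before, after)
            assert before * (1 + pct / 100.0) == pytest.approx(after, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestInactivation:
    def test_exact_exponential_recovered(self):
        t = np.linspace(0, 10, 500)
        i = 40.0 * np.exp(-t / 2.0) + 3.0
        fit = fit_exponential_inactivation(t, i)
        assert fit.tau_s == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude_pA == pytest.approx(40.0, rel=1e-6)
        assert not fit.flagged

    def test_generator_ensemble_recovery_within_10_percent(self):
        params = gc.ChannelSimParams(n_channels=200, open_rate=50.0,
                                     close_rate=1.0, tau_inact_s=2.0,
                                     noise_sd_pA=0.5, sample_interval_s=2e-3,
                                     voltage_protocol=((80.0, 8.0),), seed=1)
        trace, _ = gc.make_channel_trace(params)
        fit = fit_exponential_inactivation(trace.t_s, trace.samples_pA)
        assert fit.tau_s == pytest.approx(2.0, rel=0.10)

    def test_constant_sweep_is_flagged_not_raised(self):
        t = np.linspace(0, 5, 100)
        fit = fit_exponential_inactivation(t, np.full(100, 7.0))
        assert fit.flagged

    def test_window_outside_sweep_rejected(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(ValueError, match="window"):
            fit_exponential_inactivation(t, t, fit_window=(0, 6))


class TestMacroscopicSweeps:
    def test_no_inactivation_means_no_decay(self):
        params = gc.ChannelSimParams(n_channels=100, open_rate=0.0, close_rate=0.0,
                                     start_open=True, noise_sd_pA=0.0,
                                     tau_inact_s=None, sample_interval_s=5e-3,
                                     voltage_protocol=((80.0, 5.0), (40.0, 5.0)))
        sweeps = gc.make_macroscopic_sweeps(params)
        assert len(sweeps) == 2
        for trace, _ in sweeps:
            assert np.ptp(trace.samples_pA) == pytest.approx(0.0, abs=1e-9)

    def test_slow_inactivation_recovered_per_sweep(self):
        params = gc.ChannelSimParams(n_channels=300, open_rate=1e4, close_rate=0.0,
                                     noise_sd_pA=0.2, tau_inact_s=2.0,
                                     sample_interval_s=4e-3,
                                     voltage_protocol=((80.0, 8.0),), seed=1)
        (trace, _), = gc.make_macroscopic_sweeps(params)
        fit = fit_exponential_inactivation(trace.t_s, trace.samples_pA)
        assert fit.tau_s == pytest.approx(2.0, rel=0.10)


class TestWholeCellRates:
    def test_constant_series_has_zero_rate(self):
        pts = [(t, 100.0) for t in range(10)]
        assert current_change_rate(pts) == pytest.approx(0.0)

    def test_exact_ramp(self):
        pts = [(t, 12.0 * t + 3.0) for t in range(10)]
        assert current_change_rate(pts) == pytest.approx(12.0)

    def test_secretion_staircase_matches_compound_poisson_expectation(self):
        p = gc.SecretionSimParams()
        expected = (p.pulse_rate_hz * p.fusion_rate_per_pulse
                    * p.conductance_per_event_nS * (80.0 - p.erev_mV))
        rates = []
        for seed in range(12):
            sess = gc.make_whole_cell_session(gc.SecretionSimParams(seed=seed))
            rates.append(current_change_rate(sess[["t_s", "i_plus80_pA"]].to_numpy()))
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert rates.mean() > 0
        assert abs(rates.mean() - expected) < 3 * se


class TestGroupComparison:
    def test_identical_samples(self):
        t, p, p_adj = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p, p_adj) == (0.0, 1.0, 1.0)

    def test_matches_closed_form_welch_on_two_point_samples(self):
        a, b = [1.0, 2.0], [4.0, 6.0]
        t, p, _ = compare_groups(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 2, np.var(b, ddof=1) / 2
        t_hand = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 + vb ** 2)   # Welch-Satterthwaite, n=2
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_power_on_one_sigma_shift(self, rng):
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(1.0, 1.0, 50)
        _, p, _ = compare_groups(a, b)
        assert p < 0.05

    def test_bonferroni_caps_at_one(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        _, p, p_adj = compare_groups(a, b, n_comparisons=50)
        assert p_adj == min(1.0, p * 50)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
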