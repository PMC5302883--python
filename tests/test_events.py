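"""Single-photon response estimation, event detection, and Poisson rate analysis."""

import math

import numpy as np
import pytest

import pigmentnoise as pn
from pigmentnoise.errors import DataError, DegenerateSignalError, DomainError


class TestSinglePhotonResponse:
    def test_identical_trials_are_degenerate(self, spr_template):
        trial = pn.CurrentTrace(np.tile(spr_template.waveform, 1), 1000.0)
        ens = pn.FlashEnsemble(trials=[trial, trial, trial])
        spr = pn.single_photon_response(ens)
        assert spr.degenerate
        assert spr.amplitude == 0.0

    def test_amplitude_recovered_from_poisson_capture(self, spr_template):
        """Var/Mean at the peak recovers the quantal amplitude for Poisson
        photon counts (mean ~1 per flash), within 3 SE over 150 trials."""
        n_trials = 150
        ens = pn.simulate_flash_ensemble(
            A_e=0.5, I=2.0, n_trials=n_trials, spr=spr_template, noise_sd=0.02, seed=7
        )
        spr = pn.single_photon_response(ens)
        # Var(Var/Mean) ~ a^2 * (2 + 1/lam) / n  for Poisson(lam) peak counts
        lam = 1.0
        se = 1.0 * math.sqrt((2 + 1 / lam) / n_trials)
        assert abs(spr.amplitude - spr_template.amplitude) < 3 * se

    def test_amplitude_scales_linearly(self, spr_template):
        ens = pn.simulate_flash_ensemble(
            A_e=0.5, I=2.0, n_trials=60, spr=spr_template, noise_sd=0.02, seed=3
        )
        doubled = pn.FlashEnsemble(
            trials=[
                pn.CurrentTrace(2 * t.samples, t.sampling_rate, t.filter_cutoff)
                for t in ens.trials
            ],
            flash_intensity=ens.flash_intensity,
            flash_time=ens.flash_time,
        )
        a1 = pn.single_photon_response(ens).amplitude
        a2 = pn.single_photon_response(doubled).amplitude
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(DataError):
            pn.FlashEnsemble(trials=[])


class TestIntegrationTime:
    def test_rectangular_pulse(self):
        fs = 1000.0
        w = np.zeros(3000)
        w[1000:2000] = 2.5  # 1-s pulse
        assert pn.integration_time(w, fs) == pytest.approx(1.0, rel=1e-2)

    def test_decaying_exponential(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        tau = 0.7
        w = 3.0 * np.exp(-t / tau)
        assert pn.integration_time(w, fs) == pytest.approx(tau, rel=1e-3)

    def test_template_matches_trapezoid_oracle(self, spr_template):
        oracle = np.trapezoid(spr_template.waveform, dx=1e-3) / spr_template.waveform.max()
        assert pn.integration_time(spr_template.waveform, 1000.0) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_all_zero_waveform_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pn.integration_time(np.zeros(100), 1000.0)


class TestDetectEvents:
    def test_noise_only_trace_yields_no_events(self, spr_template):
        cfg = pn.TraceSimConfig(duration=300.0, event_rate=0.0, seed=11)
        trace, _ = pn.simulate_dark_trace(cfg)
        events = pn.detect_events(trace, spr_template)
        assert len(events) == 0

    def test_small_events_rejected_full_events_kept(self, spr_template):
        """5 full-amplitude events pass; 2 events at 20% amplitude fail the
        30% criterion."""
        fs = 1000.0
        n = int(200 * fs)
        clean = np.zeros(n)
        rng = np.random.default_rng(0)
        full_times = [20.0, 55.0, 90.0, 125.0, 160.0]
        small_times = [37.0, 180.0]
        tpl = spr_template.waveform
        for t0 in full_times:
            i = int(t0 * fs)
            clean[i : i + tpl.size] += tpl
        for t0 in small_times:
            i = int(t0 * fs)
            clean[i : i + tpl.size] += 0.2 * tpl
        noisy = clean + rng.normal(0, 0.5, n)
        from pigmentnoise.filtering import lowpass_zero_phase

        trace = pn.CurrentTrace(lowpass_zero_phase(noisy, fs, 20.0), fs)
        events = pn.detect_events(trace, spr_template)
        assert len(events) == 5
        assert np.allclose(
            np.sort(events.times), np.array(full_times) + spr_template.peak_time, atol=0.3
        )

    def test_slow_drift_rejected_by_kinetics(self, spr_template):
        """A deflection with 3x the dim-flash integration time fails the
        50-200% kinetics window even though it passes the amplitude test."""
        fs = 1000.0
        n = int(120 * fs)
        clean = np.zeros(n)
        ti = spr_template.integration_time
        # half-sine bump with integration time 3x the template's
        width = 3.0 * ti * math.pi / 2.0
        i0 = int(40 * fs)
        k = np.arange(int(width * fs))
        clean[i0 : i0 + k.size] += 1.0 * np.sin(math.pi * k / k.size)
        trace = pn.CurrentTrace(clean, fs)
        events = pn.detect_events(trace, spr_template)
        assert len(events) == 0

    def test_degenerate_spr_rejected(self, spr_template):
        bad = pn.SinglePhotonResponse(
            waveform=spr_template.waveform,
            sampling_rate=1000.0,
            amplitude=0.0,
            integration_time=spr_template.integration_time,
            degenerate=True,
        )
        cfg = pn.TraceSimConfig(duration=60.0, event_rate=0.0, seed=1)
        trace, _ = pn.simulate_dark_trace(cfg)
        with pytest.raises(DegenerateSignalError):
            pn.detect_events(trace, bad)

    def test_recovers_simulated_events(self, spr_template, dark_trace_with_truth):
        trace, truth = dark_trace_with_truth
        events = pn.detect_events(trace, spr_template)
        assert abs(len(events) - len(truth)) <= 1


class TestCountingRate:
    def test_zero_events(self):
        ev = pn.EventList(np.array([]), np.array([]), np.array([]), 600.0)
        assert pn.counting_rate(ev).rate == 0.0

    def test_nine_events_in_600s(self):
        times = np.linspace(10, 590, 9)
        ev = pn.EventList(times, np.ones(9), np.ones(9), 600.0)
        assert pn.counting_rate(ev).rate == pytest.approx(0.015, rel=1e-12)


class TestEpochCounts:
    def test_600s_gives_six_epochs(self):
        ev = pn.EventList(np.array([]), np.array([]), np.array([]), 600.0)
        counts = pn.epoch_counts(ev, epoch_length=100.0)
        assert counts.n_epochs == 6

    def test_events_assigned_to_epochs(self):
        ev = pn.EventList(
            np.array([50.0, 150.0]), np.ones(2), np.ones(2), 600.0
        )
        counts = pn.epoch_counts(ev, epoch_length=100.0)
        assert counts.counts.tolist() == [1, 1, 0, 0, 0, 0]

    def test_partial_trailing_epoch_discarded(self):
        ev = pn.EventList(np.array([420.0]), np.ones(1), np.ones(1), 450.0)
        counts = pn.epoch_counts(ev, epoch_length=100.0)
        assert counts.n_epochs == 4
        assert counts.counts.sum() == 0  # event in the discarded tail

    def test_conserves_events_in_covered_epochs(self, spr_template, dark_trace_with_truth):
        trace, truth = dark_trace_with_truth
        events = pn.detect_events(trace, spr_template)
        counts = pn.epoch_counts(events, epoch_length=100.0)
        covered = events.times < counts.n_epochs * 100.0
        assert counts.counts.sum() == covered.sum()


class TestPoissonFit:
    def test_all_zero_counts(self):
        counts = pn.EpochCounts(100.0, np.zeros(5, dtype=int))
        w, rate = pn.poisson_fit(counts)
        assert w == 0.0 and rate == 0.0

    def test_unit_counts(self):
        counts = pn.EpochCounts(100.0, np.array([1, 1, 1]))
        w, rate = pn.poisson_fit(counts)
        assert w == 1.0
        assert rate == pytest.approx(0.01)

    def test_mle_equals_sample_mean(self):
        rng = np.random.default_rng(5)
        draws = rng.poisson(0.8, size=200)
        counts = pn.EpochCounts(100.0, draws)
        w, _ = pn.poisson_fit(counts)
        assert w == pytest.approx(draws.mean(), rel=1e-14)

    def test_bias_vanishes_with_many_epochs(self):
        rng = np.random.default_rng(8)
        w_true = 0.23
        ws = []
        for _ in range(50):
            counts = pn.EpochCounts(100.0, rng.poisson(w_true, size=500))
            ws.append(pn.poisson_fit(counts)[0])
        se = math.sqrt(w_true / 500) / math.sqrt(50)
        assert abs(np.mean(ws) - w_true) < 3 * se


class TestPoissonPmf:
    def test_zero_zero(self):
        assert pn.poisson_pmf(0, 0.0) == 1.0

    def test_direct_formula(self):
        assert pn.poisson_pmf(1, 0.23) == pytest.approx(0.23 * math.exp(-0.23), rel=1e-12)

    def test_normalization(self):
        w = 2.7
        total = sum(pn.poisson_pmf(u, w) for u in range(10 + int(10 * w)))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestCollectingArea:
    def test_zero_probability(self):
        assert pn.collecting_area(0.0, 5.0) == 0.0

    def test_analytic_point(self):
        assert pn.collecting_area(1 - math.exp(-1), 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_with_success_probability(self):
        for A_e, I in [(0.44, 2.0), (0.35, 5.0), (1.2, 0.3)]:
            p = pn.success_probability(A_e, I)
            assert pn.collecting_area(p, I) == pytest.approx(A_e, rel=1e-12)

    def test_saturated_probability_rejected(self):
        with pytest.raises(DomainError):
            pn.collecting_area(1.0, 1.0)

    def test_monte_carlo_recovery_within_binomial_ci(self):
        """A_e recovered from simulated trial successes within the 95% CI."""
        A_e, I, n_trials = 0.44, 2.0, 400
        rng = np.random.default_rng(12)
        successes = (rng.poisson(A_e * I, size=n_trials) > 0).mean()
        p_true = pn.success_probability(A_e, I)
        se = math.sqrt(p_true * (1 - p_true) / n_trials)
        est = pn.collecting_area(successes, I)
        # propagate the binomial CI through the (monotone) inverse
        lo = pn.collecting_area(max(p_true - 2 * se, 0.0), I)
        hi = pn.collecting_area(min(p_true + 2 * se, 0.999), I)
        assert lo <= est <= hi
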