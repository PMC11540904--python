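"""Event detection, summaries and comparisons: unit and recovery tests."""

import numpy as np
import pytest

from flimfret import events as ev
from flimfret import imaging
from flimfret import synthetic_data as synth
from flimfret.decay_model import DomainError
from flimfret.imaging import ROITrace


def _trace(values, dt=0.128):
    return ROITrace(times_s=np.arange(len(values)) * dt, value=np.asarray(values, float))


def _noise_trace(rng, n=2000, sd=1.0, dt=0.128):
    return _trace(rng.normal(0.0, sd, n), dt)


class TestDetrend:
    def test_pure_ramp_flattened(self):
        t = np.arange(500) * 0.128
        tr = ROITrace(times_s=t, value=0.001 * t)
        out, slope, intercept = ev.detrend_linear(tr, 300)
        assert slope == pytest.approx(0.001, abs=1e-12)
        assert np.abs(out.value).max() < 1e-12

    def test_flat_trace_unchanged(self):
        tr = _trace(np.full(300, 1.5))
        out, slope, _ = ev.detrend_linear(tr, 200)
        assert abs(slope) < 1e-12
        np.testing.assert_allclose(out.value, 0.0, atol=1e-12)

    def test_too_few_baseline_samples(self):
        tr = _trace(np.zeros(100))
        with pytest.raises(DomainError):
            ev.detrend_linear(tr, 2)


class TestDetectCaEvents:
    def test_quiet_trace_no_events(self, rng):
        tr = _noise_trace(rng, sd=0.01)
        calls = ev.detect_ca_events(tr, baseline_window=500)
        # pure noise yields only rare single-frame crossings
        assert len(calls) < 10

    def test_injected_transient_called_once_at_right_time(self, rng):
        v = rng.normal(0, 1.0, 2000)
        peak_idx = 1200
        v[peak_idx : peak_idx + 20] += 10.0 * np.exp(-np.arange(20) / 10.0)
        tr = _trace(v)
        calls = [c for c in ev.detect_ca_events(tr, baseline_window=800, min_separation_s=2.0, min_width_s=0.5)]
        assert len(calls) == 1
        assert abs(calls[0].peak_s - peak_idx * 0.128) <= 0.128

    def test_detection_invariant_to_linear_drift(self, rng):
        v = rng.normal(0, 1.0, 3000)
        v[2000:2015] += 12.0
        t = np.arange(3000) * 0.128
        base = ev.detect_ca_events(_trace(v), baseline_window=1000)
        drift = ev.detect_ca_events(
            ROITrace(times_s=t, value=v + 0.004 * t + 3.0), baseline_window=1000
        )
        assert len(base) == len(drift)
        assert [c.onset_s for c in base] == [c.onset_s for c in drift]

    def test_degenerate_noise_rejected(self):
        with pytest.raises(DomainError, match="SD"):
            ev.detect_ca_events(_trace(np.zeros(2000)), baseline_window=500)

    def test_false_positive_rate_matches_independent_oracle(self, rng):
        """3-SD excursion rate on pure noise vs a brute-force re-count."""

        def oracle_count(values, threshold, min_sep_frames):
            # independent, loop-based implementation of threshold + merge
            above = values > threshold
            events = 0
            last_end = None
            i = 0
            n = len(values)
            while i < n:
                if above[i]:
                    j = i
                    while j < n and above[j]:
                        j += 1
                    if last_end is not None and (i - last_end) < min_sep_frames:
                        pass  # merged into previous event
                    else:
                        events += 1
                    last_end = j
                    i = j
                else:
                    i += 1
            return events

        n_frames, dt = 2000, 0.128
        ours, oracle = [], []
        for rep in range(50):
            v = rng.normal(0, 1.0, n_frames)
            tr = _trace(v, dt)
            calls = ev.detect_ca_events(tr, baseline_window=n_frames, min_separation_s=2.0)
            detr, _, _ = ev.detrend_linear(tr, n_frames)
            sd = detr.value.std(ddof=1)
            ours.append(len(calls))
            oracle.append(oracle_count(detr.value, 3.0 * sd, int(round(2.0 / dt))))
        diff = np.mean(ours) - np.mean(oracle)
        se = np.std(np.array(ours) - np.array(oracle), ddof=1) / np.sqrt(50) + 1e-12
        assert abs(diff) <= max(2 * se, 0.05)


class TestDetectCamkiiEvents:
    def _cohort_trace(self, onset_s=35.0, amp=0.03, seed=0):
        cfg = synth.ScenarioConfig()
        rng = np.random.default_rng(seed)
        trace, truth = synth._lifetime_trace(rng, cfg, "r0", True, [onset_s])
        return cfg, trace, truth

    def test_onset_recovered_within_two_seconds(self):
        cfg, trace, truth = self._cohort_trace()
        calls = ev.detect_camkii_events(trace, protocol_time_s=cfg.pre_duration_s)
        delayed = [c for c in calls if c.onset_s >= cfg.pre_duration_s]
        assert len(delayed) == 1
        got = delayed[0].onset_s - cfg.pre_duration_s
        assert abs(got - truth.events[0].onset_s) < 2.5

    def test_amplitude_floor_suppresses_small_events(self):
        cfg = synth.ScenarioConfig(event_amplitude_ns=0.004, event_amplitude_shape=400.0)
        rng = np.random.default_rng(1)
        trace, _ = synth._lifetime_trace(rng, cfg, "r0", True, [40.0])
        calls = ev.detect_camkii_events(trace, protocol_time_s=cfg.pre_duration_s)
        assert not [c for c in calls if c.onset_s >= cfg.pre_duration_s]

    def test_cohort_responder_fraction_recovered(self):
        cfg = synth.ScenarioConfig(n_recordings=200)
        traces, truth = synth.simulate_ddsc_cohort(cfg, seed=21)
        detected = 0
        for tr in traces:
            calls = ev.detect_camkii_events(tr, protocol_time_s=cfg.pre_duration_s)
            detected += any(c.onset_s >= cfg.pre_duration_s for c in calls)
        frac = detected / len(traces)
        se = np.sqrt(truth.responder_fraction * (1 - truth.responder_fraction) / 200)
        assert abs(frac - truth.responder_fraction) <= 2 * se

    def test_amplitude_recovery_mean_bias_small(self):
        cfg = synth.ScenarioConfig(n_recordings=120)
        traces, truth = synth.simulate_ddsc_cohort(cfg, seed=22)
        pairs = []
        for tr, rec in zip(traces, truth.records):
            if not rec.events:
                continue
            calls = [
                c for c in ev.detect_camkii_events(tr, protocol_time_s=cfg.pre_duration_s)
                if c.onset_s >= cfg.pre_duration_s
            ]
            if calls:
                pairs.append((calls[0].amplitude, rec.events[0].amplitude))
        got, want = map(np.array, zip(*pairs))
        assert abs(got.mean() / want.mean() - 1.0) < 0.10


class TestTriggeredAverage:
    def test_single_pulse_alignment(self):
        v = np.zeros(200)
        v[100] = 1.0
        tr = _trace(v, dt=0.1)
        avg = ev.event_triggered_average([10.0], tr, window_s=(-0.5, 0.5))
        assert avg.n_used == 1
        assert avg.mean[np.argmin(np.abs(avg.lags_s))] == 1.0

    def test_constant_trace_constant_average(self):
        tr = _trace(np.full(300, 2.2), dt=0.1)
        avg = ev.event_triggered_average([10.0, 20.0], tr, window_s=(-1, 1))
        np.testing.assert_allclose(avg.mean, 2.2)

    def test_template_recovered_from_jittered_noisy_copies(self, rng):
        dt = 0.1
        n = 30000
        v = rng.normal(0, 0.05, n)
        template = np.exp(-np.arange(0, 30) * dt / 1.0)
        peaks = []
        for k in range(100):
            i = 200 + k * 290 + rng.integers(-3, 4)
            v[i : i + 30] += template
            peaks.append(i * dt)
        tr = _trace(v, dt)
        avg = ev.event_triggered_average(peaks, tr, window_s=(-2, 2))
        assert avg.n_used == 100
        lag0 = np.argmin(np.abs(avg.lags_s))
        se = avg.segments[:, lag0].std(ddof=1) / 10.0
        # jitter of +-0.3 s smears the peak; mean at lag 0 stays near template top
        assert avg.mean[lag0] > 0.75
        assert avg.mean[lag0] == pytest.approx(avg.segments[:, lag0].mean(), abs=3 * se)

    def test_partial_windows_dropped_and_counted(self):
        tr = _trace(np.zeros(100), dt=0.1)
        avg = ev.event_triggered_average([0.2, 5.0], tr, window_s=(-1, 1))
        assert avg.n_used == 1 and avg.n_dropped == 1

    def test_no_usable_events_explicit_empty(self):
        tr = _trace(np.zeros(50), dt=0.1)
        avg = ev.event_triggered_average([0.0], tr, window_s=(-10, 10))
        assert avg.empty


class TestCooccurrence:
    def test_silent_kinase_trace_gives_zero(self):
        tr = _trace(np.zeros(2000))
        frac, flags = ev.cooccurrence([50.0, 100.0], tr)
        assert frac == 0.0 and not flags.any()

    def test_fully_coupled_gives_one(self):
        v = np.zeros(2000)
        for p in (500, 1000, 1500):
            v[p : p + 50] = 0.03
        tr = _trace(v)
        frac, _ = ev.cooccurrence([p * 0.128 for p in (500, 1000, 1500)], tr)
        assert frac == 1.0

    def test_zero_events_error(self):
        with pytest.raises(DomainError):
            ev.cooccurrence([], _trace(np.zeros(100)))

    def test_coupling_fraction_round_trip(self):
        flags_all = []
        for s in range(25):
            sim = synth.simulate_ca_ephys(synth.ScenarioConfig(), seed=3000 + s)
            ca = imaging.ca_ratio(sim.ca_channel, sim.structural_channel, times_s=sim.times_s)
            pend = sim.protocol_time_s + synth.ScenarioConfig().protocol.duration_s
            calls = ev.detect_ca_events(
                ca, baseline_window=(0.0, sim.protocol_time_s), min_separation_s=2.0, min_width_s=0.5
            )
            post = [c for c in calls if c.onset_s >= pend]
            if not post:
                continue
            proc = imaging.smooth_trace(imaging.normalize_trace(sim.camkii_trace), 60)
            detr, _, _ = ev.detrend_linear(proc, (0.0, sim.protocol_time_s))
            _, flags = ev.cooccurrence(post, detr)
            flags_all.extend(flags)
        frac = np.mean(flags_all)
        se = np.sqrt(0.57 * 0.43 / len(flags_all))
        assert abs(frac - 0.57) <= 2.5 * se


class TestOnsetSummary:
    def _mk(self, onsets, rec_ids=None):
        rec_ids = rec_ids or [f"r{i}" for i in range(len(onsets))]
        return [
            ev.EventCall(onset_s=o, peak_s=o + 1, amplitude=0.02, width_s=2.0, channel="camkii", recording_id=r)
            for o, r in zip(onsets, rec_ids)
        ]

    def test_point_mass_single_bin(self):
        s = ev.onset_summary(self._mk([35.0] * 7), n_recordings=10)
        assert s.counts.sum() == 7
        assert s.mode_bin == (30.0, 40.0)
        assert np.count_nonzero(s.counts) == 1
        assert s.responder_fraction == 0.7

    def test_empty_condition_zero_histogram(self):
        s = ev.onset_summary([], n_recordings=5)
        assert s.counts.sum() == 0 and s.n_events == 0
        assert s.cumulative_counts.size == 0

    def test_overflow_conservation(self):
        s = ev.onset_summary(self._mk([5.0, 35.0, 150.0]), n_recordings=3)
        assert s.counts.sum() == 2 and s.overflow == 1
        assert s.counts.sum() + s.overflow == s.n_events

    def test_first_event_only_default(self):
        calls = self._mk([20.0, 60.0], rec_ids=["a", "a"])
        s = ev.onset_summary(calls, n_recordings=1)
        assert s.n_events == 1
        s_all = ev.onset_summary(calls, n_recordings=1, first_event_only=False)
        assert s_all.n_events == 2

    def test_default_cohort_mode_bin(self):
        cfg = synth.ScenarioConfig(n_recordings=250)
        traces, _ = synth.simulate_ddsc_cohort(cfg, seed=31)
        calls = []
        for tr in traces:
            for c in ev.detect_camkii_events(tr, protocol_time_s=cfg.pre_duration_s):
                if c.onset_s >= cfg.pre_duration_s:
                    calls.append(
                        ev.EventCall(
                            onset_s=c.onset_s - cfg.pre_duration_s,
                            peak_s=c.peak_s - cfg.pre_duration_s,
                            amplitude=c.amplitude, width_s=c.width_s,
                            channel=c.channel, recording_id=c.recording_id,
                        )
                    )
        s = ev.onset_summary(calls, n_recordings=len(traces))
        assert s.mode_bin == (30.0, 40.0)


class TestAucWindow:
    def test_constant_trace_area(self):
        tr = ROITrace(times_s=np.linspace(0, 60, 601), value=np.full(601, 0.02))
        assert ev.auc_window(tr, (30, 40)) == pytest.approx(0.2, rel=1e-9)

    def test_zero_trace(self):
        tr = ROITrace(times_s=np.linspace(0, 60, 601), value=np.zeros(601))
        assert ev.auc_window(tr, (30, 40)) == 0.0

    def test_window_outside_span_rejected(self):
        tr = ROITrace(times_s=np.linspace(0, 20, 201), value=np.zeros(201))
        with pytest.raises(DomainError):
            ev.auc_window(tr, (30, 40))

    def test_stimulated_cohort_auc_exceeds_control(self):
        wins = 0
        for rep in range(20):
            cfg = synth.ScenarioConfig(n_recordings=15)
            stim_traces, _ = synth.simulate_ddsc_cohort(cfg, seed=5000 + rep)
            ctrl_traces, _ = synth.simulate_ddsc_cohort(cfg, condition="control", seed=6000 + rep)

            def mean_auc(traces):
                vals = []
                for tr in traces:
                    proc = imaging.smooth_trace(imaging.normalize_trace(tr, 100), 60)
                    vals.append(
                        ev.auc_window(proc, (cfg.pre_duration_s + 30, cfg.pre_duration_s + 40))
                    )
                return np.mean(vals)

            wins += mean_auc(stim_traces) > mean_auc(ctrl_traces)
        assert wins >= 19


class TestCompartmentComparison:
    def _paired(self, dend_onsets, soma_onsets, seed=0, soma_factor=1.0):
        # near-deterministic amplitudes so the synthesized compartment ratio
        # is exactly soma_factor
        cfg = synth.ScenarioConfig(event_amplitude_ns=0.04, event_amplitude_shape=1e6)
        rng = np.random.default_rng(seed)
        d, td = synth._lifetime_trace(rng, cfg, "d0", bool(dend_onsets), list(dend_onsets))
        s, ts = synth._lifetime_trace(
            rng, cfg, "s0", bool(soma_onsets), list(soma_onsets),
            compartment="soma", amplitude_factor=soma_factor,
        )
        return cfg, d, s

    def test_dendrite_only(self):
        cfg, d, s = self._paired([35.0], [])
        cls, _, _ = ev.compartment_comparison(d, s, protocol_time_s=cfg.pre_duration_s)
        assert cls == "dendrite_only"

    def test_neither(self):
        cfg, d, s = self._paired([], [])
        cls, _, _ = ev.compartment_comparison(d, s, protocol_time_s=cfg.pre_duration_s)
        assert cls == "neither"

    def test_both_with_amplitude_ratio(self):
        cfg, d, s = self._paired([35.0], [35.0], seed=3, soma_factor=0.5)
        cls, damp, samp = ev.compartment_comparison(d, s, protocol_time_s=cfg.pre_duration_s)
        assert cls == "both"
        assert samp / damp == pytest.approx(0.5, abs=0.15)

    def test_misaligned_rejected(self):
        cfg, d, s = self._paired([35.0], [])
        short = ROITrace(times_s=s.times_s[:-10], value=s.value[:-10])
        with pytest.raises(DomainError):
            ev.compartment_comparison(d, short)


class TestKSComparison:
    def test_identical_samples(self):
        a = np.arange(50.0)
        res = ev.compare_onset_distributions(a, a)
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ev.compare_onset_distributions(np.arange(50.0), 100.0 + np.arange(50.0), n_comparisons=4)
        assert res.statistic == 1.0
        assert res.p_adjusted == pytest.approx(min(1.0, res.pvalue * 4))

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(35, 12, 40)
            b = rng.normal(35, 12, 40)
            if ev.compare_onset_distributions(a, b).pvalue < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.09

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            ev.compare_onset_distributions([], [1.0])
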