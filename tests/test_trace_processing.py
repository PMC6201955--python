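"""Drift removal, high-pass tuning, spike detection and train matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogmap.synthetic_data import TraceNoiseSpec, render_trace, spike_kernel
from cogmap.trace_processing import (
    DetectionParams,
    FluorescenceTrace,
    SpikeTrain,
    detect_spikes,
    firing_frequency,
    highpass_filter,
    match_spike_trains,
    process_trace,
    remove_drift,
    tune_highpass,
)


def _trace(samples, frame_rate=250.0):
    return FluorescenceTrace(neuron_id="n", samples=samples, frame_rate=frame_rate)


class TestRemoveDrift:
    def test_pure_degree6_polynomial_removed_exactly(self):
        t = np.arange(5000) / 250.0
        poly = 3.0 - 2.0 * t + 0.5 * t**3 - 0.01 * t**6
        out = remove_drift(_trace(poly), degree=6)
        assert np.max(np.abs(out.samples)) < 1e-8 * np.max(np.abs(poly))

    def test_recovers_fast_sine_on_polynomial_drift(self):
        # independent oracle: direct least-squares on a Vandermonde basis
        t = np.arange(7500) / 250.0
        sine = np.sin(2 * np.pi * 30.0 * t)
        drift = 5.0 + 2.0 * t - 0.3 * t**2
        out = remove_drift(_trace(drift + sine), degree=6)
        V = np.vander(t, 7)
        coef, *_ = np.linalg.lstsq(V, drift + sine, rcond=None)
        oracle = drift + sine - V @ coef
        assert np.max(np.abs(out.samples - oracle)) < 1e-8
        assert np.max(np.abs(out.samples - sine)) < 0.01  # 1% of unit amplitude

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            remove_drift(_trace(np.zeros(5)), degree=6)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = np.arange(2000) / 250.0
        x = rng.standard_normal(2000) + t**2
        once = remove_drift(_trace(x), 6)
        twice = remove_drift(once, 6)
        scale = np.max(np.abs(once.samples))
        assert np.max(np.abs(twice.samples - once.samples)) < 1e-10 * scale


class TestTuneHighpass:
    def test_slow_only_trace_follows_separation_score(self):
        # with no fast content the score is computed per candidate and the
        # argmax rule decides; verify the selection matches an independent
        # evaluation of the score
        t = np.arange(5000) / 250.0
        trace = _trace(np.sin(2 * np.pi * 1.0 * t))
        params = DetectionParams(highpass_cutoffs=(5.0, 20.0, 50.0))
        chosen = tune_highpass(trace, params)
        scores = {}
        for c in (5.0, 20.0, 50.0):
            fast = highpass_filter(trace.samples, 250.0, c)
            scores[c] = np.max(np.abs(fast)) - np.max(np.abs(trace.samples - fast))
        assert chosen == max(sorted(scores), key=lambda c: scores[c])

    def test_sway_suppressed_and_spikes_retained(self):
        # band-power oracle: chosen cutoff must suppress 2-Hz sway power
        # >= 100x while keeping >= 80% of the spike peak amplitude
        noise = TraceNoiseSpec(drift_amplitude=0.0, gaussian_noise_sd=0.0)
        rng = np.random.default_rng(1)
        spikes = np.arange(0.5, 19.5, 0.8)
        trace = render_trace(spikes, noise, rng)
        t = trace.times
        sway = 5.0 * np.sin(2 * np.pi * 2.0 * t)
        mixed = _trace(trace.samples + sway)
        params = DetectionParams(highpass_cutoffs=(5.0, 20.0, 50.0))
        cutoff = tune_highpass(mixed, params)
        sway_out = highpass_filter(sway, 250.0, cutoff)
        assert np.sum(sway_out**2) <= np.sum(sway**2) / 100.0
        spike_out = highpass_filter(trace.samples, 250.0, cutoff)
        assert np.max(spike_out) >= 0.8 * np.max(trace.samples)

    def test_single_candidate_returned(self):
        trace = _trace(np.sin(np.arange(1000)))
        assert tune_highpass(trace, DetectionParams(highpass_cutoffs=(12.0,))) == 12.0

    def test_empty_candidates_rejected(self):
        trace = _trace(np.zeros(100))
        with pytest.raises(ValueError):
            tune_highpass(trace, DetectionParams(highpass_cutoffs=()))


class TestDetectSpikes:
    def test_zero_trace_gives_empty_train(self):
        st_ = detect_spikes(_trace(np.zeros(1000)), DetectionParams())
        assert st_.n_spikes == 0

    def test_noiseless_kernels_detected_within_one_frame(self, quiet_noise):
        rng = np.random.default_rng(2)
        truth = np.sort(rng.uniform(1.0, 19.0, size=10))
        truth = truth[np.insert(np.diff(truth) > 0.1, 0, True)]
        while truth.size < 10:
            extra = np.sort(rng.uniform(1.0, 19.0, size=10))
            truth = np.sort(np.concatenate([truth, extra]))
            truth = truth[np.insert(np.diff(truth) > 0.1, 0, True)][:10]
        trace = render_trace(truth, quiet_noise, rng)
        st_ = detect_spikes(trace, DetectionParams())
        assert st_.n_spikes == 10
        assert np.max(np.abs(st_.times - truth)) <= 1.0 / 250.0 + 1e-9

    def test_refractory_merges_close_kernels(self, quiet_noise):
        rng = np.random.default_rng(3)
        trace = render_trace(np.array([5.0, 5.002]), quiet_noise, rng)
        st_ = detect_spikes(trace, DetectionParams(refractory=0.004))
        assert st_.n_spikes == 1

    def test_detection_recall_precision_on_rendered_noise(self):
        # kernel SNR 10: amplitude 10 x noise sd 1
        noise = TraceNoiseSpec()
        rng = np.random.default_rng(4)
        truth = np.sort(rng.uniform(0.5, 19.5, 80))
        truth = truth[np.insert(np.diff(truth) >= 0.012, 0, True)]
        trace = render_trace(truth, noise, rng)
        st_ = process_trace(trace, DetectionParams())
        rep = match_spike_trains(st_, SpikeTrain("ref", truth), tolerance=1 / 250.0)
        assert 1 - rep.under / truth.size >= 0.95
        assert 1 - rep.over / max(st_.n_spikes, 1) >= 0.95


class TestMatchSpikeTrains:
    def test_identical_trains_match_perfectly(self):
        times = np.arange(0.1, 5.0, 0.13)
        rep = match_spike_trains(
            SpikeTrain("a", times), SpikeTrain("b", times), tolerance=0.004
        )
        assert rep.misdetections == 0
        assert np.all(rep.latencies == 0)

    def test_misdetection_count_for_constructed_errors(self):
        # 114 reference spikes; the test train misses 4 and adds 2 spurious
        rng = np.random.default_rng(5)
        ref = np.sort(rng.uniform(0, 20, 200))
        ref = ref[np.insert(np.diff(ref) > 0.02, 0, True)][:114]
        assert ref.size == 114
        test = np.delete(ref, [10, 40, 77, 100])
        test = np.sort(np.concatenate([test, ref[[20, 60]] + 0.009]))
        rep = match_spike_trains(
            SpikeTrain("t", test), SpikeTrain("r", ref), tolerance=0.004
        )
        assert rep.under == 4
        assert rep.over == 2
        assert rep.misdetections == 6

    def test_empty_test_train_counts_all_as_under(self):
        ref = np.arange(0.1, 1.0, 0.1)
        rep = match_spike_trains(
            SpikeTrain("t", []), SpikeTrain("r", ref), tolerance=0.01
        )
        assert rep.over == 0 and rep.under == ref.size
        assert rep.misdetections == ref.size

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_spike_trains(SpikeTrain("t", []), SpikeTrain("r", []), -1e-3)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 10, rng.integers(0, 40)))
        b = np.sort(rng.uniform(0, 10, rng.integers(0, 40)))
        a = a[np.insert(np.diff(a) > 1e-6, 0, True)] if a.size else a
        b = b[np.insert(np.diff(b) > 1e-6, 0, True)] if b.size else b
        fwd = match_spike_trains(SpikeTrain("a", a), SpikeTrain("b", b), 0.05)
        rev = match_spike_trains(SpikeTrain("b", b), SpikeTrain("a", a), 0.05)
        assert (fwd.over, fwd.under) == (rev.under, rev.over)
        assert fwd.misdetections == rev.misdetections
        assert np.allclose(np.sort(fwd.latencies), np.sort(-rev.latencies))


class TestFiringFrequency:
    @pytest.mark.parametrize(
        "times,window,expected",
        [
            (np.arange(12) * 0.5, (0.0, 6.0), 2.0),
            ([], (0.0, 6.0), 0.0),
            ([0.5, 1.5, 2.5], (1.0, 3.0), 1.0),  # half-open [1, 3)
        ],
    )
    def test_rate_is_count_over_duration(self, times, window, expected):
        assert firing_frequency(SpikeTrain("u", times), window) == expected

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            firing_frequency(SpikeTrain("u", [1.0]), (2.0, 2.0))
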