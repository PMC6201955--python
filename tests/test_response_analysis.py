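"""Response classification, ratio distributions, latency and modality."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cogmap.response_analysis import (
    Modality,
    ResponseLabel,
    ResponseMap,
    StimulusProtocol,
    build_ratio_distribution,
    classify_modality,
    classify_response,
    compare_distributions,
    frequency_difference,
    frequency_ratio,
    response_latency,
    unique_responses,
)
from cogmap.synthetic_data import (
    PopulationSpec,
    TraceNoiseSpec,
    generate_population,
    render_trace,
)
from cogmap.trace_processing import FluorescenceTrace, SpikeTrain


def train_with_counts(pre: int, on: int, protocol: StimulusProtocol) -> SpikeTrain:
    """A spike train with given counts in stim_PRE and stim_ON."""
    times = []
    if pre:
        times.extend(np.linspace(*protocol.stim_pre, pre, endpoint=False))
    if on:
        times.extend(np.linspace(*protocol.stim_on, on, endpoint=False))
    return SpikeTrain("u", np.asarray(sorted(times)))


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "pre,on,expected",
        [
            (12, 12, ResponseLabel.NONRESPONSIVE),  # zero difference
            (2, 40, ResponseLabel.EXCITED),
            (40, 2, ResponseLabel.INHIBITED),
            (12, 13, ResponseLabel.NONRESPONSIVE),  # inside the dead band
        ],
    )
    def test_count_difference_rule(self, pre, on, expected, iv_protocol):
        train = train_with_counts(pre, on, iv_protocol)
        assert classify_response(train, iv_protocol, deadband=1.0) is expected

    def test_unequal_windows_rejected(self):
        protocol = StimulusProtocol(onset=7.0, offset=10.0, pre_duration=6.0)
        with pytest.raises(ValueError):
            classify_response(SpikeTrain("u", []), protocol)

    def test_antisymmetric_under_count_swap(self, iv_protocol):
        a = classify_response(train_with_counts(3, 30, iv_protocol), iv_protocol)
        b = classify_response(train_with_counts(30, 3, iv_protocol), iv_protocol)
        assert (a, b) == (ResponseLabel.EXCITED, ResponseLabel.INHIBITED)


class TestFrequencyRatio:
    def test_equal_rates_give_unity(self, iv_protocol):
        assert frequency_ratio(train_with_counts(12, 12, iv_protocol), iv_protocol) == 1.0

    def test_silent_prestim_is_omitted(self, iv_protocol):
        assert frequency_ratio(train_with_counts(0, 12, iv_protocol), iv_protocol) is None

    def test_doubling(self, iv_protocol):
        train = train_with_counts(12, 24, iv_protocol)
        assert frequency_ratio(train, iv_protocol) == 2.0
        assert frequency_difference(train, iv_protocol) == pytest.approx(2.0)


class TestRatioDistribution:
    def test_degenerate_single_value(self):
        dist = build_ratio_distribution([[1.0] * 5])
        assert dist.mean_counts.max() == 1.0
        assert (dist.mean_counts > 0).sum() == 1

    def test_identical_preparations_average_to_themselves(self):
        ratios = [0.5, 0.8, 0.8, 1.3]
        two = build_ratio_distribution([ratios, ratios])
        one = build_ratio_distribution([ratios])
        assert np.allclose(two.mean_counts, one.mean_counts)
        assert np.allclose(two.sd_counts, 0.0)

    def test_normalized_max_is_one_per_preparation(self):
        rng = np.random.default_rng(0)
        preps = [rng.uniform(0, 3, 50) for _ in range(4)]
        dist = build_ratio_distribution(preps)
        assert np.allclose(dist.per_preparation.max(axis=1), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_ratio_distribution([[None]])


class TestCompareDistributions:
    def test_identical_samples_give_zero_statistic(self):
        a = np.arange(10.0)
        d, _ = compare_distributions(a, a)
        assert d == 0.0

    def test_disjoint_supports_give_unit_statistic(self):
        d, _ = compare_distributions([0.0], [1.0])
        assert d == 1.0

    def test_shifted_uniforms_detected(self):
        # simulation oracle: U(0,1) vs U(0.5,1.5) at n=1000 must reject
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 1, 1000)
            b = rng.uniform(0.5, 1.5, 1000)
            _, p = compare_distributions(a, b)
            assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestResponseLatency:
    def test_delta_pulse_latency_recovered(self):
        fs = 250.0
        samples = np.zeros(5000)
        onset = 7.0
        samples[int((onset + 0.030) * fs)] = 1.0
        trace = FluorescenceTrace("n", samples, frame_rate=fs)
        lat = response_latency(trace, onset, 0.1)
        assert lat == pytest.approx(0.030, abs=1.0 / fs)

    def test_flat_trace_ties_to_window_start(self):
        trace = FluorescenceTrace("n", np.zeros(5000), frame_rate=250.0)
        assert response_latency(trace, 7.0, 0.1) == 0.0

    def test_window_beyond_sweep_rejected(self):
        trace = FluorescenceTrace("n", np.zeros(250), frame_rate=250.0)
        with pytest.raises(ValueError):
            response_latency(trace, 0.95, 0.2)

    def test_sample_mean_latency_matches_generator(self):
        # sampling-distribution oracle: latencies ~ N(29.7 ms, 11.4 ms)
        # truncated at 0; the mean of n=60 measured latencies must fall
        # within 2 standard errors of the mean
        spec = PopulationSpec(
            n_neurons=60,
            p_multimodal=1.0, p_unimodal=0.0, p_nonparticipant=0.0,
            p_excited_by_condition={"IV": 1.0, "VCN": 1.0},
            p_sign_switch=0.0,
            seed=11,
        )
        noise = TraceNoiseSpec(drift_amplitude=0.0, gaussian_noise_sd=0.0)
        protocol = StimulusProtocol(condition="IV", pulse_rate=1.0)
        traces, truth = generate_population(spec, noise, [protocol], n_trials=1)
        measured = []
        for tr in traces:
            measured.append(response_latency(tr, protocol.onset, 0.1))
        se = 0.0114 / np.sqrt(len(measured))
        assert abs(np.mean(measured) - 0.0297) < 2 * se


class TestModality:
    @pytest.mark.parametrize(
        "iv,vcn,expected",
        [
            (ResponseLabel.EXCITED, ResponseLabel.INHIBITED, Modality.MULTIMODAL),
            (ResponseLabel.NONRESPONSIVE, ResponseLabel.EXCITED, Modality.UNIMODAL),
            (ResponseLabel.NONRESPONSIVE, ResponseLabel.NONRESPONSIVE,
             Modality.NONPARTICIPANT),
        ],
    )
    def test_definition(self, iv, vcn, expected):
        rmap = ResponseMap(labels={("n0", "IV"): iv, ("n0", "VCN"): vcn})
        modality, proportions = classify_modality(rmap)
        assert modality["n0"] is expected
        assert sum(proportions.values()) == pytest.approx(100.0)

    def test_generator_proportions_within_binomial_ci(self):
        spec = PopulationSpec(n_neurons=100, seed=1)
        _, truth = generate_population(
            spec, TraceNoiseSpec(), [StimulusProtocol("IV"), StimulusProtocol("VCN")],
            render=False,
        )
        rmap = ResponseMap(labels=dict(truth.labels))
        _, proportions = classify_modality(rmap)
        for key, p in (("multimodal", 0.80), ("unimodal", 0.18),
                       ("nonparticipant", 0.02)):
            lo, hi = stats.binom.interval(0.95, 100, p)
            assert lo <= proportions[key] <= hi

    def test_missing_condition_rejected(self):
        rmap = ResponseMap(labels={("n0", "IV"): ResponseLabel.EXCITED})
        with pytest.raises(ValueError):
            classify_modality(rmap)


def _expected_unique(labels):
    """Independent enumeration of the unique-response definition."""
    if len(set(labels)) != 2:
        return None  # identical or pairwise distinct: omitted
    for i, lab in enumerate(labels):
        others = [x for j, x in enumerate(labels) if j != i]
        if others[0] == others[1] != lab:
            return i
    return None


class TestUniqueResponses:
    def test_matches_enumeration_of_all_27_triples(self):
        conditions = ("IV", "VCN", "bimodal")
        triples = list(itertools.product(ResponseLabel, repeat=3))
        labels = {}
        for k, triple in enumerate(triples):
            for c, lab in zip(conditions, triple):
                labels[(f"n{k:02d}", c)] = lab
        result = unique_responses(ResponseMap(labels=labels))
        expected_counts = {c: 0 for c in conditions}
        n_identical = n_distinct = 0
        for triple in triples:
            idx = _expected_unique(triple)
            if idx is not None:
                expected_counts[conditions[idx]] += 1
            elif len(set(triple)) == 1:
                n_identical += 1
            elif len(set(triple)) == 3:
                n_distinct += 1
        assert result["unique_count"] == expected_counts
        assert result["n_omitted_identical"] == n_identical
        assert result["n_omitted_distinct"] == n_distinct

    def test_worked_examples(self):
        ex, inh, nr = ResponseLabel.EXCITED, ResponseLabel.INHIBITED, \
            ResponseLabel.NONRESPONSIVE
        labels = {}
        for k, triple in enumerate([(ex, inh, inh), (ex, ex, ex), (ex, inh, nr)]):
            for c, lab in zip(("IV", "VCN", "bimodal"), triple):
                labels[(f"n{k}", c)] = lab
        result = unique_responses(ResponseMap(labels=labels))
        assert result["unique_count"] == {"IV": 1, "VCN": 0, "bimodal": 0}
        assert result["n_omitted_identical"] == 1
        assert result["n_omitted_distinct"] == 1
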