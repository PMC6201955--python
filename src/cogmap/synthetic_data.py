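"""Ground-truth-labelled synthetic populations of CoG activity.

The generator emulates the statistical structure of voltage-sensitive-dye
recordings from the crab commissural ganglion so that every downstream
analysis stage can be exercised against known labels:

- population composition ~80% multimodal / 18% unimodal / 2% nonparticipant,
  with ~46% of multimodal neurons switching response sign between the
  chemosensory (IV) and mechanosensory (VCN) conditions;
- spontaneous firing 0.33-6.8 Hz, stimulus-evoked rates up to 14 Hz,
  6-s stimulus trains, response latencies of ~30 ms with condition-specific
  jitter (IV 29.7 +/- 11.4 ms, VCN 31.9 +/- 7.7 ms);
- fluorescence rendered at 250 frames/s over 20-s sweeps as biexponential
  spike kernels on degree-6 polynomial drift plus Gaussian noise;
- a triphasic pyloric rhythm (PD/LP/PY bursts, ~1-s period) whose burst
  metrics change by configurable relative amounts after stimulation.

Spikes are drawn from an inhomogeneous Poisson process with a 10-ms dead
time (biological refractoriness keeps even 14-Hz firing resolvable at the
4-ms frame interval).  All randomness flows from one seed; identical specs
and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .response_analysis import ResponseLabel, StimulusProtocol
from .trace_processing import FluorescenceTrace, SpikeTrain

__all__ = [
    "PopulationSpec",
    "TraceNoiseSpec",
    "GroundTruth",
    "spike_kernel",
    "render_trace",
    "generate_population",
    "generate_pyloric",
    "default_protocols",
]

#: Pulse rates at or below this are treated as the low-frequency latency
#: protocol: excited neurons fire one pulse-locked spike per pulse.
LOW_RATE_CUTOFF = 2.0


@dataclass
class PopulationSpec:
    """Statistical composition of a synthetic CoG population.

    Defaults reproduce the published population statistics: the 80/18/2
    modality split, excitation probabilities per condition, a 46.15% chance
    that a multimodal neuron flips response sign between IV and VCN,
    spontaneous rates of 0.33-6.8 Hz and evoked rates up to 14 Hz, and
    condition-specific latency means and SDs (seconds).

    ``bimodal_rule`` controls how the bimodal-condition label of a
    responding neuron is drawn: ``"independent"`` uses the published bimodal
    proportions (59.19% excited / 33.56% inhibited / 7.25% nonresponsive);
    ``"additive"`` applies the additive expectation from the IV and VCN
    labels (opposite-sign pairs resolved by a fair coin), producing a
    population that is perfectly congruent where a rule exists.
    ``rate_dispersion`` is the trial-to-trial coefficient of variation of
    the evoked rate (the source data do not constrain it; default 0).

    ``common_drive`` is the depth (0-1) of a slow network co-modulation
    shared by all excited neurons of a sweep during stimulation: their
    evoked rates are scaled by ``1 + common_drive * s(t)`` with a common
    smooth signal ``s(t)``.  Co-activated neurons in the real ganglion
    covary through shared synaptic drive, which is what makes their
    fluorescence coherent; the default depth puts the functional
    connectivity of a typical population in the empirically observed
    few-percent density range.  Set 0 for fully independent spiking.
    """

    n_neurons: int = 100
    p_multimodal: float = 0.80
    p_unimodal: float = 0.18
    p_nonparticipant: float = 0.02
    p_excited_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"IV": 0.51, "VCN": 0.55, "bimodal": 0.6383}
    )
    p_sign_switch: float = 0.4615
    baseline_rate_range: tuple[float, float] = (0.33, 6.8)
    evoked_rate_range: tuple[float, float] = (7.0, 14.0)
    latency_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "IV": (0.0297, 0.0114),
            "VCN": (0.0319, 0.0077),
            "bimodal": (0.0300, 0.0100),
        }
    )
    inhibition_factor: float = 0.2
    rate_dispersion: float = 0.0
    common_drive: float = 0.9
    refractory: float = 0.010
    bimodal_rule: str = "independent"
    p_bimodal_label: tuple[float, float, float] = (0.5919, 0.3356, 0.0725)
    field_shape: tuple[float, float] = (192.0, 128.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_multimodal + self.p_unimodal + self.p_nonparticipant
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"modality probabilities must sum to 1 (got {total})")
        for p in (self.p_multimodal, self.p_unimodal, self.p_nonparticipant,
                  self.p_sign_switch, *self.p_excited_by_condition.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.baseline_rate_range, self.evoked_rate_range):
            if lo <= 0 or hi < lo:
                raise ValueError("rate ranges must be positive and ordered")
        if self.evoked_rate_range[1] < self.baseline_rate_range[1]:
            raise ValueError("evoked max rate must be >= baseline max rate")
        if self.bimodal_rule not in ("independent", "additive"):
            raise ValueError("bimodal_rule must be 'independent' or 'additive'")
        if not 0 <= self.common_drive <= 1:
            raise ValueError("common_drive must lie in [0, 1]")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")


@dataclass
class TraceNoiseSpec:
    """Rendering model for fluorescence sweeps.

    A spike contributes a biexponential kernel (rise/decay time constants in
    seconds) with peak ``kernel_amplitude``; the sweep additionally carries a
    random polynomial drift (degree 6, matching the removal stage, scaled to
    a ``drift_amplitude`` peak-to-peak span) and white Gaussian noise.  The
    kernel-amplitude-to-noise-SD ratio is the controllable SNR.

    ``subthreshold_amplitude`` scales the slow shared membrane-potential
    fluctuation rendered into excited neurons' traces during stimulation
    (times each neuron's coupling strength).  Slow subthreshold changes in
    these recordings are often larger than the undersampled spikes; they
    are what makes co-activated neurons' fluorescence cohere, and the
    per-neuron high-pass stage exists to separate spikes from them.  Set 0
    for spiking-only traces.
    """

    frame_rate: float = 250.0
    sweep_length: float = 20.0
    drift_poly_degree: int = 6
    drift_amplitude: float = 20.0
    gaussian_noise_sd: float = 1.0
    kernel_amplitude: float = 10.0
    kernel_tau_rise: float = 0.002
    kernel_tau_decay: float = 0.008
    subthreshold_amplitude: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.sweep_length <= 0:
            raise ValueError("frame_rate and sweep_length must be positive")
        if self.gaussian_noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be non-negative")
        if self.subthreshold_amplitude < 0:
            raise ValueError("subthreshold_amplitude must be non-negative")
        if min(self.kernel_tau_rise, self.kernel_tau_decay) <= 0:
            raise ValueError("kernel time constants must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_length * self.frame_rate))


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    modality: dict[str, str]
    labels: dict[tuple[str, str], ResponseLabel]
    spike_times: dict[tuple[str, str], list[np.ndarray]]  # per trial
    latency: dict[tuple[str, str], float | None]
    baseline_rate: dict[str, float]
    evoked_rate: dict[tuple[str, str], float]
    xy: dict[str, tuple[float, float]]
    coupling: dict[str, float] = field(default_factory=dict)

    @property
    def neurons(self) -> list[str]:
        return sorted(self.modality)


def default_protocols(
    conditions: Sequence[str] = ("IV", "VCN", "bimodal"),
) -> dict[str, StimulusProtocol]:
    """Physiological 6-s trains: IV 40 Hz, VCN 15 Hz, bimodal both at once."""
    rates = {"IV": 40.0, "VCN": 15.0, "bimodal": 40.0, "none": 0.0}
    return {
        c: StimulusProtocol(condition=c, pulse_rate=rates.get(c, 40.0))
        for c in conditions
    }


def spike_kernel(noise: TraceNoiseSpec) -> tuple[np.ndarray, int]:
    """Sampled biexponential spike waveform and the index of its peak.

    The optical action potential is undersampled at 250 frames/s; a
    biexponential pulse about 4 frames wide stands in for its waveform.
    """
    dt = 1.0 / noise.frame_rate
    length = int(math.ceil(6 * noise.kernel_tau_decay / dt)) + 1
    t = np.arange(length) * dt
    shape = np.exp(-t / noise.kernel_tau_decay) - np.exp(-t / noise.kernel_tau_rise)
    peak = int(np.argmax(shape))
    return noise.kernel_amplitude * shape / shape[peak], peak


def render_trace(
    spike_times: np.ndarray,
    noise: TraceNoiseSpec,
    rng: np.random.Generator,
    *,
    neuron_id: str = "n0",
    sweep_id: str = "0",
) -> FluorescenceTrace:
    """Render spikes as kernel pulses on polynomial drift plus Gaussian noise.

    Each kernel is placed so its peak falls on the frame nearest the spike
    time, keeping detected peak times within one frame of ground truth.
    """
    n = noise.n_samples
    samples = np.zeros(n)
    kernel, peak = spike_kernel(noise)
    for t_spike in np.asarray(spike_times, float):
        center = int(round(t_spike * noise.frame_rate))
        lo = center - peak
        hi = lo + kernel.size
        k_lo, k_hi = max(0, -lo), kernel.size - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            samples[lo:hi] += kernel[k_lo:k_hi]
    if noise.drift_amplitude > 0:
        x = np.linspace(-1.0, 1.0, n)
        coeffs = rng.standard_normal(noise.drift_poly_degree + 1)
        drift = np.polynomial.polynomial.polyval(x, coeffs)
        span = np.ptp(drift)
        if span > 0:
            drift *= noise.drift_amplitude / span
        samples += drift
    else:
        rng.standard_normal(noise.drift_poly_degree + 1)  # keep stream aligned
    if noise.gaussian_noise_sd > 0:
        samples += noise.gaussian_noise_sd * rng.standard_normal(n)
    return FluorescenceTrace(
        neuron_id=neuron_id, samples=samples, frame_rate=noise.frame_rate,
        sweep_id=sweep_id,
    )


def _make_modulation(freqs: np.ndarray, phases: np.ndarray):
    """Smooth shared drive: a mean of three random-phase slow sinusoids.

    Accepts a scalar time or a time array.
    """

    def s(t):
        t_arr = np.asarray(t, dtype=float)
        vals = np.mean(
            np.sin(2.0 * np.pi * freqs[:, None] * t_arr.ravel()[None, :]
                   + phases[:, None]),
            axis=0,
        )
        return float(vals[0]) if t_arr.ndim == 0 else vals.reshape(t_arr.shape)

    return s


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gaussian draw truncated at zero (latencies cannot be negative)."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    return max(mean, 0.0)


def _sample_inhomogeneous(
    rng: np.random.Generator,
    segments: Sequence[tuple[float, float, float, bool]],
    refractory: float,
    modulation=None,
    depth: float = 0.0,
) -> np.ndarray:
    """Thinning sampler for a piecewise-rate process with dead time.

    Each segment is ``(start, end, rate, modulated)``; modulated segments
    have their rate scaled by ``max(0, 1 + depth * modulation(t))``.
    """
    use_mod = modulation is not None and depth > 0
    rates = [
        r * (1.0 + depth) if (m and use_mod) else r for _, _, r, m in segments
    ]
    r_max = max(rates, default=0.0)
    if r_max <= 0:
        return np.empty(0)
    t_end = max(end for _, end, _, _ in segments)
    spikes: list[float] = []
    t = segments[0][0]
    while True:
        t += rng.exponential(1.0 / r_max)
        if t >= t_end:
            break
        rate = 0.0
        for s, e, r, m in segments:
            if s <= t < e:
                rate = r * max(0.0, 1.0 + depth * modulation(t)) if (m and use_mod) else r
                break
        if rng.uniform() < rate / r_max:
            spikes.append(t)
            t += refractory
    return np.asarray(spikes)


def _draw_labels(
    spec: PopulationSpec, rng: np.random.Generator, conditions: Sequence[str]
) -> tuple[str, dict[str, ResponseLabel]]:
    """Modality class and per-condition response labels for one neuron."""
    ex, inh, nr = ResponseLabel.EXCITED, ResponseLabel.INHIBITED, ResponseLabel.NONRESPONSIVE
    u = rng.uniform()
    labels: dict[str, ResponseLabel] = {}
    if u < spec.p_nonparticipant:
        modality = "nonparticipant"
        labels["IV"] = labels["VCN"] = nr
    elif u < spec.p_nonparticipant + spec.p_unimodal:
        modality = "unimodal"
        responsive = "IV" if rng.uniform() < 0.5 else "VCN"
        silent = "VCN" if responsive == "IV" else "IV"
        sign = ex if rng.uniform() < spec.p_excited_by_condition[responsive] else inh
        labels[responsive], labels[silent] = sign, nr
    else:
        modality = "multimodal"
        iv_sign = ex if rng.uniform() < spec.p_excited_by_condition["IV"] else inh
        if rng.uniform() < spec.p_sign_switch:
            vcn_sign = inh if iv_sign is ex else ex
        else:
            vcn_sign = iv_sign
        labels["IV"], labels["VCN"] = iv_sign, vcn_sign
    if "bimodal" in conditions:
        if modality == "nonparticipant":
            labels["bimodal"] = nr
        elif spec.bimodal_rule == "additive":
            from .congruency import NO_RULE, expected_bimodal

            expected = expected_bimodal(labels["IV"], labels["VCN"])
            if expected is NO_RULE:
                expected = ex if rng.uniform() < 0.5 else inh
            labels["bimodal"] = expected
        else:
            p_ex, p_inh, _ = spec.p_bimodal_label
            v = rng.uniform()
            labels["bimodal"] = ex if v < p_ex else inh if v < p_ex + p_inh else nr
    return modality, labels


def _spike_segments(
    label: ResponseLabel,
    protocol: StimulusProtocol,
    baseline: float,
    evoked: float,
    latency: float,
    inhibition_factor: float,
    sweep_length: float,
) -> list[tuple[float, float, float, bool]]:
    """Piecewise firing rate over one sweep; the evoked segment of excited
    neurons is flagged for shared-drive modulation."""
    onset, offset = protocol.onset, protocol.offset
    if label is ResponseLabel.EXCITED:
        stim_rate, start, modulated = evoked, onset + latency, True
    elif label is ResponseLabel.INHIBITED:
        stim_rate, start, modulated = baseline * inhibition_factor, onset + latency, False
    else:
        return [(0.0, sweep_length, baseline, False)]
    return [
        (0.0, start, baseline, False),
        (start, offset, stim_rate, modulated),
        (offset, sweep_length, baseline, False),
    ]


def generate_population(
    spec: PopulationSpec,
    noise: TraceNoiseSpec,
    protocols: Mapping[str, StimulusProtocol] | Sequence[StimulusProtocol],
    *,
    n_trials: int = 1,
    seed: int | None = None,
    render: bool = True,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Generate a labelled population of fluorescence sweeps.

    One trace is produced per neuron, condition and trial; its ``sweep_id``
    is ``"<condition>:<trial>"``.  Excited neurons step from their baseline
    rate to a condition-specific evoked rate at (onset + latency); inhibited
    neurons drop to ``baseline * inhibition_factor``.  Under low-frequency
    protocols (pulse rate <= 2 Hz) excited neurons instead fire one
    pulse-locked spike per pulse at an independently jittered latency, the
    regime used for latency measurements.  ``render=False`` skips trace
    rendering (the ground-truth spike trains are still produced), which is
    useful for rate-level simulations.

    Deterministic for a given spec, protocols and seed (default
    ``spec.seed``).
    """
    if isinstance(protocols, Mapping):
        protocol_list = list(protocols.values())
    else:
        protocol_list = list(protocols)
    if not protocol_list:
        raise ValueError("need at least one stimulus protocol")
    conditions = [p.condition for p in protocol_list]
    if len(set(conditions)) != len(conditions):
        raise ValueError("protocol conditions must be distinct")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    master_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)
    # shared slow co-modulation per sweep, from a dedicated stream so the
    # label/rate draws are unaffected by the drive settings
    rng_mod = np.random.default_rng([master_seed % 2**31, 104729])
    modulations: dict[tuple[str, int], object] = {}
    for protocol in protocol_list:
        for trial in range(n_trials):
            freqs = rng_mod.uniform(0.3, 2.0, 3)
            phases = rng_mod.uniform(0.0, 2.0 * np.pi, 3)
            modulations[(protocol.condition, trial)] = _make_modulation(freqs, phases)

    modality: dict[str, str] = {}
    labels: dict[tuple[str, str], ResponseLabel] = {}
    spike_times: dict[tuple[str, str], list[np.ndarray]] = {}
    latency: dict[tuple[str, str], float | None] = {}
    baseline_rate: dict[str, float] = {}
    evoked_rate: dict[tuple[str, str], float] = {}
    xy: dict[str, tuple[float, float]] = {}
    coupling: dict[str, float] = {}
    traces: list[FluorescenceTrace] = []

    half_w, half_h = spec.field_shape[0] / 2.0, spec.field_shape[1] / 2.0
    width = max(2, len(str(spec.n_neurons - 1)))
    for i in range(spec.n_neurons):
        neuron = f"n{i:0{width}d}"
        # soma position: uniform inside the elliptical imaged field
        while True:
            px, py = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if px * px + py * py <= 1.0:
                break
        xy[neuron] = (half_w + px * half_w, half_h + py * half_h)
        baseline = rng.uniform(*spec.baseline_rate_range)
        baseline_rate[neuron] = baseline
        modality[neuron], neuron_labels = _draw_labels(spec, rng, conditions)
        coupling[neuron] = float(rng.uniform())  # strength of shared drive
        for protocol in protocol_list:
            condition = protocol.condition
            label = neuron_labels.get(condition, ResponseLabel.NONRESPONSIVE)
            labels[(neuron, condition)] = label
            evoked = rng.uniform(*spec.evoked_rate_range)
            evoked_rate[(neuron, condition)] = evoked
            mean, sd = spec.latency_mean_sd.get(condition, (0.03, 0.01))
            lat = (
                _truncated_normal(rng, mean, sd)
                if label is not ResponseLabel.NONRESPONSIVE
                else None
            )
            latency[(neuron, condition)] = lat
            trials: list[np.ndarray] = []
            low_rate = 0 < protocol.pulse_rate <= LOW_RATE_CUTOFF
            for trial in range(n_trials):
                if spec.rate_dispersion > 0:
                    trial_evoked = max(
                        evoked * (1.0 + spec.rate_dispersion * rng.standard_normal()), 0.0
                    )
                else:
                    trial_evoked = evoked
                if low_rate and label is ResponseLabel.EXCITED:
                    pulse_lats = np.array(
                        [_truncated_normal(rng, mean, sd) for _ in protocol.pulse_times()]
                    )
                    evoked_spikes = protocol.pulse_times() + pulse_lats
                    base = _sample_inhomogeneous(
                        rng, [(0.0, noise.sweep_length, baseline, False)],
                        spec.refractory,
                    )
                    base = base[
                        (base < protocol.onset) | (base >= protocol.offset + 0.1)
                    ]
                    spikes = np.sort(np.concatenate([base, evoked_spikes]))
                else:
                    segments = _spike_segments(
                        label, protocol, baseline, trial_evoked,
                        lat if lat is not None else 0.0,
                        spec.inhibition_factor, noise.sweep_length,
                    )
                    spikes = _sample_inhomogeneous(
                        rng, segments, spec.refractory,
                        modulation=modulations[(condition, trial)],
                        depth=spec.common_drive,
                    )
                trials.append(spikes)
                if render:
                    trace = render_trace(
                        spikes, noise, rng,
                        neuron_id=neuron, sweep_id=f"{condition}:{trial}",
                    )
                    if (
                        label is ResponseLabel.EXCITED
                        and not low_rate
                        and noise.subthreshold_amplitude > 0
                    ):
                        # shared slow depolarisation: what co-activated
                        # neurons' coherence rides on
                        t_grid = trace.times
                        start = protocol.onset + (lat or 0.0)
                        mask = (t_grid >= start) & (t_grid < protocol.offset)
                        drive = modulations[(condition, trial)](t_grid[mask])
                        samples = trace.samples.copy()
                        samples[mask] += (
                            coupling[neuron] * noise.subthreshold_amplitude * drive
                        )
                        trace = replace(trace, samples=samples)
                    traces.append(trace)
            spike_times[(neuron, condition)] = trials

    truth = GroundTruth(
        modality=modality, labels=labels, spike_times=spike_times,
        latency=latency, baseline_rate=baseline_rate, evoked_rate=evoked_rate,
        xy=xy, coupling=coupling,
    )
    return traces, truth


#: Default per-unit burst structure of the triphasic pyloric rhythm:
#: phase of burst onset within the cycle, duty cycle, spikes per burst.
PYLORIC_UNITS: dict[str, tuple[float, float, int]] = {
    "PD": (0.0, 0.25, 6),
    "LP": (0.40, 0.25, 8),
    "PY": (0.70, 0.25, 10),
}


def generate_pyloric(
    condition_effects: Mapping[str, float] | None = None,
    cycle_period: float = 1.0,
    seed: int = 0,
    *,
    protocol: StimulusProtocol | None = None,
    duration: float = 30.0,
    units: Mapping[str, tuple[float, float, int]] | None = None,
    jitter: float = 0.01,
) -> dict[str, SpikeTrain]:
    """Generate PD/LP/PY spike trains for a triphasic pyloric rhythm.

    Cycles before the stimulus offset follow the baseline ``cycle_period``
    and per-unit burst structure; cycles starting at or after the offset
    apply the relative changes in ``condition_effects`` (keys among
    ``cycle_period``, ``burst_duration``, ``spikes_per_burst``,
    ``firing_frequency``; a ``firing_frequency`` change rescales the spike
    count at fixed duration unless ``spikes_per_burst`` is also given).
    Burst onsets receive Gaussian jitter with SD ``jitter * period``.
    """
    effects = dict(condition_effects or {})
    units = dict(units or PYLORIC_UNITS)
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    protocol = protocol or StimulusProtocol(condition="none", pulse_rate=0.0)
    for metric, change in effects.items():
        if metric not in ("cycle_period", "burst_duration", "spikes_per_burst",
                          "firing_frequency"):
            raise ValueError(f"unknown pyloric metric {metric!r}")
        if change <= -1.0 and metric in ("cycle_period", "burst_duration"):
            raise ValueError(f"{metric} change {change} produces negative durations")
    phases = sorted((phase, phase + duty) for phase, duty, _ in units.values())
    for (s1, e1), (s2, _) in zip(phases, phases[1:]):
        if s2 < e1:
            raise ValueError("burst phases must be non-overlapping within a cycle")
    if phases[-1][1] > 1.0:
        raise ValueError("burst phases must fit within one cycle")

    rng = np.random.default_rng(seed)
    post_period = cycle_period * (1.0 + effects.get("cycle_period", 0.0))
    spikes: dict[str, list[float]] = {u: [] for u in units}
    t = 0.0
    while t < duration:
        post = t >= protocol.offset
        period = post_period if post else cycle_period
        for unit, (phase, duty, n_base) in units.items():
            onset = t + phase * period + rng.normal(0.0, jitter * period)
            dur = duty * period
            n = n_base
            if post:
                dur *= 1.0 + effects.get("burst_duration", 0.0)
                if "spikes_per_burst" in effects:
                    n = int(round(n_base * (1.0 + effects["spikes_per_burst"])))
                if "firing_frequency" in effects:
                    # spike counts are integers, so the target in-burst rate
                    # is met exactly by adjusting the burst duration to the
                    # rounded count
                    base_freq = n_base / (duty * cycle_period)
                    target = base_freq * (1.0 + effects["firing_frequency"])
                    if "spikes_per_burst" not in effects:
                        n = max(1, int(round(target * dur)))
                    dur = n / target
            if dur <= 0 or n < 1:
                raise ValueError("requested change produces an empty or negative burst")
            spikes[unit].extend(onset + np.linspace(0.0, dur, n))
        t += period
    trains = {}
    for unit, times in spikes.items():
        arr = np.sort(np.asarray(times))
        arr = arr[(arr >= 0) & (arr < duration)]
        # jitter could in principle create coincident times; nudge duplicates
        dup = np.flatnonzero(np.diff(arr) <= 0)
        while dup.size:
            arr[dup + 1] = arr[dup] + 1e-6
            arr = np.sort(arr)
            dup = np.flatnonzero(np.diff(arr) <= 0)
        trains[unit] = SpikeTrain(unit_id=unit, times=arr, source="extracellular")
    return trains
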