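"""Per-neuron sensory-response classification and population distributions.

Each neuron is classified per stimulus condition as excited, inhibited or
nonresponsive from the trial-averaged difference in spike counts between the
6-s stimulation window (stim_ON) and the 6 s immediately preceding it
(stim_PRE).  Rate coding is probed through the frequency ratio
``f_ON / f_PRE`` (undefined for spontaneously silent neurons, which are
omitted) and the frequency difference ``f_ON - f_PRE``; per-preparation
histograms (bin width 0.1) are max-normalised and averaged across
preparations, and condition differences are tested with the two-sample
Kolmogorov-Smirnov statistic.  Neurons are multimodal if they respond to
both pathways, unimodal if to exactly one, nonparticipant otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trace_processing import FluorescenceTrace, SpikeTrain, mean_count

__all__ = [
    "Condition",
    "ResponseLabel",
    "StimulusProtocol",
    "ResponseMap",
    "RatioDistribution",
    "classify_response",
    "frequency_ratio",
    "frequency_difference",
    "build_ratio_distribution",
    "compare_distributions",
    "response_latency",
    "classify_modality",
    "unique_responses",
]

#: Conditions used throughout: chemosensory, mechanosensory, both at once.
Condition = str
CONDITIONS: tuple[Condition, ...] = ("IV", "VCN", "bimodal")


class ResponseLabel(str, enum.Enum):
    EXCITED = "excited"
    INHIBITED = "inhibited"
    NONRESPONSIVE = "nonresponsive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Modality(str, enum.Enum):
    MULTIMODAL = "multimodal"
    UNIMODAL = "unimodal"
    NONPARTICIPANT = "nonparticipant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StimulusProtocol:
    """One stimulation epoch: a 6-s pulse train plus its analysis windows.

    ``pulse_rate`` is the within-train pulse rate (40 Hz for IV, 15 Hz for
    VCN at physiological intensity; 1 Hz for the latency protocol).
    ``stim_PRE`` covers the ``pre_duration`` seconds before onset,
    ``stim_ON`` the train itself, and ``stim_POST`` starts after an
    exclusion gap ``post_gap`` past the offset.
    """

    condition: Condition = "IV"
    pulse_rate: float = 40.0
    onset: float = 7.0
    offset: float = 13.0
    pre_duration: float = 6.0
    post_gap: float = 1.5
    post_duration: float = 6.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")
        if min(self.pre_duration, self.post_duration) <= 0 or self.post_gap < 0:
            raise ValueError("window durations must be positive and gap non-negative")
        if self.onset - self.pre_duration < 0:
            raise ValueError("stim_PRE window starts before the sweep")

    @property
    def stim_pre(self) -> tuple[float, float]:
        return (self.onset - self.pre_duration, self.onset)

    @property
    def stim_on(self) -> tuple[float, float]:
        return (self.onset, self.offset)

    @property
    def stim_post(self) -> tuple[float, float]:
        start = self.offset + self.post_gap
        return (start, start + self.post_duration)

    @property
    def train_duration(self) -> float:
        return self.offset - self.onset

    def pulse_times(self) -> np.ndarray:
        """Onset times of the individual pulses in the train."""
        n = int(math.floor(self.train_duration * self.pulse_rate))
        return self.onset + np.arange(max(n, 1)) / self.pulse_rate


def _as_trains(trains: SpikeTrain | Sequence[SpikeTrain]) -> list[SpikeTrain]:
    if isinstance(trains, SpikeTrain):
        return [trains]
    trains = list(trains)
    if not trains:
        raise ValueError("need at least one spike train")
    return trains


def classify_response(
    trains: SpikeTrain | Sequence[SpikeTrain],
    protocol: StimulusProtocol,
    deadband: float = 1.0,
    z: float = 2.5,
) -> ResponseLabel:
    """Label a neuron excited/inhibited/nonresponsive for one condition.

    The decision statistic is the trial-averaged spike-count difference
    ``Δ = count(stim_ON) - count(stim_PRE)``; ``Δ`` above the dead band is
    excited, below its negative inhibited, otherwise nonresponsive.

    The dead band must absorb Poisson counting noise, whose scale grows
    with the firing rate (SD of ``Δ`` for an unchanged neuron is
    ``sqrt((c_PRE + c_ON) / n_trials)``), so it is the larger of
    ``deadband`` (an absolute floor, default one spike per window) and
    ``z`` such standard errors (default 2.5).  Set ``z=0`` for a fixed
    absolute dead band.
    """
    pre, on = protocol.stim_pre, protocol.stim_on
    if not math.isclose(pre[1] - pre[0], on[1] - on[0], rel_tol=1e-9):
        raise ValueError("stim_PRE and stim_ON must have equal durations")
    trains = _as_trains(trains)
    c_pre = mean_count(trains, pre)
    c_on = mean_count(trains, on)
    delta = c_on - c_pre
    band = max(deadband, z * math.sqrt((c_pre + c_on) / len(trains)))
    if delta > band:
        return ResponseLabel.EXCITED
    if delta < -band:
        return ResponseLabel.INHIBITED
    return ResponseLabel.NONRESPONSIVE


def frequency_ratio(
    trains: SpikeTrain | Sequence[SpikeTrain], protocol: StimulusProtocol
) -> float | None:
    """``f_ON / f_PRE``; ``None`` (omitted) for spontaneously silent neurons.

    Ratios > 1 indicate excitation, < 1 inhibition, = 1 no rate change.
    """
    trains = _as_trains(trains)
    f_pre = np.mean([tr.count(protocol.stim_pre) for tr in trains]) / protocol.pre_duration
    f_on = np.mean([tr.count(protocol.stim_on) for tr in trains]) / protocol.train_duration
    if f_pre == 0:
        return None
    return float(f_on / f_pre)


def frequency_difference(
    trains: SpikeTrain | Sequence[SpikeTrain], protocol: StimulusProtocol
) -> float:
    """``f_ON - f_PRE`` in Hz; defined for all neurons."""
    trains = _as_trains(trains)
    f_pre = np.mean([tr.count(protocol.stim_pre) for tr in trains]) / protocol.pre_duration
    f_on = np.mean([tr.count(protocol.stim_on) for tr in trains]) / protocol.train_duration
    return float(f_on - f_pre)


@dataclass
class RatioDistribution:
    """Max-normalised frequency-ratio histograms averaged across preparations."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    per_preparation: np.ndarray  # shape (n_preparations, n_bins)

    @property
    def n_preparations(self) -> int:
        return self.per_preparation.shape[0]


def build_ratio_distribution(
    ratios_per_preparation: Sequence[Sequence[float | None]],
    bin_width: float = 0.1,
    upper: float | None = None,
) -> RatioDistribution:
    """Histogram ratios per preparation, normalise to the max count, average.

    Undefined ratios (``None``/NaN, i.e. silent neurons) are dropped.  Bin
    edges run from 0 to the max observed ratio rounded up to the next bin
    (or ``upper``), shared across preparations for comparability.
    """
    cleaned: list[np.ndarray] = []
    for ratios in ratios_per_preparation:
        vals = np.asarray(
            [r for r in ratios if r is not None and not math.isnan(r)], dtype=float
        )
        if vals.size:
            cleaned.append(vals)
    if not cleaned:
        raise ValueError("no preparation with a defined frequency ratio")
    top = upper if upper is not None else max(v.max() for v in cleaned)
    n_bins = max(1, int(math.ceil(round(top / bin_width, 9))))
    edges = np.arange(n_bins + 1) * bin_width
    per_prep = np.empty((len(cleaned), n_bins))
    for k, vals in enumerate(cleaned):
        counts, _ = np.histogram(vals, bins=edges)
        per_prep[k] = counts / counts.max() if counts.max() > 0 else counts
    return RatioDistribution(
        bin_edges=edges,
        mean_counts=per_prep.mean(axis=0),
        sd_counts=per_prep.std(axis=0, ddof=1) if len(cleaned) > 1 else np.zeros(n_bins),
        per_preparation=per_prep,
    )


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test; returns (D, asymptotic p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(a, b, method="asymp")
    return float(result.statistic), float(result.pvalue)


def response_latency(
    mean_trace: FluorescenceTrace, onset: float, search_window: float = 0.1
) -> float:
    """Time from stimulus onset to the peak of a trial-averaged trace.

    The peak is the first global maximum within ``[onset, onset +
    search_window]`` (ties resolved to the earliest sample).
    """
    times = mean_trace.times
    if onset < times[0] or onset + search_window > times[-1]:
        raise ValueError("search window extends beyond the sweep")
    lo = int(np.searchsorted(times, onset, side="left"))
    hi = int(np.searchsorted(times, onset + search_window, side="right"))
    segment = mean_trace.samples[lo:hi]
    return float(times[lo + int(np.argmax(segment))] - onset)


@dataclass
class ResponseMap:
    """Per-neuron, per-condition labels and metrics, with soma coordinates."""

    labels: dict[tuple[str, Condition], ResponseLabel]
    ratio: dict[tuple[str, Condition], float | None] = field(default_factory=dict)
    diff: dict[tuple[str, Condition], float] = field(default_factory=dict)
    latency: dict[tuple[str, Condition], float | None] = field(default_factory=dict)
    xy: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def neurons(self) -> list[str]:
        return sorted({n for n, _ in self.labels})

    @property
    def conditions(self) -> list[Condition]:
        return sorted({c for _, c in self.labels})

    def label(self, neuron: str, condition: Condition) -> ResponseLabel:
        return self.labels[(neuron, condition)]

    @classmethod
    def from_spike_trains(
        cls,
        trains: Mapping[tuple[str, Condition], Sequence[SpikeTrain]],
        protocols: Mapping[Condition, StimulusProtocol],
        deadband: float = 1.0,
        z: float = 2.5,
        xy: Mapping[str, tuple[float, float]] | None = None,
    ) -> "ResponseMap":
        """Classify every (neuron, condition) group of trial spike trains."""
        labels, ratio, diff = {}, {}, {}
        for (neuron, condition), trial_trains in trains.items():
            protocol = protocols[condition]
            labels[(neuron, condition)] = classify_response(
                trial_trains, protocol, deadband, z
            )
            ratio[(neuron, condition)] = frequency_ratio(trial_trains, protocol)
            diff[(neuron, condition)] = frequency_difference(trial_trains, protocol)
        return cls(labels=labels, ratio=ratio, diff=diff, xy=dict(xy or {}))

    def condition_proportions(self, condition: Condition) -> dict[str, float]:
        """Percent of neurons excited/inhibited/nonresponsive in a condition."""
        labels = [lab for (n, c), lab in self.labels.items() if c == condition]
        if not labels:
            raise ValueError(f"no labels for condition {condition!r}")
        total = len(labels)
        return {
            lab.value: 100.0 * sum(1 for x in labels if x == lab) / total
            for lab in ResponseLabel
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (neuron, condition)."""
        rows = []
        for (neuron, condition), label in sorted(self.labels.items()):
            rows.append(
                {
                    "neuron_id": neuron,
                    "condition": condition,
                    "label": label.value,
                    "ratio": self.ratio.get((neuron, condition)),
                    "diff": self.diff.get((neuron, condition)),
                    "latency": self.latency.get((neuron, condition)),
                }
            )
        return pd.DataFrame(rows)


def classify_modality(
    response_map: ResponseMap,
) -> tuple[dict[str, Modality], dict[str, float]]:
    """Assign multimodal/unimodal/nonparticipant per neuron from IV and VCN.

    Returns the per-neuron labels and the population proportions in percent
    (NPG %).  A neuron is multimodal iff both unimodal conditions evoked a
    response, unimodal iff exactly one did, nonparticipant iff neither.
    """
    modality: dict[str, Modality] = {}
    for neuron in response_map.neurons:
        try:
            iv = response_map.label(neuron, "IV")
            vcn = response_map.label(neuron, "VCN")
        except KeyError as exc:
            raise ValueError(f"neuron {neuron!r} is missing an IV or VCN label") from exc
        responded = sum(lab != ResponseLabel.NONRESPONSIVE for lab in (iv, vcn))
        modality[neuron] = (
            Modality.MULTIMODAL
            if responded == 2
            else Modality.UNIMODAL if responded == 1 else Modality.NONPARTICIPANT
        )
    total = len(modality)
    proportions = {
        m.value: 100.0 * sum(1 for v in modality.values() if v == m) / total
        for m in Modality
    }
    return modality, proportions


def unique_responses(
    response_map: ResponseMap,
    conditions: Iterable[Condition] = CONDITIONS,
) -> dict[str, object]:
    """Proportion of neurons uniquely responsive to each of three conditions.

    A neuron is unique for condition ``c`` when its labels in the other two
    conditions agree with each other and its label in ``c`` differs.
    Neurons with three identical labels are not unique participants and are
    omitted; neurons with three pairwise-distinct labels satisfy no
    two-agree/one-differs pattern and are likewise omitted (and counted).
    Percentages use all scored neurons as the denominator.
    """
    conditions = list(conditions)
    if len(conditions) != 3:
        raise ValueError("unique-response analysis needs exactly three conditions")
    unique_count = {c: 0 for c in conditions}
    n_identical = n_distinct = 0
    neurons = response_map.neurons
    for neuron in neurons:
        try:
            labels = [response_map.label(neuron, c) for c in conditions]
        except KeyError as exc:
            raise ValueError(f"neuron {neuron!r} lacks a label in some condition") from exc
        distinct = len(set(labels))
        if distinct == 1:
            n_identical += 1
        elif distinct == 3:
            n_distinct += 1
        else:
            # exactly two distinct labels: the minority condition is unique
            for c, lab in zip(conditions, labels):
                if sum(1 for x in labels if x == lab) == 1:
                    unique_count[c] += 1
    total = len(neurons)
    if total == 0:
        raise ValueError("empty response map")
    return {
        "unique_percent": {c: 100.0 * unique_count[c] / total for c in conditions},
        "unique_count": unique_count,
        "n_neurons": total,
        "n_omitted_identical": n_identical,
        "n_omitted_distinct": n_distinct,
    }
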