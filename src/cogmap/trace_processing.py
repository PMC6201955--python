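"""Optical spike detection from voltage-sensitive-dye fluorescence traces.

Raw single-soma fluorescence reports membrane potential but rides on slow
drift (dye bleaching, movement) and shot noise.  The processing chain is:

1. :func:`remove_drift` — subtract a least-squares polynomial fit (degree 6
   by default) so the trace is zero-mean and drift-free.
2. :func:`tune_highpass` — pick, per neuron, the high-pass cutoff that best
   separates fast spike transients from slower membrane-potential changes.
3. :func:`detect_spikes` — threshold at ``k`` robust standard deviations
   (``median(|x|)/0.6745``) and keep one local maximum per refractory window.
4. :func:`match_spike_trains` — validate optical detection against a
   simultaneously recorded reference train by greedy nearest-neighbour
   pairing, counting over- and under-detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "FluorescenceTrace",
    "SpikeTrain",
    "DetectionParams",
    "MatchReport",
    "remove_drift",
    "highpass_filter",
    "tune_highpass",
    "detect_spikes",
    "process_trace",
    "match_spike_trains",
    "firing_frequency",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """One neuron's uniformly sampled optical signal for one sweep."""

    neuron_id: str
    samples: np.ndarray
    frame_rate: float = 250.0
    sweep_id: str = "0"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.frame_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) for one unit."""

    unit_id: str
    times: np.ndarray
    source: str = "optical"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float).ravel()
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError(f"spike times for {self.unit_id!r} must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def count(self, window: tuple[float, float]) -> int:
        """Number of spikes in the half-open window ``[start, end)``."""
        start, end = window
        return int(np.searchsorted(self.times, end, side="left")
                   - np.searchsorted(self.times, start, side="left"))


@dataclass
class DetectionParams:
    """Parameters of the optical spike-detection chain.

    ``threshold_k`` multiplies the robust noise estimate
    ``median(|x|)/0.6745``; the threshold convention follows the standard
    median-based spike-detection literature.  ``refractory`` (default 4 ms,
    one frame at 250 fps) suppresses double counts of undersampled optical
    spikes.
    """

    poly_degree: int = 6
    threshold_k: float = 4.0
    highpass_cutoffs: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0)
    refractory: float = 0.004
    prominence_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.poly_degree < 0:
            raise ValueError("poly_degree must be >= 0")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if any(c <= 0 for c in self.highpass_cutoffs):
            raise ValueError("high-pass cutoffs must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if self.prominence_factor < 0:
            raise ValueError("prominence_factor must be non-negative")


def remove_drift(trace: FluorescenceTrace, degree: int = 6) -> FluorescenceTrace:
    """Subtract the least-squares polynomial fit of ``degree`` from the trace."""
    n = trace.n_samples
    if n <= degree + 1:
        raise ValueError(f"trace of {n} samples is too short for a degree-{degree} fit")
    t = trace.times
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (zero span)")
    fit = np.polynomial.Polynomial.fit(t, trace.samples, degree)
    return replace(trace, samples=trace.samples - fit(t))


def highpass_filter(x: np.ndarray, frame_rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth high-pass."""
    nyquist = frame_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyquist}) Hz")
    sos = signal.butter(2, cutoff, btype="highpass", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def tune_highpass(trace: FluorescenceTrace, params: DetectionParams) -> float:
    """Select the high-pass cutoff that best separates fast from slow activity.

    Spike amplitude varies across neurons, so the cutoff is adjusted per
    neuron.  The separation score of a candidate cutoff is the peak amplitude
    of the fast (filtered) band minus the peak amplitude of the slow residual
    (trace minus fast band); the candidate maximising the score wins, ties
    going to the lowest cutoff.  The trace should already be drift-removed.
    """
    candidates = sorted(params.highpass_cutoffs)
    if not candidates:
        raise ValueError("empty high-pass candidate list")
    best_cutoff, best_score = None, -np.inf
    for cutoff in candidates:
        fast = highpass_filter(trace.samples, trace.frame_rate, cutoff)
        slow = trace.samples - fast
        score = np.max(np.abs(fast)) - np.max(np.abs(slow))
        if score > best_score:
            best_cutoff, best_score = cutoff, score
    return float(best_cutoff)


def detect_spikes(
    trace: FluorescenceTrace,
    params: DetectionParams,
    *,
    threshold: float | None = None,
    align_to: np.ndarray | None = None,
) -> SpikeTrain:
    """Detect spikes as local maxima above a median-based threshold.

    ``threshold`` overrides the default
    ``threshold_k * median(|x|) / 0.6745``.  The trace is expected to be
    drift-removed and high-pass filtered.  An all-constant trace yields an
    empty train.

    High-pass filtering can nudge a peak by a frame when consecutive spike
    waveforms overlap; passing the unfiltered (drift-removed) samples as
    ``align_to`` re-centres each detected peak on the local maximum of that
    wideband signal within one frame.
    """
    x = trace.samples
    if threshold is None:
        sigma = np.median(np.abs(x)) / 0.6745
        threshold = params.threshold_k * sigma
    # A noiseless sparse trace has median 0; any strictly positive peak counts.
    height = threshold if threshold > 0 else np.finfo(float).tiny
    distance = max(1, int(round(params.refractory * trace.frame_rate)))
    # a prominence floor rejects noise bumps riding on the decaying flank of
    # a preceding spike without touching isolated spikes
    prominence = params.prominence_factor * height
    peaks, _ = signal.find_peaks(x, height=height, distance=distance,
                                 prominence=prominence if prominence > 0 else None)
    if align_to is not None and peaks.size:
        wide = np.asarray(align_to, dtype=float)
        if wide.shape != x.shape:
            raise ValueError("align_to must match the trace length")
        lo = np.maximum(peaks - 1, 0)
        shifted = np.array(
            [lo_i + int(np.argmax(wide[lo_i:p + 2])) for lo_i, p in zip(lo, peaks)]
        )
        # re-centring must not merge peaks closer than the refractory window
        keep = np.ones(shifted.size, dtype=bool)
        keep[1:] = np.diff(shifted) >= distance
        peaks = np.unique(shifted[keep])
    times = trace.t0 + peaks / trace.frame_rate
    return SpikeTrain(unit_id=trace.neuron_id, times=times, source="optical")


def process_trace(trace: FluorescenceTrace, params: DetectionParams | None = None) -> SpikeTrain:
    """Full per-neuron chain: drift removal, per-neuron cutoff, detection."""
    params = params or DetectionParams()
    detrended = remove_drift(trace, params.poly_degree)
    cutoff = tune_highpass(detrended, params)
    filtered = replace(
        detrended,
        samples=highpass_filter(detrended.samples, detrended.frame_rate, cutoff),
    )
    return detect_spikes(filtered, params, align_to=detrended.samples)


@dataclass
class MatchReport:
    """Outcome of validating a test spike train against a reference train.

    Unpaired test spikes are overdetections, unpaired reference spikes are
    underdetections; misdetections is their sum.  ``latencies`` are the
    signed test-minus-reference times of the paired spikes.
    """

    n_test: int
    n_reference: int
    over: int
    under: int
    latencies: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def misdetections(self) -> int:
        return self.over + self.under

    @property
    def n_matched(self) -> int:
        return self.n_test - self.over


def match_spike_trains(
    test: SpikeTrain, reference: SpikeTrain, tolerance: float
) -> MatchReport:
    """Greedy nearest-neighbour pairing of two spike trains within ``tolerance``.

    Candidate pairs within tolerance are taken in order of increasing
    absolute latency (ties broken by spike times), each spike used at most
    once.  The pairing is symmetric: swapping the trains swaps over/under
    counts and negates latencies.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    t, r = test.times, reference.times
    candidates = []
    for i, ti in enumerate(t):
        lo = np.searchsorted(r, ti - tolerance, side="left")
        hi = np.searchsorted(r, ti + tolerance, side="right")
        for j in range(lo, hi):
            candidates.append((abs(ti - r[j]), ti, r[j], i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_r: set[int] = set()
    latencies = []
    for _, ti, rj, i, j in candidates:
        if i in used_t or j in used_r:
            continue
        used_t.add(i)
        used_r.add(j)
        latencies.append(ti - rj)
    return MatchReport(
        n_test=t.size,
        n_reference=r.size,
        over=t.size - len(used_t),
        under=r.size - len(used_r),
        latencies=np.asarray(latencies),
    )


def firing_frequency(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in the half-open window divided by its duration (Hz)."""
    start, end = window
    duration = end - start
    if duration <= 0:
        raise ValueError("window duration must be positive")
    return train.count((start, end)) / duration


def mean_count(trains: Sequence[SpikeTrain], window: tuple[float, float]) -> float:
    """Trial-averaged spike count in a half-open window."""
    if not trains:
        raise ValueError("need at least one spike train")
    return float(np.mean([tr.count(window) for tr in trains]))
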