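"""Pyloric motor-pattern quantification from motor-nerve spike trains.

The pyloric rhythm is a spontaneous triphasic pattern of PD (pacemaker),
LP and PY bursts with a period near one second.  Four measures describe it:
within-burst firing frequency (spikes per burst divided by burst duration),
spikes per burst, burst duration (first to last spike of a burst), and the
cycle period (interval between successive PD burst onsets).  Sensory
effects are expressed as the normalised change between the 6-s windows
before and after stimulation,

    norm. Δ = (stim_POST − stim_PRE) / stim_PRE,

with the first pyloric cycle(s) after the stimulus excluded, since direct
(CoG-independent) sensory effects on the motor circuits dissipate within
about 1-2 seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

from .response_analysis import StimulusProtocol
from .trace_processing import SpikeTrain

__all__ = [
    "Burst",
    "BurstSeries",
    "MotorMetricChange",
    "segment_bursts",
    "cycle_period",
    "burst_metrics",
    "normalized_change",
    "analyze_condition",
    "METRICS",
]

METRICS = ("firing_frequency", "spikes_per_burst", "burst_duration", "cycle_period")


class Burst(NamedTuple):
    onset: float
    offset: float
    count: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BurstSeries:
    """Ordered, non-overlapping bursts of one motor unit."""

    unit_id: str
    bursts: list[Burst]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.bursts, self.bursts[1:]):
            if cur.onset <= prev.offset:
                raise ValueError("bursts must be ordered and non-overlapping")

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray([b.onset for b in self.bursts])

    def in_window(self, window: tuple[float, float]) -> "BurstSeries":
        """Bursts whose onset falls in the half-open window."""
        start, end = window
        return BurstSeries(
            self.unit_id, [b for b in self.bursts if start <= b.onset < end]
        )


def segment_bursts(
    train: SpikeTrain, gap_threshold: float = 0.2, min_spikes: int = 2
) -> BurstSeries:
    """Group spikes into bursts by an inter-spike-interval criterion.

    Consecutive spikes closer than ``gap_threshold`` (default 0.2 s, about a
    fifth of the pyloric period) share a burst; bursts with fewer than
    ``min_spikes`` spikes are discarded.  An empty train yields an empty
    series.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    times = train.times
    if times.size == 0:
        return BurstSeries(train.unit_id, [])
    breaks = np.flatnonzero(np.diff(times) > gap_threshold) + 1
    bursts = [
        Burst(float(chunk[0]), float(chunk[-1]), int(chunk.size))
        for chunk in np.split(times, breaks)
        if chunk.size >= min_spikes
    ]
    return BurstSeries(train.unit_id, bursts)


def cycle_period(
    pd_series: BurstSeries, window: tuple[float, float] | None = None
) -> float | None:
    """Mean interval between successive PD burst onsets; None if < 2 bursts."""
    series = pd_series if window is None else pd_series.in_window(window)
    if series.n_bursts < 2:
        return None
    return float(np.mean(np.diff(series.onsets)))


def burst_metrics(
    series: BurstSeries, window: tuple[float, float] | None = None
) -> dict[str, float | None]:
    """Mean firing frequency, spikes per burst and burst duration in a window.

    Firing frequency is the within-burst rate (count / duration) averaged
    over bursts; metrics are None when the window holds no (usable) burst.
    """
    sel = series if window is None else series.in_window(window)
    if sel.n_bursts == 0:
        return {"firing_frequency": None, "spikes_per_burst": None,
                "burst_duration": None}
    counts = np.asarray([b.count for b in sel.bursts], dtype=float)
    durations = np.asarray([b.duration for b in sel.bursts])
    usable = durations > 0
    freq = float(np.mean(counts[usable] / durations[usable])) if usable.any() else None
    return {
        "firing_frequency": freq,
        "spikes_per_burst": float(np.mean(counts)),
        "burst_duration": float(np.mean(durations)),
    }


def normalized_change(pre: float | None, post: float | None) -> float:
    """``(post - pre) / pre``; NaN (flagged undefined) when pre is 0 or missing."""
    if pre is None or post is None or pre == 0:
        return math.nan
    return (post - pre) / pre


@dataclass
class MotorMetricChange:
    """Pre/post values and normalised change of one metric for one unit."""

    unit_id: str
    metric: str
    pre: float | None
    post: float | None
    norm_delta: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.norm_delta)


def analyze_condition(
    trains: Mapping[str, SpikeTrain],
    protocol: StimulusProtocol,
    exclusion: float = 1.5,
    *,
    gap_threshold: float = 0.2,
    min_spikes: int = 2,
    pacemaker: str = "PD",
) -> list[MotorMetricChange]:
    """All four pyloric metrics per unit, pre versus post stimulation.

    ``stim_PRE`` is the protocol's pre-stimulus window; the post window is
    the protocol's ``stim_POST`` with bursts starting within ``exclusion``
    seconds of the stimulus offset dropped (first-cycle exclusion).  The
    cycle period is computed from the pacemaker unit only.  Metrics without
    bursts in a window are emitted with an undefined (NaN) change.
    """
    if exclusion < 0:
        raise ValueError("exclusion must be non-negative")
    post_window = protocol.stim_post
    post_start = max(post_window[0], protocol.offset + exclusion)
    if post_start >= post_window[1]:
        raise ValueError("exclusion window swallows the entire stim_POST window")
    pre_window = protocol.stim_pre
    results: list[MotorMetricChange] = []
    for unit_id in sorted(trains):
        series = segment_bursts(trains[unit_id], gap_threshold, min_spikes)
        pre = burst_metrics(series, pre_window)
        post = burst_metrics(series, (post_start, post_window[1]))
        for metric in ("firing_frequency", "spikes_per_burst", "burst_duration"):
            results.append(
                MotorMetricChange(
                    unit_id, metric, pre[metric], post[metric],
                    normalized_change(pre[metric], post[metric]),
                )
            )
        if unit_id == pacemaker:
            p_pre = cycle_period(series, pre_window)
            p_post = cycle_period(series, (post_start, post_window[1]))
            results.append(
                MotorMetricChange(
                    unit_id, "cycle_period", p_pre, p_post,
                    normalized_change(p_pre, p_post),
                )
            )
    return results
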