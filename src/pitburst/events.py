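"""Event detection, spike/burst classification and summary statistics.

An event is a maximal contiguous excursion of the membrane potential
above a detection threshold (-45 mV throughout).  Events shorter than
100 ms with no depolarised-plateau oscillations are spikes; anything
longer, or any event with oscillations, is a burst.  The bursting
fraction (BF) is the fraction of detected events that are bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import DETECTION_THRESHOLD, SimulationConfig, Trace, simulate

__all__ = [
    "Event",
    "EventSummary",
    "detect_events",
    "count_oscillations",
    "classify_event",
    "summarize",
    "collect_events",
]

#: Spike/burst duration boundary (ms).
BURST_DURATION_MS = 100.0
#: Minimum prominence (mV) for a post-peak local maximum to count as an
#: oscillation; separates genuine plateau oscillations (several mV) from
#: sub-mV channel-noise flicker.
OSCILLATION_PROMINENCE_MV = 1.0
#: Minimum separation (ms) between counted oscillation maxima.
OSCILLATION_SEPARATION_MS = 1.0
#: Events shorter than this (ms) are threshold-crossing flicker — noise
#: re-crossing the detection threshold during an up- or downstroke — not
#: genuine depolarisation events; the shortest real spikes last ~50 ms.
MIN_EVENT_DURATION_MS = 5.0


@dataclass
class Event:
    """One above-threshold excursion."""

    t_start: float          # ms, first supra-threshold sample
    t_end: float            # ms, last supra-threshold sample
    V_max: float            # mV
    t_Vmax: float           # ms
    n_oscillations: int
    label: str = field(init=False)      # 'spike' | 'burst'

    def __post_init__(self):
        self.label = classify_event_fields(self.duration, self.n_oscillations)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def classify_event_fields(duration: float, n_oscillations: int,
                          burst_ms: float = BURST_DURATION_MS) -> str:
    return ("spike"
            if duration < burst_ms and n_oscillations == 0
            else "burst")


def classify_event(e: Event) -> str:
    """Spike iff duration < 100 ms and no oscillations; else burst."""
    return classify_event_fields(e.duration, e.n_oscillations)


def count_oscillations(segment: np.ndarray, dt: float,
                       prominence: float = OSCILLATION_PROMINENCE_MV,
                       min_separation: float = OSCILLATION_SEPARATION_MS) -> int:
    """Count depolarised-plateau oscillations in one event's V samples.

    Oscillations are strict local maxima occurring after the event's
    global maximum whose prominence is at least ``prominence`` mV (so V
    must dip and recover around each) and which are separated by at
    least ``min_separation`` ms.  A monotone rise-then-fall gives 0.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 3:
        return 0
    i_max = int(np.argmax(segment))
    tail = segment[i_max:]
    if tail.size < 3:
        return 0
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(tail, prominence=prominence, distance=distance)
    return int(len(peaks))


def detect_events(trace: Trace, threshold: float = DETECTION_THRESHOLD,
                  transient_discard: Optional[float] = None,
                  burst_ms: float = BURST_DURATION_MS,
                  min_duration: float = MIN_EVENT_DURATION_MS) -> List[Event]:
    """Detect and classify events in a voltage trace.

    The first ``transient_discard`` ms (defaulting to the value carried
    on the trace) are ignored, and events truncated by either end of the
    analysis window are dropped since their duration is unknown.
    Excursions shorter than ``min_duration`` are discarded as threshold
    flicker (set it to 0 to keep every crossing).
    """
    if len(trace) == 0:
        return []
    discard = (trace.transient_discard if transient_discard is None
               else transient_discard)
    dt = trace.sample_dt
    i0 = int(np.ceil(discard / dt)) if discard > 0 else 0
    V = trace.V[i0:]
    if V.size == 0:
        return []
    t_offset = i0 * dt

    above = V > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)   # last supra-threshold index of a run
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [V.size - 1]))

    events: List[Event] = []
    for a, b in zip(starts, ends):
        if a == 0 or b == V.size - 1:
            continue  # truncated by the window boundary
        if (b - a) * dt < min_duration:
            continue  # threshold flicker, not a depolarisation event
        seg = V[a:b + 1]
        i_rel = int(np.argmax(seg))
        e = Event(
            t_start=t_offset + a * dt,
            t_end=t_offset + b * dt,
            V_max=float(seg[i_rel]),
            t_Vmax=t_offset + (a + i_rel) * dt,
            n_oscillations=count_oscillations(seg, dt),
        )
        if burst_ms != BURST_DURATION_MS:
            e.label = classify_event_fields(e.duration, e.n_oscillations, burst_ms)
        events.append(e)
    return events


@dataclass
class EventSummary:
    """Counts, bursting fraction and per-label V_max statistics."""

    n_events: int
    n_spikes: int
    n_bursts: int
    bf: float                       # NaN when no events
    bf_se: float                    # binomial standard error of bf
    spike_vmax_mean: float
    spike_vmax_std: float
    burst_vmax_mean: float
    burst_vmax_std: float
    durations: np.ndarray
    spike_vmax: np.ndarray
    burst_vmax: np.ndarray

    @property
    def has_events(self) -> bool:
        return self.n_events > 0

    def duration_histogram(self, bin_ms: float = 10.0):
        """Event-duration histogram as (counts, bin_edges)."""
        if self.n_events == 0:
            return np.array([]), np.array([])
        hi = max(self.durations.max(), bin_ms)
        edges = np.arange(0.0, hi + bin_ms, bin_ms)
        counts, edges = np.histogram(self.durations, bins=edges)
        return counts, edges


def _mean_std(x: np.ndarray):
    if x.size == 0:
        return np.nan, np.nan
    return float(np.mean(x)), float(np.std(x))


def summarize(events: Sequence[Event]) -> EventSummary:
    """Summarise a list of events; BF is NaN (flagged) when empty."""
    n = len(events)
    spikes = np.array([e.V_max for e in events if e.label == "spike"])
    bursts = np.array([e.V_max for e in events if e.label == "burst"])
    n_bursts = bursts.size
    if n > 0:
        bf = n_bursts / n
        bf_se = float(np.sqrt(bf * (1.0 - bf) / n))
    else:
        bf, bf_se = np.nan, np.nan
    s_mean, s_std = _mean_std(spikes)
    b_mean, b_std = _mean_std(bursts)
    return EventSummary(
        n_events=n, n_spikes=n - n_bursts, n_bursts=n_bursts,
        bf=bf, bf_se=bf_se,
        spike_vmax_mean=s_mean, spike_vmax_std=s_std,
        burst_vmax_mean=b_mean, burst_vmax_std=b_std,
        durations=np.array([e.duration for e in events]),
        spike_vmax=spikes, burst_vmax=bursts,
    )


def collect_events(p, cfg: SimulationConfig, min_events: int = 200,
                   threshold: float = DETECTION_THRESHOLD,
                   max_chunks: int = 100) -> List[Event]:
    """Accumulate events over repeated simulations until ``min_events``.

    BF is defined over a long recording, so stochastic estimates need
    enough events; this driver runs ``cfg``-sized chunks with distinct
    sub-seeds (derived from ``cfg.seed``) until the target is reached.
    Deterministic runs stop after one chunk (further chunks repeat the
    same periodic solution).
    """
    events: List[Event] = []
    for chunk in range(max_chunks):
        sub_seed = int(np.random.SeedSequence([cfg.seed, chunk]
                                              ).generate_state(1)[0] % (2 ** 31))
        trace = simulate(p, cfg.replace(seed=sub_seed))
        events.extend(detect_events(trace, threshold))
        if len(events) >= min_events or not cfg.noise.any:
            break
    return events
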