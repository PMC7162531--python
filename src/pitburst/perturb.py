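"""Threshold-triggered single-channel perturbations.

The protocol probes when, during an action potential, opening or
closing channels converts spikes to bursts (or back).  A perturbation
time is specified as an offset from the peak of the deterministic spike
waveform; the waveform maps that offset onto a trigger potential V*,
and during each event the perturbation fires at most once — the first
time V rises above V* (offsets before the peak) or, once past the
peak, first drops below it (offsets after the peak).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import EventSummary, detect_events, summarize
from .model_core import DEFAULT_PARAMS, ModelParameters
from .simulate import (
    DETECTION_THRESHOLD,
    NoiseFlags,
    PerturbationSpec,
    SimulationConfig,
    Trace,
    simulate,
)

__all__ = [
    "deterministic_reference_trace",
    "offset_to_threshold",
    "run_perturbed",
    "bf_vs_offset_curve",
]


def deterministic_reference_trace(p: ModelParameters = DEFAULT_PARAMS,
                                  duration: float = 5000.0) -> Trace:
    """Deterministic run providing the reference spike waveform."""
    cfg = SimulationConfig(duration=duration, noise=NoiseFlags.none(),
                           transient_discard=1000.0)
    return simulate(p, cfg)


def offset_to_threshold(det_trace: Trace, t_offset: float,
                        threshold: float = DETECTION_THRESHOLD,
                        ) -> Tuple[float, str]:
    """Map a time offset from the deterministic peak onto (V*, direction).

    Negative offsets lie on the rising phase (trigger: first upward
    crossing of V*), positive offsets on the falling phase (trigger:
    first downward crossing after the peak); offset 0 triggers at the
    peak itself, on the rising side.  The waveform is strictly monotone
    on each side of the peak, so each admissible offset maps to a unique
    V*.  Offsets outside the reference event are rejected.
    """
    events = detect_events(det_trace, threshold)
    if not events:
        raise ValueError("reference trace contains no complete events")
    ref = events[len(events) // 2]
    t_target = ref.t_Vmax + t_offset
    if not ref.t_start <= t_target <= ref.t_end:
        raise ValueError(
            f"offset {t_offset} ms falls outside the reference event "
            f"([{ref.t_start - ref.t_Vmax:.2f}, {ref.t_end - ref.t_Vmax:.2f}] ms "
            "around the peak)")
    idx = int(round(t_target / det_trace.sample_dt))
    v_star = float(det_trace.V[idx])
    return v_star, ("rising" if t_offset <= 0 else "falling")


def run_perturbed(p: ModelParameters, cfg: SimulationConfig,
                  spec: PerturbationSpec, min_events: int = 0,
                  max_chunks: int = 100) -> Tuple[EventSummary, int]:
    """Simulate with a perturbation; returns (summary, n applied).

    All detected events enter the summary whether or not they reached
    the trigger (events that never cross V* count at their unperturbed
    fate).  With ``min_events`` > 0, chunks with distinct sub-seeds are
    accumulated as in :func:`pitburst.events.collect_events`.
    """
    events: List = []
    n_applied = 0
    chunks = max_chunks if min_events > 0 else 1
    for chunk in range(chunks):
        sub_seed = int(np.random.SeedSequence([cfg.seed, chunk]
                                              ).generate_state(1)[0] % (2 ** 31))
        trace = simulate(p, cfg.replace(seed=sub_seed,
                                        perturbation=spec))
        events.extend(detect_events(trace))
        n_applied += trace.n_perturbations
        if len(events) >= min_events or not cfg.noise.any:
            break
    return summarize(events), n_applied


def bf_vs_offset_curve(p: ModelParameters, cfg: SimulationConfig,
                       channel: str, q: int, offsets: Sequence[float],
                       det_trace: Optional[Trace] = None,
                       min_events: int = 300) -> pd.DataFrame:
    """BF as a function of perturbation timing, plus a baseline row.

    Each offset runs with an independent seed stream; the first row
    (offset = NaN, q = 0) is the unperturbed baseline under the same
    event budget.
    """
    if det_trace is None:
        det_trace = deterministic_reference_trace(p)
    rows = []

    baseline, _ = run_perturbed(
        p, cfg.replace(seed=int(np.random.SeedSequence([cfg.seed, 991]
                                                       ).generate_state(1)[0] % 2 ** 31)),
        PerturbationSpec(channel=channel, q=0, v_star=0.0, direction="rising"),
        min_events=min_events)
    rows.append(dict(offset_ms=np.nan, v_star=np.nan, direction="baseline",
                     q=0, n_events=baseline.n_events, n_applied=0,
                     bf=baseline.bf, bf_se=baseline.bf_se))

    for i, off in enumerate(offsets):
        v_star, direction = offset_to_threshold(det_trace, off)
        spec = PerturbationSpec(channel=channel, q=q, v_star=v_star,
                                direction=direction)
        sub = cfg.replace(seed=int(np.random.SeedSequence([cfg.seed, i]
                                                          ).generate_state(1)[0] % 2 ** 31))
        summary, n_applied = run_perturbed(p, sub, spec, min_events=min_events)
        rows.append(dict(offset_ms=off, v_star=v_star, direction=direction,
                         q=q, n_events=summary.n_events, n_applied=n_applied,
                         bf=summary.bf, bf_se=summary.bf_se))
    return pd.DataFrame(rows)
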