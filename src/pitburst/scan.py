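"""Randomised parameter-robustness scan.

Seven parameters — the four single-channel conductances, the leak
conductance and reversal potential, and the calcium extrusion rate —
are redrawn uniformly within ±50% of their defaults.  Each sampled
cell is simulated with full channel noise and its voltage behaviour
classified as depolarised, hyperpolarised, noisy steady state or
event-containing; event-containing cells are subclassified by bursting
fraction regime.  Helpers also test, per sampled cell, whether BF
against N_BK is sigmoidal and estimate its large-N_BK limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import Event, collect_events, detect_events, summarize
from .model_core import DEFAULT_PARAMS, ModelParameters
from .simulate import SimulationConfig, Trace, simulate

__all__ = [
    "SCANNED_PARAMETERS",
    "ScanRecord",
    "sample_parameter_set",
    "classify_behaviour",
    "regime_from_bf",
    "sigmoidality_check",
    "run_scan",
    "bf_vs_nbk",
    "large_nbk_scan",
]

#: Parameters redrawn by the scan, in draw order.
SCANNED_PARAMETERS = ("g1_Ca", "g1_K", "g1_SK", "g1_BK", "g_l", "V_l", "k_c")

BEHAVIOURS = ("depolarised", "hyperpolarised", "noisy_steady_state",
              "event_containing")
REGIMES = ("pure_spiking", "almost_pure_spiking", "mixed",
           "almost_pure_bursting", "pure_bursting")

#: Noisy-steady-state rule (iii): mean event duration at least this many
#: times the mean inter-event interval means the "events" are really a
#: flickering plateau rather than discrete excursions.
DURATION_GAP_RATIO = 5.0


def _default_scan_config(seed: int = 0) -> SimulationConfig:
    # 10 s per cell with a 1 s transient: enough events to classify the
    # behaviour category without resolving BF precisely.
    return SimulationConfig(duration=10000.0, transient_discard=1000.0,
                            seed=seed, record_stride=5)


@dataclass
class ScanRecord:
    """One sampled parameter set and its classified behaviour."""

    index: int
    seed: int
    params: Dict[str, float]
    behaviour: str
    n_events: int = 0
    bf: float = np.nan
    bf_se: float = np.nan
    regime: Optional[str] = None
    error: Optional[str] = None


def sample_parameter_set(base: ModelParameters,
                         rng: np.random.Generator) -> ModelParameters:
    """Redraw the seven scanned parameters uniformly on ±50% of default.

    Channel counts stay at base; total conductances are recomputed from
    the redrawn single-channel conductances.
    """
    changes = {name: getattr(base, name) * rng.uniform(0.5, 1.5)
               for name in SCANNED_PARAMETERS}
    for ch in ("Ca", "K", "SK", "BK"):
        changes[f"g_{ch}"] = changes[f"g1_{ch}"] * base.count(ch) / 1000.0
    return base.replace(**changes)


def classify_behaviour(trace: Trace, events: Optional[Sequence[Event]] = None,
                       duration_gap_ratio: float = DURATION_GAP_RATIO) -> str:
    """Classify post-transient voltage behaviour into one of four types.

    Depolarised/hyperpolarised: V range below 10 mV, with the mid-range
    (max+min)/2 above/below -50 mV.  Noisy steady state: no complete
    events, or V range in [10, 35) mV, or mean event duration much
    longer (``duration_gap_ratio`` times) than the mean inter-event
    interval.  Everything else is event-containing.
    """
    dt = trace.sample_dt
    i0 = int(np.ceil(trace.transient_discard / dt))
    V = trace.V[i0:]
    if V.size == 0:
        raise ValueError("no samples after the transient window")
    v_min, v_max = float(V.min()), float(V.max())
    v_range = v_max - v_min
    if v_range < 10.0:
        return "depolarised" if 0.5 * (v_max + v_min) > -50.0 else "hyperpolarised"
    if events is None:
        events = detect_events(trace)
    if len(events) == 0:
        return "noisy_steady_state"
    if 10.0 <= v_range < 35.0:
        return "noisy_steady_state"
    durations = np.array([e.duration for e in events])
    if len(events) >= 2:
        starts = np.array([e.t_start for e in events])
        ends = np.array([e.t_end for e in events])
        mean_gap = float(np.mean(starts[1:] - ends[:-1]))
    else:
        window = trace.t[-1] - i0 * dt
        mean_gap = max(window - float(durations.sum()), dt)
    if float(durations.mean()) >= duration_gap_ratio * mean_gap:
        return "noisy_steady_state"
    return "event_containing"


def regime_from_bf(bf: float) -> str:
    """BF regime with the exact boundary conventions:
    0 | (0, 0.05) | [0.05, 0.95] | (0.95, 1) | 1."""
    if not 0.0 <= bf <= 1.0:
        raise ValueError(f"BF = {bf} outside [0, 1]")
    if bf == 0.0:
        return "pure_spiking"
    if bf < 0.05:
        return "almost_pure_spiking"
    if bf <= 0.95:
        return "mixed"
    if bf < 1.0:
        return "almost_pure_bursting"
    return "pure_bursting"


def sigmoidality_check(bf_series: Sequence[float],
                       se: Optional[Sequence[float]] = None,
                       late_decrease_allowance: float = 0.1,
                       se_multiple: float = 2.0,
                       require_range: Optional[float] = None) -> bool:
    """Is BF against increasing N_BK sigmoidal?

    True iff the series is non-decreasing up to its maximum within
    noise tolerance (dips up to ``se_multiple`` standard errors are
    allowed) and any decrease after the maximum stays within
    ``late_decrease_allowance`` (small late declines occur even at the
    default parameters).  If ``require_range`` is set, a series whose
    BF range is below it is ineligible and raises rather than returning
    False.
    """
    bf = np.asarray(bf_series, dtype=float)
    if bf.size < 2:
        raise ValueError("need at least two BF values")
    errs = np.zeros_like(bf) if se is None else np.asarray(se, dtype=float)
    if require_range is not None and bf.max() - bf.min() < require_range:
        raise ValueError(
            f"BF range {bf.max() - bf.min():.3f} below the selection floor "
            f"{require_range}; series ineligible for the sigmoidality check")
    i_max = int(np.argmax(bf))
    for j in range(i_max):
        tol = se_multiple * max(errs[j], errs[j + 1])
        if bf[j + 1] < bf[j] - tol:
            return False
    if i_max < bf.size - 1:
        if bf[i_max] - bf[i_max:].min() > late_decrease_allowance:
            return False
    return True


def _child_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % 2 ** 31)


def run_scan(n_sets: int, seed: int,
             base: ModelParameters = DEFAULT_PARAMS,
             cfg: Optional[SimulationConfig] = None,
             ) -> Tuple[Dict[str, float], pd.DataFrame]:
    """Sample and classify ``n_sets`` parameter sets.

    Returns (summary, records): summary holds the behaviour-category
    fractions (summing to 1) and regime fractions among event-containing
    sets; records has one row per set.  Fully reproducible from
    ``seed``; per-set simulation failures are recorded, not fatal.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be at least 1")
    cfg = cfg or _default_scan_config()
    records: List[ScanRecord] = []
    for i in range(n_sets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        p_i = sample_parameter_set(base, rng)
        sim_seed = _child_seed(seed, i, 1)
        rec = ScanRecord(index=i, seed=sim_seed,
                         params={k: getattr(p_i, k) for k in SCANNED_PARAMETERS},
                         behaviour="error")
        try:
            trace = simulate(p_i, cfg.replace(seed=sim_seed))
            events = detect_events(trace)
            rec.behaviour = classify_behaviour(trace, events)
            if rec.behaviour == "event_containing":
                s = summarize(events)
                rec.n_events, rec.bf, rec.bf_se = s.n_events, s.bf, s.bf_se
                rec.regime = regime_from_bf(s.bf)
        except (FloatingPointError, ValueError) as exc:  # recorded, not fatal
            rec.error = str(exc)
        records.append(rec)

    rows = pd.DataFrame([dict(index=r.index, seed=r.seed, **r.params,
                              behaviour=r.behaviour, n_events=r.n_events,
                              bf=r.bf, bf_se=r.bf_se, regime=r.regime,
                              error=r.error) for r in records])
    n = len(records)
    summary = {f"frac_{b}": sum(r.behaviour == b for r in records) / n
               for b in BEHAVIOURS}
    summary["frac_error"] = sum(r.behaviour == "error" for r in records) / n
    n_ec = sum(r.behaviour == "event_containing" for r in records)
    for reg in REGIMES:
        summary[f"frac_{reg}"] = (sum(r.regime == reg for r in records) / n_ec
                                  if n_ec else np.nan)
    return summary, rows


def bf_vs_nbk(p: ModelParameters, nbk_values: Sequence[int],
              cfg: SimulationConfig, min_events: int = 0) -> pd.DataFrame:
    """BF (and behaviour class) across BK channel counts at fixed g1_BK."""
    rows = []
    for j, nbk in enumerate(nbk_values):
        p_j = p.with_counts(BK=int(nbk))
        sub = cfg.replace(seed=_child_seed(cfg.seed, j))
        if min_events > 0:
            events = collect_events(p_j, sub, min_events=min_events)
            trace = None
            behaviour = "event_containing" if events else "noisy_steady_state"
        else:
            trace = simulate(p_j, sub)
            events = detect_events(trace)
            behaviour = classify_behaviour(trace, events)
        s = summarize(events)
        rows.append(dict(N_BK=int(nbk), g_BK=p_j.g_BK, behaviour=behaviour,
                         n_events=s.n_events, bf=s.bf, bf_se=s.bf_se))
    return pd.DataFrame(rows)


def large_nbk_scan(n_selected: int, seed: int,
                   base: ModelParameters = DEFAULT_PARAMS,
                   nbk_grid: Sequence[int] = (2, 5, 20, 100),
                   cfg: Optional[SimulationConfig] = None,
                   min_events_large: int = 200,
                   bf_range_floor: float = 0.2,
                   max_candidates: int = 400,
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate the large-N_BK BF limit across random parameter sets.

    Candidate sets are drawn as in :func:`run_scan`; a candidate is
    selected when every N_BK on ``nbk_grid`` is event-containing and the
    BF range across the grid is at least ``bf_range_floor`` (the same
    eligibility filter used for the sigmoidality analysis).  For each
    selected set, BF at the largest grid count is re-estimated from at
    least ``min_events_large`` events.  Stops after ``n_selected``
    selections or ``max_candidates`` candidates.

    Returns (selected, candidates) tables; ``selected`` includes the
    refined ``bf_large`` estimates and the per-set sigmoidality flag.
    """
    cfg = cfg or _default_scan_config()
    nbk_grid = sorted(int(n) for n in nbk_grid)
    nbk_large = nbk_grid[-1]
    cand_rows = []
    sel_rows = []
    for i in range(max_candidates):
        if len(sel_rows) >= n_selected:
            break
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        p_i = sample_parameter_set(base, rng)
        sub = cfg.replace(seed=_child_seed(seed, i, 7))
        try:
            grid = bf_vs_nbk(p_i, nbk_grid, sub)
        except (FloatingPointError, ValueError) as exc:
            cand_rows.append(dict(index=i, selected=False, reason=str(exc)))
            continue
        all_ec = bool((grid["behaviour"] == "event_containing").all())
        bf_range = float(grid["bf"].max() - grid["bf"].min()) if all_ec else np.nan
        selected = all_ec and bf_range >= bf_range_floor
        cand_rows.append(dict(index=i, selected=selected,
                              all_event_containing=all_ec, bf_range=bf_range,
                              reason=None))
        if not selected:
            continue
        p_large = p_i.with_counts(BK=nbk_large)
        events = collect_events(
            p_large, sub.replace(seed=_child_seed(seed, i, 11)),
            min_events=min_events_large)
        s = summarize(events)
        sigmoidal = sigmoidality_check(grid["bf"].to_numpy(),
                                       grid["bf_se"].to_numpy())
        sel_rows.append(dict(index=i, **{k: getattr(p_i, k)
                                         for k in SCANNED_PARAMETERS},
                             bf_range=bf_range, sigmoidal=sigmoidal,
                             n_events_large=s.n_events,
                             bf_large=s.bf, bf_large_se=s.bf_se))
    return pd.DataFrame(sel_rows), pd.DataFrame(cand_rows)
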