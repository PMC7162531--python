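"""Cell-size scaling and size-dependent bursting.

Cell size means diameter; the base cell (lam = 1) has diameter 10 µm,
so radius R = 5 * lam µm.  Scaling the radius by lam scales membrane
area quantities (capacitance, conductances, channel counts) by lam² and
volume quantities by lam³, giving the full transformation

    C -> lam² C,  g_X -> lam² g_X,  g_l -> lam² g_l,
    alpha -> alpha / lam³,  k_c -> k_c / lam,  N_X -> lam² N_X.

Because capacitance and conductances scale together, the voltage
equation is invariant; the only dynamical effect on the six state
variables is a 1/lam factor on the calcium equation, equivalently the
reduced transformation f_c -> f_c / lam with N_X -> lam² N_X at fixed
total conductances.  Larger cells therefore have slower effective
calcium dynamics, longer events, and more bursting.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .events import collect_events, detect_events, summarize
from .model_core import CHANNEL_TYPES, DEFAULT_PARAMS, ModelParameters
from .simulate import NoiseFlags, SimulationConfig, simulate

__all__ = [
    "scale_full",
    "scale_reduced",
    "admissible_sizes",
    "critical_gbk",
    "critical_lambda",
    "bf_vs_size",
    "bf_vs_density",
]

_BASE_RADIUS_UM = 5.0


def _scaled_counts(p: ModelParameters, lam: float, stochastic: bool) -> dict:
    """lam²-scaled channel counts; non-integral counts are rejected in
    stochastic mode and rounded (with the single-channel conductance
    rebalanced by the caller) otherwise."""
    counts = {}
    for ch in CHANNEL_TYPES:
        scaled = lam * lam * p.count(ch)
        n = int(round(scaled))
        if stochastic and abs(scaled - n) > 1e-9 * max(1.0, scaled):
            raise ValueError(
                f"lam = {lam} gives non-integer {ch} channel count {scaled}; "
                "see admissible_sizes()")
        if stochastic and n < 1:
            raise ValueError(
                f"lam = {lam} leaves no {ch} channels; cell too small for "
                "stochastic simulation")
        counts[ch] = max(n, 1) if not stochastic else n
    return counts


def scale_full(p: ModelParameters, lam: float,
               stochastic: bool = False) -> ModelParameters:
    """Full size transformation: area terms by lam², alpha by 1/lam³,
    k_c by 1/lam, counts by lam²; single-channel conductances unchanged
    (up to count rounding in deterministic mode)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    lam2 = lam * lam
    counts = _scaled_counts(p, lam, stochastic)
    changes = dict(
        C=p.C * lam2, g_l=p.g_l * lam2,
        alpha=p.alpha / lam ** 3, k_c=p.k_c / lam,
    )
    for ch in CHANNEL_TYPES:
        g_new = p.total_conductance(ch) * lam2
        changes[f"g_{ch}"] = g_new
        changes[f"N_{ch}"] = counts[ch]
        changes[f"g1_{ch}"] = 1000.0 * g_new / counts[ch]
    return p.replace(**changes)


def scale_reduced(p: ModelParameters, lam: float,
                  stochastic: bool = False) -> ModelParameters:
    """Reduced, trajectory-equivalent transformation: f_c -> f_c/lam and
    N_X -> lam² N_X at fixed total conductances (so single-channel
    conductances shrink by 1/lam²)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    counts = _scaled_counts(p, lam, stochastic)
    changes = {"f_c": p.f_c / lam}
    for ch in CHANNEL_TYPES:
        changes[f"N_{ch}"] = counts[ch]
        changes[f"g1_{ch}"] = 1000.0 * p.total_conductance(ch) / counts[ch]
    return p.replace(**changes)


def admissible_sizes(base_counts: Sequence[int] = (200, 640, 200, 5),
                     lam_max: float = 3.5) -> np.ndarray:
    """Sizes lam = sqrt(k/5) (k a positive integer) at which lam² times
    every base channel count is an integer without rounding."""
    k_max = int(np.floor(5.0 * lam_max ** 2))
    ks = [k for k in range(1, k_max + 1)
          if all((k * n) % 5 == 0 for n in base_counts)]
    return np.sqrt(np.array(ks) / 5.0)


def _deterministic_bf(p: ModelParameters, duration: float = 11000.0) -> float:
    cfg = SimulationConfig(duration=duration, noise=NoiseFlags.none(),
                           transient_discard=1000.0, record_stride=5)
    events = detect_events(simulate(p, cfg))
    if not events:
        return np.nan
    return summarize(events).bf


def critical_gbk(p: ModelParameters, lam: float = 1.0,
                 bracket: Tuple[float, float] = (0.2, 1.2),
                 tol: float = 1e-3) -> Tuple[float, float]:
    """Critical total BK conductance g_BK* (nS) of a size-lam cell, and
    the corresponding membrane density g_BK*/(4 pi R²) in nS/µm².

    Deterministic bursting switches on as a step, so the transition is
    located by bisection on the first g_BK with BF > 0.5.  ``bracket``
    is in base-cell (lam = 1) conductance units and is scaled by lam²
    internally, since total conductances grow with membrane area.
    """
    p_scaled = scale_full(p, lam)
    lam2 = lam * lam

    def is_bursting(g_phys: float) -> bool:
        bf = _deterministic_bf(p_scaled.replace(g_BK=g_phys))
        if np.isnan(bf):
            raise RuntimeError(f"no events at g_BK = {g_phys:.4f} nS (lam = {lam})")
        return bf > 0.5

    lo, hi = bracket[0] * lam2, bracket[1] * lam2
    if is_bursting(lo) or not is_bursting(hi):
        raise RuntimeError(
            f"no spiking-to-bursting transition inside bracket {bracket} at lam = {lam}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_bursting(mid):
            hi = mid
        else:
            lo = mid
    g_star = 0.5 * (lo + hi)
    radius = _BASE_RADIUS_UM * lam
    return g_star, g_star / (4.0 * np.pi * radius ** 2)


def critical_lambda(p: ModelParameters = DEFAULT_PARAMS,
                    bracket: Tuple[float, float] = (1.0, 2.0),
                    tol: float = 2e-3) -> float:
    """Smallest size factor at which the deterministic model bursts.

    Applies the reduced scaling (f_c -> f_c/lam) and bisects lam for the
    BF 0 -> 1 step; with defaults (g_BK = 0.5 nS at lam = 1) the
    transition sits near lam = 1.35.
    """

    def is_bursting(lam: float) -> bool:
        bf = _deterministic_bf(scale_reduced(p, lam))
        if np.isnan(bf):
            raise RuntimeError(f"no events at lam = {lam:.4f}")
        return bf > 0.5

    lo, hi = bracket
    if is_bursting(lo) or not is_bursting(hi):
        raise RuntimeError(f"no spiking-to-bursting transition inside {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_bursting(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bf_vs_size(p: ModelParameters, lams: Sequence[float],
               cfg: Optional[SimulationConfig] = None,
               min_events: int = 200) -> pd.DataFrame:
    """Bursting fraction against cell size (stochastic unless cfg says
    otherwise); lams must be admissible in stochastic mode."""
    cfg = cfg or SimulationConfig(duration=11000.0, record_stride=5)
    rows = []
    for i, lam in enumerate(lams):
        p_lam = scale_reduced(p, lam, stochastic=cfg.noise.any)
        sub = cfg.replace(seed=int(np.random.SeedSequence([cfg.seed, i]
                                                          ).generate_state(1)[0] % 2 ** 31))
        events = collect_events(p_lam, sub, min_events=min_events)
        s = summarize(events)
        rows.append(dict(lam=lam, n_events=s.n_events, bf=s.bf, bf_se=s.bf_se,
                         mean_duration_ms=float(np.mean(s.durations))
                         if s.n_events else np.nan))
    return pd.DataFrame(rows)


def bf_vs_density(p: ModelParameters, lam: float, densities: Sequence[float],
                  cfg: Optional[SimulationConfig] = None,
                  min_events: int = 200) -> pd.DataFrame:
    """Bursting fraction against BK conductance area density (nS/µm²)
    for a cell of size lam; counts snap to the nearest integer."""
    cfg = cfg or SimulationConfig(duration=11000.0, record_stride=5)
    radius = _BASE_RADIUS_UM * lam
    area = 4.0 * np.pi * radius ** 2
    p_lam = scale_full(p, lam, stochastic=cfg.noise.any)
    rows = []
    for i, dens in enumerate(densities):
        g_bk = dens * area
        p_i = p_lam.with_total_conductance("BK", g_bk, snap_count=True)
        if cfg.noise.bk and p_i.N_BK < 1:
            rows.append(dict(lam=lam, density=dens, g_BK=g_bk, n_events=0,
                             bf=np.nan, bf_se=np.nan))
            continue
        sub = cfg.replace(seed=int(np.random.SeedSequence([cfg.seed, 1000 + i]
                                                          ).generate_state(1)[0] % 2 ** 31))
        events = collect_events(p_i, sub, min_events=min_events)
        s = summarize(events)
        rows.append(dict(lam=lam, density=dens, g_BK=p_i.g_BK,
                         n_events=s.n_events, bf=s.bf, bf_se=s.bf_se))
    return pd.DataFrame(rows)
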