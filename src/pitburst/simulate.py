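"""Fixed-step Euler simulation of the full model.

Supports per-channel-type noise flags (any mix of stochastic and
deterministic gating), sigma-scaling of channel numbers at fixed total
conductance, seeded bit-reproducible runs, and an optional
threshold-triggered perturbation applied at most once per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel
from .model_core import (
    CHANNEL_TYPES,
    CellState,
    DEFAULT_PARAMS,
    ModelParameters,
    deterministic_derivatives,
    membrane_currents,
    steady_state_activations,
)

__all__ = [
    "NoiseFlags",
    "PerturbationSpec",
    "SimulationConfig",
    "Trace",
    "apply_sigma",
    "auto_initial_state",
    "euler_step",
    "simulate",
]

#: Detection threshold (mV) shared by event analysis and perturbation triggers.
DETECTION_THRESHOLD = -45.0


@dataclass(frozen=True)
class NoiseFlags:
    """Which channel types open and close stochastically."""

    ca: bool = True
    k: bool = True
    sk: bool = True
    bk: bool = True

    @classmethod
    def all_channels(cls) -> "NoiseFlags":
        return cls(True, True, True, True)

    @classmethod
    def none(cls) -> "NoiseFlags":
        return cls(False, False, False, False)

    @classmethod
    def bk_only(cls) -> "NoiseFlags":
        return cls(False, False, False, True)

    @classmethod
    def non_bk(cls) -> "NoiseFlags":
        return cls(True, True, True, False)

    @classmethod
    def parse(cls, text: str) -> "NoiseFlags":
        """Parse CLI-style specs: 'none', 'bk-only', 'non-bk', 'all' or 'ca,k'."""
        text = text.strip().lower()
        named = {
            "all": cls.all_channels(),
            "none": cls.none(),
            "bk-only": cls.bk_only(),
            "non-bk": cls.non_bk(),
        }
        if text in named:
            return named[text]
        wanted = {t.strip() for t in text.split(",") if t.strip()}
        valid = {"ca", "k", "sk", "bk"}
        if not wanted <= valid:
            raise ValueError(f"unknown channel types in noise spec {text!r}")
        return cls("ca" in wanted, "k" in wanted, "sk" in wanted, "bk" in wanted)

    def as_tuple(self):
        """Booleans in the canonical (Ca, K, SK, BK) order."""
        return (self.ca, self.k, self.sk, self.bk)

    def is_stochastic(self, channel: str) -> bool:
        return dict(zip(CHANNEL_TYPES, self.as_tuple()))[channel]

    @property
    def any(self) -> bool:
        return any(self.as_tuple())


@dataclass(frozen=True)
class PerturbationSpec:
    """One-shot perturbation of channel type ``channel`` by ``q`` channels.

    The perturbation fires at most once per detected event, the first
    time V crosses ``v_star`` in the stated direction (the falling
    trigger arms only once V has decreased for >= 1 ms, i.e. after the
    event's peak).  If the channel type is simulated deterministically
    the perturbation is a current g_X (q/N_X)(V - V_X) injected for
    ``duration`` ms; if stochastic, q channels are opened (q > 0) or
    closed (q < 0) instantaneously, clamped to [0, N_X].
    """

    channel: str
    q: int
    v_star: float
    direction: str = "rising"           # 'rising' | 'falling'
    duration: float = 5.0               # ms, current mode only
    mode: Optional[str] = None          # 'current' | 'channels' | None = infer

    def __post_init__(self):
        if self.channel not in CHANNEL_TYPES:
            raise ValueError(f"unknown channel type {self.channel!r}")
        if self.direction not in ("rising", "falling"):
            raise ValueError("direction must be 'rising' or 'falling'")
        if self.mode not in (None, "current", "channels"):
            raise ValueError("mode must be 'current', 'channels' or None")
        if self.duration <= 0:
            raise ValueError("current-injection duration must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for :func:`simulate`.

    ``transient_discard`` is carried on the resulting trace and applied
    by the event analysis, not by truncating the trace itself.
    """

    duration: float = 5000.0            # ms
    dt: float = 0.01                    # ms
    seed: int = 0
    noise: NoiseFlags = field(default_factory=NoiseFlags.all_channels)
    sigma: float = 1.0
    transient_discard: float = 1000.0   # ms
    initial_state: Optional[CellState] = None
    perturbation: Optional[PerturbationSpec] = None
    record_stride: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.transient_discard >= 0:
            raise ValueError("need duration > transient_discard >= 0")
        if self.record_stride < 1 or self.record_stride != int(self.record_stride):
            raise ValueError("record_stride must be a positive integer")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class Trace:
    """Regularly sampled simulation output.

    Samples are spaced ``dt * stride`` ms apart, starting at t = 0 with
    the initial state.  ``open_counts`` maps each stochastically
    simulated channel type to its open-count series.
    """

    dt: float
    V: np.ndarray
    Ca: np.ndarray
    m: np.ndarray
    n: np.ndarray
    s: np.ndarray
    f: np.ndarray
    open_counts: dict
    stride: int = 1
    seed: Optional[int] = None
    transient_discard: float = 0.0
    n_perturbations: int = 0
    n_clamped_perturbations: int = 0

    @property
    def sample_dt(self) -> float:
        return self.dt * self.stride

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.V)) * self.sample_dt

    def __len__(self) -> int:
        return len(self.V)

    def to_dataframe(self):
        import pandas as pd

        data = {"t_ms": self.t, "V_mV": self.V, "Ca_uM": self.Ca,
                "m": self.m, "n": self.n, "s": self.s, "f": self.f}
        for ch in CHANNEL_TYPES:
            col = f"open_{ch}"
            data[col] = self.open_counts.get(
                ch, np.full(len(self.V), np.nan))
        return pd.DataFrame(data)


def apply_sigma(p: ModelParameters, sigma: float) -> ModelParameters:
    """Scale all channel counts by ``sigma`` at fixed total conductance.

    Counts become ``sigma * N_X`` (which must be integral) and
    single-channel conductances shrink by ``1/sigma``, so total
    conductances — and hence the deterministic dynamics — are unchanged
    while the relative noise amplitude scales like 1/sqrt(sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if sigma == 1.0:
        return p
    changes = {}
    for ch in CHANNEL_TYPES:
        scaled = sigma * p.count(ch)
        n_new = int(round(scaled))
        if abs(scaled - n_new) > 1e-9 * max(1.0, scaled):
            raise ValueError(
                f"sigma = {sigma} gives non-integer count {scaled} for {ch} channels")
        changes[f"N_{ch}"] = n_new
        changes[f"g1_{ch}"] = p.single_conductance(ch) / sigma
    return p.replace(**changes)


def auto_initial_state(p: ModelParameters) -> CellState:
    """Default start: V = -60 mV, [Ca] = 0.1 µM, gating at steady state."""
    V0, Ca0 = -60.0, 0.1
    m_inf, n_inf, f_inf, s_inf = steady_state_activations(V0, Ca0, p)
    return CellState(V=V0, m=float(m_inf), n=float(n_inf), s=float(s_inf),
                     f=float(f_inf), Ca=Ca0)


def _pack_params(p: ModelParameters) -> np.ndarray:
    P = np.empty(_kernel.N_PACKED)
    P[0:6] = (p.C, p.g_Ca, p.g_K, p.g_SK, p.g_BK, p.g_l)
    P[6:9] = (p.V_Ca, p.V_K, p.V_l)
    P[9:13] = (p.tau_m, p.tau_n, p.tau_s, p.tau_BK)
    P[13:19] = (p.v_m, p.s_m, p.v_n, p.s_n, p.v_f, p.s_f)
    P[19:23] = (p.k_s, p.f_c, p.alpha, p.k_c)
    return P


def _validate_dt(p: ModelParameters, dt: float) -> None:
    tau_min = min(p.tau_m, p.tau_n, p.tau_s, p.tau_BK)
    if dt > tau_min:
        raise ValueError(
            f"dt = {dt} ms exceeds the smallest gating time constant "
            f"({tau_min} ms); per-step transition probabilities would exceed 1")


def _rng_seeds(seed: int) -> np.ndarray:
    """Four (initstate, initseq) pairs, one PCG32 stream per channel type."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(8, np.uint64).reshape(4, 2)


def simulate(p: ModelParameters = DEFAULT_PARAMS,
             cfg: SimulationConfig = SimulationConfig()) -> Trace:
    """Run the model and return a :class:`Trace`.

    Identical parameters, config and seed give bit-identical traces.
    A non-finite state aborts with a diagnostic naming the step and
    variable.
    """
    p_eff = apply_sigma(p, cfg.sigma)
    _validate_dt(p_eff, cfg.dt)

    state0 = cfg.initial_state or auto_initial_state(p_eff)
    y0 = np.array([state0.V, state0.m, state0.n, state0.s, state0.f, state0.Ca])
    o0 = np.full(4, -1, dtype=np.int64)
    if state0.open_counts:
        for i, ch in enumerate(CHANNEL_TYPES):
            if ch in state0.open_counts:
                o0[i] = int(state0.open_counts[ch])

    N = np.array([p_eff.count(ch) for ch in CHANNEL_TYPES], dtype=np.int64)
    stoch = np.array(cfg.noise.as_tuple())
    for i, ch in enumerate(CHANNEL_TYPES):
        if stoch[i] and N[i] < 1:
            raise ValueError(f"stochastic {ch} gating requires at least one channel")

    pert = cfg.perturbation
    if pert is not None:
        ch_idx = CHANNEL_TYPES.index(pert.channel)
        if abs(pert.q) > N[ch_idx]:
            raise ValueError(
                f"|q| = {abs(pert.q)} exceeds N_{pert.channel} = {N[ch_idx]}")
        if pert.mode is None:
            current_mode = not stoch[ch_idx]
        else:
            current_mode = pert.mode == "current"
        pert_args = (True, ch_idx, int(pert.q), float(pert.v_star),
                     pert.direction == "rising", bool(current_mode),
                     int(round(pert.duration / cfg.dt)))
    else:
        pert_args = (False, 0, 0, 0.0, True, False, 0)

    rng = np.zeros((4, 2), dtype=np.uint64)
    _kernel.seed_streams(rng, _rng_seeds(cfg.seed))

    n_steps = int(round(cfg.duration / cfg.dt))
    out, out_open, status, err_step, err_var, n_fired, n_clamped = _kernel.run_kernel(
        _pack_params(p_eff), N, stoch, y0, o0, n_steps, cfg.dt,
        int(cfg.record_stride), rng, *pert_args, DETECTION_THRESHOLD)

    if status != 0:
        var = {0: "V", 5: "Ca"}[err_var]
        raise FloatingPointError(
            f"non-finite {var} at step {err_step} (t = {err_step * cfg.dt:.3f} ms)")

    open_counts = {ch: out_open[:, i].copy()
                   for i, ch in enumerate(CHANNEL_TYPES) if stoch[i]}
    return Trace(dt=cfg.dt, V=out[:, 0].copy(), m=out[:, 1].copy(),
                 n=out[:, 2].copy(), s=out[:, 3].copy(), f=out[:, 4].copy(),
                 Ca=out[:, 5].copy(), open_counts=open_counts,
                 stride=int(cfg.record_stride), seed=cfg.seed,
                 transient_discard=cfg.transient_discard,
                 n_perturbations=int(n_fired),
                 n_clamped_perturbations=int(n_clamped))


def euler_step(state: CellState, p: ModelParameters,
               cfg: SimulationConfig = SimulationConfig(),
               rng: Optional[np.random.Generator] = None,
               extra_current: float = 0.0) -> CellState:
    """One Euler step in plain Python; reference for the compiled kernel.

    Follows the same five phases and operation order as the kernel.
    ``extra_current`` (pA) stands in for phase (ii)'s perturbation
    current.  Stochastic channel types require ``state.open_counts`` and
    an ``rng``; draws come from numpy's binomial generator, so the path
    is statistically — not bitwise — equivalent to the kernel's.
    """
    from .channels import ChannelPopulation, binomial_channel_step, transition_rates

    dt = cfg.dt
    cur = membrane_currents(state, p)
    I_tot = cur.total + extra_current
    V_new = state.V + dt * (-I_tot / p.C)
    Ca_new = state.Ca + dt * (-p.f_c * (p.alpha * cur.I_Ca + p.k_c * state.Ca))
    if not (np.isfinite(V_new) and np.isfinite(Ca_new)):
        raise FloatingPointError("non-finite state after Euler step")

    m_inf, n_inf, f_inf, s_inf = steady_state_activations(V_new, Ca_new, p)
    xinf = dict(Ca=float(m_inf), K=float(n_inf), SK=float(s_inf), BK=float(f_inf))

    gates = {}
    new_counts = {} if state.open_counts else None
    for ch in CHANNEL_TYPES:
        x = state.gating(ch)
        if cfg.noise.is_stochastic(ch):
            if rng is None or not state.open_counts or ch not in state.open_counts:
                raise ValueError(
                    f"stochastic {ch} update requires open_counts and an rng")
            pop = ChannelPopulation(channel_type=ch, N_total=p.count(ch),
                                    N_open=int(state.open_counts[ch]),
                                    g1=p.single_conductance(ch), tau=p.tau(ch))
            rates = transition_rates(xinf[ch], p.tau(ch))
            n_open = binomial_channel_step(pop, rates, dt, rng)
            new_counts[ch] = n_open
            gates[ch] = n_open / p.count(ch)
        else:
            gates[ch] = x + dt * (xinf[ch] - x) / p.tau(ch)
            if new_counts is not None and state.open_counts and ch in state.open_counts:
                new_counts[ch] = state.open_counts[ch]

    return CellState(V=float(V_new), m=gates["Ca"], n=gates["K"],
                     s=gates["SK"], f=gates["BK"], Ca=float(Ca_new),
                     open_counts=new_counts)
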