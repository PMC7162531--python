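"""Deterministic core of the pituitary-cell membrane model.

The model tracks six state variables: the membrane potential ``V`` (mV),
four channel gating variables (``m`` for L-type Ca channels, ``n`` for
delayed-rectifier K channels, ``s`` for SK channels, ``f`` for BK
channels), and the free intracellular calcium concentration ``Ca`` (µM).
Five currents drive the potential: an inward Ca current, three outward K
currents (K, SK, BK) and a passive leak.

Units are fixed throughout the package: capacitance in pF, conductances
in nS (single-channel conductances in pS), potentials in mV, currents in
pA, time in ms, calcium in µM and the charge-to-concentration factor
``alpha`` in µM/fC.  These are mutually consistent: nS·mV = pA and
pA/pF = mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "CHANNEL_TYPES",
    "ModelParameters",
    "CellState",
    "Currents",
    "DEFAULT_PARAMS",
    "steady_state_activations",
    "membrane_currents",
    "deterministic_derivatives",
]

#: Order used everywhere a quantity is indexed per channel type.
CHANNEL_TYPES = ("Ca", "K", "SK", "BK")

# pS -> nS
_PS_PER_NS = 1000.0


def logistic(x):
    """Overflow-safe standard logistic 1/(1+e^-x); accepts scalars or arrays."""
    return 1.0 / (1.0 + np.exp(np.clip(-x, -700.0, 700.0)))


@dataclass(frozen=True)
class ModelParameters:
    """All biophysical constants of the model.

    Total conductances are tied to the single-channel conductances via
    ``g_X = g1_X * N_X / 1000`` (pS -> nS); use :meth:`with_total_conductance`
    or :meth:`with_counts` to change one side while keeping the relation
    intact.
    """

    C: float = 10.0            # membrane capacitance, pF
    g_Ca: float = 2.0          # maximal conductances, nS
    g_K: float = 3.2
    g_SK: float = 2.0
    g_BK: float = 0.5
    g_l: float = 0.2           # leak conductance, nS
    V_Ca: float = 60.0         # reversal potentials, mV
    V_K: float = -75.0
    V_l: float = -50.0
    tau_m: float = 0.1         # gating time constants, ms
    tau_n: float = 30.0
    tau_s: float = 0.1
    tau_BK: float = 5.0
    v_m: float = -20.0         # activation midpoints, mV
    s_m: float = 12.0          # activation slopes, mV
    v_n: float = -5.0
    s_n: float = 10.0
    v_f: float = -20.0
    s_f: float = 2.0
    k_s: float = 0.4           # SK calcium midpoint, µM
    f_c: float = 0.01          # free-calcium fraction
    alpha: float = 0.0015      # charge-to-concentration factor, µM/fC
    k_c: float = 0.12          # calcium extrusion rate, 1/ms
    g1_Ca: float = 10.0        # single-channel conductances, pS
    g1_K: float = 5.0
    g1_SK: float = 10.0
    g1_BK: float = 100.0
    N_Ca: int = 200            # channel counts
    N_K: int = 640
    N_SK: int = 200
    N_BK: int = 5

    def __post_init__(self):
        positive = (
            "C", "g_Ca", "g_K", "g_SK", "g_BK", "g_l",
            "tau_m", "tau_n", "tau_s", "tau_BK",
            "s_m", "s_n", "s_f", "k_s", "f_c", "alpha", "k_c",
            "g1_Ca", "g1_K", "g1_SK", "g1_BK",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("N_Ca", "N_K", "N_SK", "N_BK"):
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"channel count {name} must be a non-negative integer")
            object.__setattr__(self, name, int(value))

    # -- per-channel-type accessors -------------------------------------

    def total_conductance(self, channel: str) -> float:
        return getattr(self, f"g_{channel}")

    def single_conductance(self, channel: str) -> float:
        return getattr(self, f"g1_{channel}")

    def count(self, channel: str) -> int:
        return getattr(self, f"N_{channel}")

    def reversal(self, channel: str) -> float:
        return self.V_Ca if channel == "Ca" else self.V_K

    def tau(self, channel: str) -> float:
        return {"Ca": self.tau_m, "K": self.tau_n, "SK": self.tau_s,
                "BK": self.tau_BK}[channel]

    # -- consistent modification ----------------------------------------

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def with_total_conductance(self, channel: str, g: float,
                               snap_count: bool = True) -> "ModelParameters":
        """Set ``g_X``, recomputing ``N_X`` from the single-channel conductance.

        With ``snap_count`` (default) the count is rounded to the nearest
        integer and ``g_X`` snapped back to ``g1_X * N_X`` so the
        conductance/count relation holds exactly; this is required for
        stochastic simulation.
        """
        if channel not in CHANNEL_TYPES:
            raise ValueError(f"unknown channel type {channel!r}")
        g1 = self.single_conductance(channel)
        n = int(np.floor(g * _PS_PER_NS / g1 + 0.5))
        if snap_count:
            g = g1 * n / _PS_PER_NS
        return self.replace(**{f"g_{channel}": g, f"N_{channel}": n})

    def with_counts(self, **counts: int) -> "ModelParameters":
        """Set channel counts (``Ca=..., BK=...``), recomputing totals."""
        changes = {}
        for channel, n in counts.items():
            if channel not in CHANNEL_TYPES:
                raise ValueError(f"unknown channel type {channel!r}")
            changes[f"N_{channel}"] = int(n)
            changes[f"g_{channel}"] = self.single_conductance(channel) * int(n) / _PS_PER_NS
        return self.replace(**changes)

    def counts_consistent(self, rtol: float = 1e-9) -> bool:
        """True if g_X = g1_X * N_X (within rounding) for all channel types."""
        for ch in CHANNEL_TYPES:
            expected = self.single_conductance(ch) * self.count(ch) / _PS_PER_NS
            if not np.isclose(self.total_conductance(ch), expected, rtol=rtol, atol=1e-12):
                return False
        return True


#: Default parameter set for a 10 µm-diameter cell.
DEFAULT_PARAMS = ModelParameters()


@dataclass
class CellState:
    """Instantaneous model state.

    ``open_counts`` holds the per-channel-type number of open channels
    when that type is simulated stochastically (in which case the gating
    variable equals ``open/N`` exactly); otherwise it is ``None``.
    """

    V: float
    m: float
    n: float
    s: float
    f: float
    Ca: float
    open_counts: Optional[dict] = None

    def __post_init__(self):
        for name in ("m", "n", "s", "f"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")
        if self.Ca < 0:
            raise ValueError(f"negative calcium concentration {self.Ca}")

    def gating(self, channel: str) -> float:
        return {"Ca": self.m, "K": self.n, "SK": self.s, "BK": self.f}[channel]


@dataclass(frozen=True)
class Currents:
    """The five ionic currents, in pA (positive = outward)."""

    I_Ca: float
    I_K: float
    I_SK: float
    I_BK: float
    I_leak: float

    @property
    def total(self) -> float:
        return self.I_Ca + self.I_K + self.I_SK + self.I_BK + self.I_leak


def steady_state_activations(V, Ca, p: ModelParameters = DEFAULT_PARAMS):
    """Steady-state open probabilities ``(m_inf, n_inf, f_inf, s_inf)``.

    ``m``, ``n`` and ``f`` follow logistic functions of voltage with
    midpoints ``v_x`` and slopes ``s_x``; SK activation is a Hill function
    of calcium with exponent 2 and midpoint ``k_s``.  Accepts scalars or
    arrays and is overflow-safe for extreme voltages.
    """
    if np.any(np.asarray(Ca) < 0):
        raise ValueError("calcium concentration must be non-negative")
    m_inf = logistic((np.asarray(V) - p.v_m) / p.s_m)
    n_inf = logistic((np.asarray(V) - p.v_n) / p.s_n)
    f_inf = logistic((np.asarray(V) - p.v_f) / p.s_f)
    Ca2 = np.asarray(Ca) ** 2
    s_inf = Ca2 / (Ca2 + p.k_s ** 2)
    return m_inf, n_inf, f_inf, s_inf


def membrane_currents(state: CellState, p: ModelParameters = DEFAULT_PARAMS) -> Currents:
    """Ionic currents at the given state (nS · mV = pA)."""
    V = state.V
    return Currents(
        I_Ca=p.g_Ca * state.m * (V - p.V_Ca),
        I_K=p.g_K * state.n * (V - p.V_K),
        I_SK=p.g_SK * state.s * (V - p.V_K),
        I_BK=p.g_BK * state.f * (V - p.V_K),
        I_leak=p.g_l * (V - p.V_l),
    )


def deterministic_derivatives(state: CellState, p: ModelParameters = DEFAULT_PARAMS):
    """Time derivatives ``(dV, dm, dn, ds, df, dCa)`` in per-ms units.

    The potential relaxes under the summed currents, each gating variable
    relaxes exponentially to its steady state with its own time constant,
    and calcium balances influx through Ca channels against first-order
    extrusion:

        C dV/dt  = -(I_Ca + I_K + I_SK + I_BK + I_leak)
        tau_x dx/dt = x_inf - x
        d[Ca]/dt = -f_c (alpha I_Ca + k_c [Ca])
    """
    cur = membrane_currents(state, p)
    m_inf, n_inf, f_inf, s_inf = steady_state_activations(state.V, state.Ca, p)
    dV = -cur.total / p.C
    dm = (m_inf - state.m) / p.tau_m
    dn = (n_inf - state.n) / p.tau_n
    ds = (s_inf - state.s) / p.tau_s
    df = (f_inf - state.f) / p.tau_BK
    dCa = -p.f_c * (p.alpha * cur.I_Ca + p.k_c * state.Ca)
    return dV, dm, dn, ds, df, dCa
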