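"""Two-state Markov channel populations.

Each channel of a type flips independently between closed and open with
voltage- (or calcium-) dependent rates derived from the deterministic
gating equation: writing tau dx/dt = x_inf - x as a master equation
gives an opening rate beta = x_inf/tau and closing rate
gamma = (1 - x_inf)/tau, so beta + gamma = 1/tau always.  Over a step
dt, the number of channels opening (closing) is Binomial(N_closed,
beta dt) (Binomial(N_open, gamma dt)), valid while rate * dt <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelPopulation",
    "TransitionRates",
    "channel_count",
    "transition_rates",
    "binomial_channel_step",
    "perturbation_quantum",
]


@dataclass
class ChannelPopulation:
    """A population of identical two-state channels of one type."""

    channel_type: str       # 'Ca' | 'K' | 'SK' | 'BK'
    N_total: int
    N_open: int
    g1: float               # single-channel conductance, pS
    tau: float              # gating time constant, ms

    def __post_init__(self):
        if self.N_total < 0:
            raise ValueError("N_total must be non-negative")
        if not 0 <= self.N_open <= self.N_total:
            raise ValueError("need 0 <= N_open <= N_total")

    @property
    def fraction_open(self) -> float:
        """Gating variable: open fraction of the population."""
        if self.N_total == 0:
            raise ValueError("open fraction undefined for an empty population")
        return self.N_open / self.N_total


@dataclass(frozen=True)
class TransitionRates:
    """Opening (beta) and closing (gamma) rates, 1/ms."""

    beta: float
    gamma: float

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("transition rates must be non-negative")


def channel_count(g_total: float, g_single: float) -> int:
    """Number of channels implied by a total (nS) and single-channel (pS)
    conductance, rounded to the nearest integer (ties up)."""
    if g_single <= 0:
        raise ValueError("single-channel conductance must be positive")
    if g_total < 0:
        raise ValueError("total conductance must be non-negative")
    return max(int(np.floor(1000.0 * g_total / g_single + 0.5)), 0)


def transition_rates(x_inf: float, tau: float) -> TransitionRates:
    """Rates of the two-state scheme from a steady-state activation."""
    if tau <= 0:
        raise ValueError("time constant must be positive")
    if not 0.0 <= x_inf <= 1.0:
        raise ValueError("steady-state activation must lie in [0, 1]")
    return TransitionRates(beta=x_inf / tau, gamma=(1.0 - x_inf) / tau)


def binomial_channel_step(pop: ChannelPopulation, rates: TransitionRates,
                          dt: float, rng: np.random.Generator) -> int:
    """Advance the population one step; returns the new open count.

    N_open' = N_open + Binomial(N_closed, beta dt) - Binomial(N_open, gamma dt).
    A transition probability above 1 is a step-size violation and raises
    rather than being silently clamped.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_open = rates.beta * dt
    p_close = rates.gamma * dt
    if p_open > 1.0 or p_close > 1.0:
        raise ValueError(
            f"rate * dt exceeds 1 (p_open = {p_open:.3g}, p_close = {p_close:.3g}); "
            "reduce the time step")
    opened = rng.binomial(pop.N_total - pop.N_open, p_open)
    closed = rng.binomial(pop.N_open, p_close)
    return int(pop.N_open + opened - closed)


def perturbation_quantum(N_total: int) -> int:
    """Perturbation size comparable across channel types: sqrt(N)/2.

    This is the largest standard deviation of the quasi-stationary
    binomial open-count distribution (attained at open probability 1/2),
    rounded to the nearest integer with a floor of one channel.
    """
    if N_total < 1:
        raise ValueError("need at least one channel")
    return max(int(np.floor(np.sqrt(N_total) / 2.0 + 0.5)), 1)
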