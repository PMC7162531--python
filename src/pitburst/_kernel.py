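"""Compiled fixed-step integration kernel.

The whole Euler loop — currents, the optional triggered perturbation,
the voltage/calcium update, steady-state activations and the per-type
gating update (binomial for stochastic channel types, forward Euler for
deterministic ones) — runs inside a single numba-compiled function so
that multi-second simulations at dt = 0.01 ms stay cheap.

Randomness uses one PCG32 stream per channel type, so toggling noise in
one channel type never changes the draws consumed by another.  Binomial
variates are generated by inversion with geometric skips, which is exact
and O(np + 1) per draw; per-step success probabilities here are at most
dt / min(tau) (0.1 at the default dt), keeping np small.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_streams", "binomial_draw", "run_kernel"]

_PCG_MULT = np.uint64(6364136223846793005)


@njit(cache=True, inline="always")
def _pcg32(st):
    """Advance one PCG32 stream (st = [state, inc]) and return a uint32."""
    old = st[0]
    st[0] = old * _PCG_MULT + st[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(0) - rot) & np.uint32(31)))
    )


@njit(cache=True)
def seed_streams(states, seeds):
    """Initialise PCG32 streams from (initstate, initseq) pairs."""
    for i in range(states.shape[0]):
        states[i, 0] = np.uint64(0)
        states[i, 1] = (seeds[i, 1] << np.uint64(1)) | np.uint64(1)
        _pcg32(states[i])
        states[i, 0] = states[i, 0] + seeds[i, 0]
        _pcg32(states[i])


@njit(cache=True, inline="always")
def _uniform(st):
    # (0, 1), never exactly 0 so log(u) is safe
    return (np.float64(_pcg32(st)) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True, inline="always", error_model="numpy")
def binomial_draw(n, p, st):
    """Binomial(n, p) by inversion with geometric skips between successes.

    The first uniform is squeezed against 1 - np <= (1-p)^n, so the
    common all-failures case costs one draw and no transcendentals; the
    same uniform seeds the full inversion otherwise, keeping the mapping
    from the random stream to the variate exact.
    """
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    u = _uniform(st)
    if u <= 1.0 - n * p:
        return 0
    log_q = np.log1p(-p)
    if log_q == 0.0:
        return 0  # p below float resolution (possibly flushed subnormal)
    successes = 0
    trials = 0
    while True:
        trials += np.int64(np.floor(np.log(u) / log_q)) + 1
        if trials > n:
            return successes
        successes += 1
        u = _uniform(st)


@njit(cache=True, inline="always")
def _logistic(x):
    z = -x
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return 1.0 / (1.0 + np.exp(z))


# Indices into the packed parameter vector (see simulate._pack_params).
_C, _GCA, _GK, _GSK, _GBK, _GL = 0, 1, 2, 3, 4, 5
_VCA, _VK, _VL = 6, 7, 8
_TAUM, _TAUN, _TAUS, _TAUBK = 9, 10, 11, 12
_VM, _SM, _VN, _SN, _VF, _SF = 13, 14, 15, 16, 17, 18
_KS, _FC, _ALPHA, _KC = 19, 20, 21, 22
N_PACKED = 23


@njit(cache=True, error_model="numpy")
def run_kernel(P, N, stoch, y0, o0, n_steps, dt, stride, rng,
               pert_on, pert_ch, pert_q, pert_vstar, pert_rising,
               pert_current_mode, pert_steps, ev_thr):
    """Integrate the model for ``n_steps`` Euler steps of size ``dt``.

    Each step follows five phases: (i) ionic currents from the current
    state; (ii) application of any due perturbation; (iii) forward-Euler
    update of V and [Ca]; (iv) steady-state activations at the updated
    V and [Ca]; (v) gating update per channel type, binomial where
    ``stoch`` is set and forward Euler otherwise.

    Returns (out, out_open, status, err_step, err_var, n_fired,
    n_clamped) where ``out`` holds rows (V, m, n, s, f, Ca) every
    ``stride`` steps (the initial state included), ``out_open`` the open
    counts (-1 for deterministic types), and status != 0 flags a
    non-finite state at step ``err_step`` in variable ``err_var``
    (0 = V, 5 = Ca).
    """
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 6))
    out_open = np.full((n_rec, 4), -1, dtype=np.int64)

    C = P[_C]
    gtot = np.empty(4)
    gtot[0], gtot[1], gtot[2], gtot[3] = P[_GCA], P[_GK], P[_GSK], P[_GBK]
    gl, VCa, VK, Vl = P[_GL], P[_VCA], P[_VK], P[_VL]
    vrev = np.empty(4)
    vrev[0], vrev[1], vrev[2], vrev[3] = VCa, VK, VK, VK
    tau = np.empty(4)
    tau[0], tau[1], tau[2], tau[3] = P[_TAUM], P[_TAUN], P[_TAUS], P[_TAUBK]
    vm, sm, vn, sn, vf, sf = P[_VM], P[_SM], P[_VN], P[_SN], P[_VF], P[_SF]
    ks, fc, alpha, kc = P[_KS], P[_FC], P[_ALPHA], P[_KC]
    ks2 = ks * ks

    V = y0[0]
    Ca = y0[5]
    g = np.empty(4)
    g[0], g[1], g[2], g[3] = y0[1], y0[2], y0[3], y0[4]

    o = np.zeros(4, dtype=np.int64)
    for i in range(4):
        if stoch[i]:
            if o0[i] >= 0:
                o[i] = o0[i]
            else:
                o[i] = binomial_draw(N[i], g[i], rng[i])
            g[i] = o[i] / N[i]

    out[0, 0] = V
    out[0, 1], out[0, 2], out[0, 3], out[0, 4] = g[0], g[1], g[2], g[3]
    out[0, 5] = Ca
    for i in range(4):
        if stoch[i]:
            out_open[0, i] = o[i]

    prev_V = V
    in_event = False
    fired = False
    falling_armed = False
    dec_ms = 0.0
    pert_timer = 0
    n_fired = 0
    n_clamped = 0
    I_ch = np.empty(4)
    xinf = np.empty(4)

    for step in range(n_steps):
        # phase (i): ionic currents
        for i in range(4):
            I_ch[i] = gtot[i] * g[i] * (V - vrev[i])
        I_leak = gl * (V - Vl)

        # phase (ii): triggered perturbation
        I_pert = 0.0
        if pert_on:
            if not in_event:
                if V > ev_thr:
                    in_event = True
                    fired = False
                    falling_armed = False
                    dec_ms = 0.0
            elif V <= ev_thr:
                in_event = False
            do_fire = False
            if in_event:
                if V < prev_V:
                    dec_ms += dt
                else:
                    dec_ms = 0.0
                if dec_ms >= 1.0:
                    falling_armed = True
                if not fired:
                    if pert_rising:
                        if prev_V < pert_vstar and V >= pert_vstar:
                            do_fire = True
                    elif falling_armed and prev_V >= pert_vstar and V < pert_vstar:
                        do_fire = True
            if do_fire:
                fired = True
                n_fired += 1
                if pert_current_mode:
                    pert_timer = pert_steps
                else:
                    target = o[pert_ch] + pert_q
                    if target < 0:
                        target = 0
                        n_clamped += 1
                    elif target > N[pert_ch]:
                        target = N[pert_ch]
                        n_clamped += 1
                    o[pert_ch] = target
                    g[pert_ch] = o[pert_ch] / N[pert_ch]
                    I_ch[pert_ch] = gtot[pert_ch] * g[pert_ch] * (V - vrev[pert_ch])
            if pert_timer > 0:
                I_pert = gtot[pert_ch] * (pert_q / N[pert_ch]) * (V - vrev[pert_ch])
                pert_timer -= 1

        # phase (iii): update V and [Ca]
        I_Ca = I_ch[0]
        if I_pert != 0.0 and pert_ch == 0:
            I_Ca += I_pert  # injected Ca-type current also carries Ca2+ influx
        I_tot = I_ch[0] + I_ch[1] + I_ch[2] + I_ch[3] + I_leak + I_pert
        V_new = V + dt * (-I_tot / C)
        Ca_new = Ca + dt * (-fc * (alpha * I_Ca + kc * Ca))
        if not (np.isfinite(V_new) and np.isfinite(Ca_new)):
            err_var = 0 if not np.isfinite(V_new) else 5
            return out, out_open, 1, step, err_var, n_fired, n_clamped

        # phase (iv): steady-state activations at the new V and [Ca]
        xinf[0] = _logistic((V_new - vm) / sm)
        xinf[1] = _logistic((V_new - vn) / sn)
        Ca2 = Ca_new * Ca_new
        xinf[2] = Ca2 / (Ca2 + ks2)
        xinf[3] = _logistic((V_new - vf) / sf)

        # phase (v): gating update
        for i in range(4):
            if stoch[i]:
                p_open = xinf[i] * dt / tau[i]
                p_close = (1.0 - xinf[i]) * dt / tau[i]
                opened = binomial_draw(N[i] - o[i], p_open, rng[i])
                closed = binomial_draw(o[i], p_close, rng[i])
                o[i] += opened - closed
                g[i] = o[i] / N[i]
            else:
                g[i] += dt * (xinf[i] - g[i]) / tau[i]

        prev_V = V
        V = V_new
        Ca = Ca_new

        if (step + 1) % stride == 0:
            j = (step + 1) // stride
            out[j, 0] = V
            out[j, 1], out[j, 2], out[j, 3], out[j, 4] = g[0], g[1], g[2], g[3]
            out[j, 5] = Ca
            for i in range(4):
                if stoch[i]:
                    out_open[j, i] = o[i]

    return out, out_open, 0, -1, -1, n_fired, n_clamped
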