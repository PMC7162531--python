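# pitburst

Stochastic ion-channel simulation of electrical activity in anterior
pituitary endocrine cells (somatotrophs/lactotrophs), for studying how
channel noise shapes spiking versus bursting — and hence hormone
secretion — as a function of BK-channel number, cell size and model
parameters.

These cells fire spontaneous depolarisation events: brief **spikes**
or prolonged **bursts** that oscillate around a depolarised level.
A handful of large-conductance BK channels (~5 per cell, 100 pS each)
decides between the two, so the random opening and closing of single
channels matters.  `pitburst` implements a Hodgkin–Huxley-type model

    C dV/dt   = -(I_Ca + I_K + I_SK + I_BK + I_leak),
    I_X       = g_X · x · (V - V_rev),        x ∈ {m, n, s, f}
    τ_x dx/dt = x_∞(V or [Ca]) - x,
    d[Ca]/dt  = -f_c(α·I_Ca + k_c[Ca]),

in which every channel population can be simulated as a two-state
Markov ensemble: over a step Δt, Binomial(N_closed, βΔt) channels open
and Binomial(N_open, γΔt) close, with β = x_∞/τ and γ = (1−x_∞)/τ, so
the gating variable is exactly the open fraction.  The package layers
on top of the simulator:

- event detection (V > −45 mV), spike/burst classification
  (< 100 ms and no plateau oscillations ⇒ spike) and the **bursting
  fraction** BF;
- per-channel-type noise switches (e.g. BK-only vs non-BK noise) and
  σ-scaling of channel counts at fixed total conductance;
- cell-size scaling λ (area quantities ×λ², volume quantities ×λ³,
  equivalent to f_c → f_c/λ with N_X → λ²N_X) and critical-conductance
  bisection;
- threshold-triggered single perturbations (open/close q channels at a
  chosen point of the action potential);
- a randomised ±50% parameter-robustness scan with behaviour and BF
  regime classification.

## Worked example

```python
from pitburst import (DEFAULT_PARAMS, SimulationConfig, NoiseFlags,
                      simulate, detect_events, summarize)

p = DEFAULT_PARAMS                      # 10 µm cell, g_BK = 0.5 nS, 5 BK channels
cfg = SimulationConfig(duration=11000, seed=3)   # ms; 1 s transient discarded
trace = simulate(p, cfg)                # full channel noise, Δt = 0.01 ms
s = summarize(detect_events(trace))
print(f"{s.n_events} events, BF = {s.bf:.2f} ± {s.bf_se:.2f}")

det = simulate(p, cfg.replace(noise=NoiseFlags.none()))
d = summarize(detect_events(det))
print(f"deterministic: BF = {d.bf:.1f}, spike peak {d.spike_vmax_mean:.1f} mV")
```

prints

```
28 events, BF = 0.43 ± 0.09
deterministic: BF = 0.0, spike peak -5.9 mV
```

Deterministically this cell spikes periodically (BF = 0, peak
−5.9 mV); channel noise converts a sizeable fraction of events into
bursts (BF fluctuates between roughly 0.2 and 0.45 across 10-second
windows).  Raising `g_BK` to 1 nS flips the deterministic model to pure
bursting (BF = 1), and with noise some bursts become spikes again —
the BF-vs-g_BK step becomes a sigmoid that saturates below 1.

The same functionality is scriptable from the shell:

```
pitburst simulate --seed 3 --duration 11000 --noise all --out trace.csv
pitburst events --trace trace.csv --out events.csv
pitburst scan --n 1000 --seed 7 --out scan.csv
```

Every command writes a `.manifest.yaml` allowing bit-identical reruns.

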