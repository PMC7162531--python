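# Methods

## The model

`pitburst` simulates the electrical activity of an anterior-pituitary
endocrine cell (somatotroph/lactotroph type) with explicit, stochastic
ion-channel gating.  The membrane potential obeys

    C dV/dt = -(I_Ca + I_K + I_SK + I_BK + I_leak),

with an inward L-type Ca²⁺ current, a delayed-rectifier K⁺ current, a
small-conductance Ca²⁺-activated K⁺ current (SK), a large-conductance
K⁺ current (BK, modelled as voltage-gated: BK channels sit in calcium
microdomains that equilibrate in microseconds) and a passive leak.
Each current is g_X·x·(V−V_rev) with gating variable x ∈ {m, n, s, f}.
Gating relaxes as τ_x dx/dt = x_inf − x with logistic voltage
activations for m, n, f and a Hill function of calcium
([Ca]²/([Ca]²+k_s²)) for s.  Free intracellular calcium follows
d[Ca]/dt = −f_c(α·I_Ca + k_c[Ca]).

Units are pF, nS (pS for single channels), mV, pA, ms, µM; these are
closed under the model's arithmetic (nS·mV = pA, pA/pF = mV/ms).
Defaults describe a 10 µm-diameter cell: g_Ca = 2, g_K = 3.2,
g_SK = 2, g_BK = 0.5, g_l = 0.2 nS; V_Ca = 60, V_K = −75, V_l = −50 mV;
τ_m = τ_s = 0.1, τ_n = 30, τ_BK = 5 ms; single-channel conductances
10/5/10/100 pS give N = 200 Ca, 640 K, 200 SK and 5 BK channels
(g_X = g1_X·N_X with the pS→nS factor of 1000).

## Stochastic gating

Writing τ dx/dt = x_inf − x as a two-state master equation gives an
opening rate β = x_inf/τ and closing rate γ = (1−x_inf)/τ per channel.
Over a step Δt, the number of channels opening is
Binomial(N_closed, βΔt) and closing Binomial(N_open, γΔt), both pools
taken at the start of the step; the gating variable is exactly
N_open/N_total.  The scheme is valid while rate·Δt ≤ 1 (at most 0.1
here, for the fast m and s gates at Δt = 0.01 ms); violating it raises
an error rather than clamping.  Drawing both binomials from the
step-start pools matters: drawing the closing count from the
already-incremented pool biases fast gates ≈ γΔt below x_inf, which is
a 9% depression of the resting Ca-channel activation and visibly
distorts event peaks.

Integration is forward Euler with Δt = 0.01 ms in five phases per
step: (i) currents from the current state, (ii) any due perturbation,
(iii) V and [Ca] updates, (iv) steady-state activations at the *new*
V and [Ca], (v) gating updates — binomial for stochastic channel
types, forward Euler for deterministic ones.  Halving Δt down to
10⁻⁴ ms changes deterministic event durations by < 0.4%.

Randomness: one PCG32 stream per channel type, seeded from a master
seed through numpy's SeedSequence, so switching noise on or off in one
channel type never changes the draws another type consumes (needed for
clean BK-only vs non-BK comparisons).  Binomial variates use exact
inversion with geometric skips (O(np+1) per draw, with a 1−np squeeze
on the first uniform); a chi-square test checks the sampler against
the reference binomial distribution.  Identical seed and configuration
give bit-identical traces.

Initial conditions default to V = −60 mV, [Ca] = 0.1 µM, gates at
their steady states, stochastic open counts drawn binomially from
those steady states.  The first second of simulation is discarded by
the analysis (the trace itself is never truncated), which is several
times the slowest time constants in play.

## Events, spikes, bursts

An event is a maximal excursion of V above −45 mV; its duration is the
time from the first to the last supra-threshold sample.  Events
shorter than 100 ms with no depolarised-plateau oscillations are
spikes; longer events, or events with oscillations, are bursts.  The
bursting fraction (BF) is the burst share of all detected events, and
is reported with its binomial standard error.

Two analysis parameters are this package's own choices where the
classification is underdetermined:

- **Oscillation floor.**  Local maxima after the event's global
  maximum count as oscillations when their prominence is ≥ 1 mV and
  they are ≥ 1 ms apart (scipy's peak prominence).  Deterministic
  burst oscillations are several mV; channel-noise flicker is sub-mV,
  so 1 mV separates the scales.  Both knobs are arguments.
- **Flicker debounce.**  Excursions shorter than 5 ms are discarded.
  Near the detection threshold, channel noise re-crosses −45 mV during
  a single up- or downstroke, fragmenting one real event into sub-ms
  shards with V_max ≈ −44 mV.  Real events in this model last ≳ 30 ms
  (deterministic spikes ≈ 72 ms), so 5 ms is an order of magnitude
  from both scales.  Without the debounce, spike-peak statistics mix
  in the shards (≈ −44 mV) and are meaningless.  `min_duration=0`
  restores the raw contract.

Events truncated by either end of the analysis window are dropped
(unknown duration).  Classification is stable under down-sampling the
trace (tested at 2×; V_max statistics shift by ≲ 0.1 mV between
0.05 ms and 1 ms sampling because a maximum over fast flicker is
slightly biased upward at finer sampling).

## Noise decomposition

With all four channel types stochastic at default parameters
(g_BK = 0.5 nS), noise converts some would-be spikes into bursts
(BF ≈ 0.25–0.3).  Splitting sources reproduces the known pattern:
non-BK noise leaves spike/burst peaks near the deterministic −5.9 mV
(spikes ≈ −5.6, bursts ≈ −5.9, sd 1.1 mV), while BK-only noise (5
channels of 100 pS) separates them — bursts ≈ −7.3 mV (an early BK
opening lowers the peak, delays K activation and prolongs the event),
spikes ≈ −4.8 mV, sd ≈ 2.4 mV.  BF against N_BK with g1_BK fixed is a
smoothed sigmoid that saturates below 1: the current step from one BK
channel is g1_BK(V−V_K) regardless of N_BK, so some bursts are always
converted to spikes.  In this implementation the saturation plateau
(≈ 0.8 at N_BK ≈ 10–40) is followed by a slow decline (≈ 0.68 by
N_BK = 300) as single-channel openings abort a growing share of
events early (30–80 ms excursions peaking near −22 mV with no
oscillations); the BF-at-large-N_BK statistics in the acceptance
script are evaluated at N_BK = 100 and inherit part of this decline.

## Cell size

Cell size means diameter; the base cell is 10 µm (R = 5 µm).  Scaling
R → λR scales membrane-area quantities by λ² (C, all g_X, g_l, N_X)
and volume quantities by λ³ (α → α/λ³; extrusion k_c → k_c/λ since it
acts through the membrane on a volume concentration).  C and g scale
together, so the V equation is invariant and the entire effect on the
six state variables reduces to f_c → f_c/λ with N_X → λ²N_X — both
transformations are implemented and tested equivalent (deterministic
trajectories identical; stochastic runs share draws).  Larger cells
have effectively slower calcium dynamics → slower SK recruitment →
longer events → more bursting.  With g_BK = 0.5 nS at λ = 1 the
deterministic model switches sharply to bursting at λ ≈ 1.33; the
critical g_BK* grows with λ while the critical membrane density
g_BK*/4πR² falls.  Stochastic sizes are restricted to λ = √(k/5)
(integer k), which keeps all four channel counts integral; λ² = 1/5
is the smallest cell with a BK channel.

## Perturbation protocol

A perturbation opens or closes q channels of one type, at most once
per event, triggered the first time V crosses a threshold V*.  V* is
obtained by mapping a time offset from the deterministic spike's peak
onto the waveform (rising side for offsets ≤ 0, falling side
otherwise).  Because V_max is unknowable online, the falling trigger
arms only after V has decreased for ≥ 1 ms.  In deterministic runs the
perturbation is a current g_X(q/N_X)(V−V_X) injected for 5 ms (for Ca
channels this current also enters the calcium balance, since it
represents Ca²⁺ flux); in stochastic runs it is an instantaneous
count change, clamped to [0, N_X] and applied to the gating variable
before that step's V update.  All detected events enter BF whether or
not they reached the trigger.  The comparable-size quantum per type is
√N/2 (the maximum binomial sd), i.e. 7 Ca, 13 K, 7 SK, 1 BK at
defaults.  Opening one BK channel 2 ms before the peak converts
deterministic pure spiking into pure bursting; in the stochastic model
opening (closing) a BK channel before the peak raises (lowers) BF.

## Robustness scan

Seven parameters (g1_Ca, g1_K, g1_SK, g1_BK, g_l, V_l, k_c) are drawn
uniformly on ±50% of their defaults, counts held fixed, totals
recomputed.  Each set runs 10 s of full-noise simulation (1 s
transient) — enough events to classify behaviour, not to resolve BF
finely — and is labelled: depolarised/hyperpolarised (V range < 10 mV,
mid-range (max+min)/2 above/below −50 mV), noisy steady state (no
events, or range in [10, 35) mV, or mean event duration ≥ 5× the mean
inter-event gap — a flickering plateau, not discrete events; the 5× is
this package's choice, configurable), else event-containing.  At 1000
sets ≈ 93% are event-containing.  Sigmoidality of BF vs N_BK tolerates
pre-maximum dips within 2 binomial standard errors and post-maximum
declines ≤ 0.1; series with BF range < 0.2 are ineligible rather than
non-sigmoidal.  The large-N_BK analysis selects sets whose grid
(N_BK = 2, 5, 20, 100) is entirely event-containing with range ≥ 0.2,
then re-estimates BF at N_BK = 100 from ≥ 200 events.

## What the synthetic fixtures do and do not show

`make_fixture` produces square pulses, smooth sub-100 ms bumps,
plateaus with a documented number of oscillations, and sub-threshold
noise.  They validate the event analyser's geometry (durations,
oscillation counting, threshold handling) in isolation from the
simulator; they do not emulate channel-noise statistics, so passing
them says nothing about classification of borderline stochastic
events — that is exercised against simulated traces.

## Numerical and runtime choices

The integrator loop is numba-compiled (first call compiles in a few
seconds).  fastmath is deliberately off: LLVM's reassociation breaks
the in-loop isfinite divergence check, and it bought no measurable
speed.  A 10-s full-noise simulation costs ≈ 0.3–0.5 s on one core.
Problem sizes in the tests and acceptance script (1000-set scan,
100–120 selected sets for the large-N_BK mean, 400–500-event V_max
statistics) were chosen to resolve each quantity's standard error well
below its comparison tolerance.  Bisections (critical g_BK, critical
λ) use deterministic BF > 0.5 as the bursting indicator with
tolerances 10⁻³ nS and 2×10⁻³.

## Known limitations

- Leak current and calcium concentration carry no noise; channels are
  two-state and history-independent; BK gating ignores calcium
  microdomain dynamics beyond the voltage-only approximation.
- The binomial step ignores the open-and-reclose-within-Δt correction
  (≲ βγΔt² per channel); at rate·Δt ≤ 0.1 this is a sub-percent effect.
- The "thin shell" alternative calcium geometry (calcium confined near
  the membrane, giving different size scaling) is not implemented; the
  scaling functions would accept it as a different transformation.
- Behaviour classification on 10-s windows mislabels very sparse
  event trains (< 2 events) as noisy steady state by construction.
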