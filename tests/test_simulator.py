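import numpy as np
import pytest

from pitburst.model_core import CellState, DEFAULT_PARAMS, steady_state_activations
from pitburst.simulate import (
    NoiseFlags,
    SimulationConfig,
    apply_sigma,
    auto_initial_state,
    euler_step,
    simulate,
)

p = DEFAULT_PARAMS


class TestNoiseFlags:
    @pytest.mark.parametrize("text,expected", [
        ("all", (True, True, True, True)),
        ("none", (False, False, False, False)),
        ("bk-only", (False, False, False, True)),
        ("non-bk", (True, True, True, False)),
        ("ca,k", (True, True, False, False)),
    ])
    def test_parse(self, text, expected):
        assert NoiseFlags.parse(text).as_tuple() == expected

    def test_parse_rejects_unknown(self):
        with pytest.raises(ValueError):
            NoiseFlags.parse("nav1.7")


class TestEulerStep:
    def test_zero_current_state_leaves_potential_unchanged(self):
        # at V = V_K = V_l with no Ca or leak driving force, every term is 0
        p0 = p.replace(V_l=p.V_K)
        state = CellState(V=p.V_K, m=0.0, n=0.2, s=0.3, f=0.1, Ca=0.0)
        new = euler_step(state, p0, SimulationConfig(noise=NoiseFlags.none()))
        assert new.V == state.V
        assert new.Ca == state.Ca

    def test_single_step_matches_hand_computed_update(self):
        """One deterministic Euler step from a frozen state, checked
        against an independent arithmetic transcription of the update."""
        dt = 0.01
        state = CellState(V=-30.0, m=0.2, n=0.1, s=0.05, f=0.02, Ca=0.25)
        new = euler_step(state, p, SimulationConfig(dt=dt, noise=NoiseFlags.none()))

        I_Ca = 2.0 * 0.2 * (-30.0 - 60.0)            # -36 pA
        I_K = 3.2 * 0.1 * (-30.0 + 75.0)             # 14.4 pA
        I_SK = 2.0 * 0.05 * (-30.0 + 75.0)           # 4.5 pA
        I_BK = 0.5 * 0.02 * (-30.0 + 75.0)           # 0.45 pA
        I_l = 0.2 * (-30.0 + 50.0)                   # 4 pA
        V1 = -30.0 + dt * (-(I_Ca + I_K + I_SK + I_BK + I_l) / 10.0)
        Ca1 = 0.25 + dt * (-0.01 * (0.0015 * I_Ca + 0.12 * 0.25))
        assert new.V == pytest.approx(V1, abs=1e-12)
        assert new.Ca == pytest.approx(Ca1, abs=1e-15)

        m_inf = 1.0 / (1.0 + np.exp((-20.0 - V1) / 12.0))
        assert new.m == pytest.approx(0.2 + dt * (m_inf - 0.2) / 0.1, abs=1e-12)
        s_inf = Ca1 ** 2 / (Ca1 ** 2 + 0.4 ** 2)
        assert new.s == pytest.approx(0.05 + dt * (s_inf - 0.05) / 0.1, abs=1e-12)

    def test_local_truncation_error_is_second_order(self):
        state = auto_initial_state(p)
        cfg = SimulationConfig(noise=NoiseFlags.none())
        big = euler_step(state, p, cfg.replace(dt=0.01))
        half = euler_step(euler_step(state, p, cfg.replace(dt=0.005)),
                          p, cfg.replace(dt=0.005))
        # O(dt^2) local difference between one dt step and two dt/2 steps
        assert abs(big.V - half.V) < 10 * 0.01 ** 2

    def test_stochastic_step_requires_counts_and_rng(self):
        state = auto_initial_state(p)
        with pytest.raises(ValueError):
            euler_step(state, p, SimulationConfig())


class TestSimulate:
    def test_same_seed_reproduces_trace_exactly(self):
        cfg = SimulationConfig(duration=1200.0, seed=5, transient_discard=0.0)
        a = simulate(p, cfg)
        b = simulate(p, cfg)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.Ca, b.Ca)
        for ch in a.open_counts:
            assert np.array_equal(a.open_counts[ch], b.open_counts[ch])

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(duration=1200.0, seed=5, transient_discard=0.0)
        a = simulate(p, cfg)
        b = simulate(p, cfg.replace(seed=6))
        assert not np.array_equal(a.V, b.V)

    def test_trace_grid_and_lengths(self):
        cfg = SimulationConfig(duration=100.0, dt=0.01, transient_discard=0.0,
                               record_stride=10)
        tr = simulate(p, cfg)
        assert len(tr) == 100 * 100 // 10 + 1
        assert tr.sample_dt == pytest.approx(0.1)
        t = tr.t
        assert np.allclose(np.diff(t), tr.sample_dt)
        assert all(len(v) == len(tr) for v in tr.open_counts.values())

    def test_kernel_matches_python_reference_deterministically(self):
        cfg = SimulationConfig(duration=20.0, dt=0.01, transient_discard=0.0,
                               noise=NoiseFlags.none())
        tr = simulate(p, cfg)
        state = auto_initial_state(p)
        for i in range(1, len(tr)):
            state = euler_step(state, p, cfg)
            assert state.V == pytest.approx(tr.V[i], abs=1e-9)
        assert state.Ca == pytest.approx(tr.Ca[-1], abs=1e-12)

    def test_channel_counts_are_irrelevant_without_noise(self):
        cfg = SimulationConfig(duration=500.0, noise=NoiseFlags.none(),
                               transient_discard=0.0)
        a = simulate(p, cfg)
        b = simulate(p.with_counts(BK=50).replace(g_BK=0.5), cfg)
        assert np.array_equal(a.V, b.V)

    def test_deterministic_runs_ignore_seed(self):
        cfg = SimulationConfig(duration=500.0, noise=NoiseFlags.none(),
                               transient_discard=0.0)
        assert np.array_equal(simulate(p, cfg).V,
                              simulate(p, cfg.replace(seed=99)).V)

    def test_gating_fraction_equals_open_count_ratio(self):
        cfg = SimulationConfig(duration=300.0, seed=2, transient_discard=0.0,
                               record_stride=50)
        tr = simulate(p, cfg)
        assert np.array_equal(tr.f, tr.open_counts["BK"] / p.N_BK)
        assert np.array_equal(tr.m, tr.open_counts["Ca"] / p.N_Ca)

    def test_oversized_dt_rejected(self):
        with pytest.raises(ValueError, match="time constant"):
            simulate(p, SimulationConfig(duration=10.0, dt=0.2,
                                         transient_discard=0.0))

    def test_nonfinite_state_aborts_with_diagnostic(self):
        bad = p.replace(C=1e-9)
        with pytest.raises(FloatingPointError, match="step"):
            simulate(bad, SimulationConfig(duration=100.0, transient_discard=0.0,
                                           noise=NoiseFlags.none()))

    def test_event_duration_insensitive_to_time_step(self, det_trace):
        from pitburst.events import detect_events
        durations = [np.mean([e.duration for e in detect_events(det_trace)])]
        cfg = SimulationConfig(duration=3000.0, dt=1e-4, transient_discard=1000.0,
                               noise=NoiseFlags.none(), record_stride=500)
        fine = simulate(p, cfg)
        durations.append(np.mean([e.duration for e in detect_events(fine)]))
        assert durations[1] == pytest.approx(durations[0], rel=0.01)


class TestApplySigma:
    def test_identity(self):
        assert apply_sigma(p, 1.0) is p

    def test_doubling_preserves_total_conductance(self):
        p2 = apply_sigma(p, 2.0)
        assert p2.N_BK == 10
        assert p2.g1_BK == pytest.approx(50.0)
        assert p2.g_BK == pytest.approx(0.5)
        assert p2.counts_consistent()

    def test_shrinking_to_single_bk_channel(self):
        p2 = apply_sigma(p, 0.2)
        assert p2.N_BK == 1
        assert p2.N_K == 128

    def test_noninteger_scaled_counts_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            apply_sigma(p, 0.3)
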