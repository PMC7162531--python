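import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pitburst import _kernel
from pitburst.channels import (
    ChannelPopulation,
    TransitionRates,
    binomial_channel_step,
    channel_count,
    perturbation_quantum,
    transition_rates,
)


class TestChannelCount:
    @pytest.mark.parametrize("g_total,g1,expected", [
        (0.5, 100.0, 5),      # BK
        (3.2, 5.0, 640),      # K
        (2.0, 10.0, 200),     # Ca
        (2.0, 10.0, 200),     # SK
        (0.01, 10.0, 1),      # equal conductances in matched units
    ])
    def test_default_conductances_give_printed_counts(self, g_total, g1, expected):
        assert channel_count(g_total, g1) == expected

    def test_nonpositive_single_conductance_rejected(self):
        with pytest.raises(ValueError):
            channel_count(1.0, 0.0)


class TestPerturbationQuantum:
    @pytest.mark.parametrize("n,expected", [
        (200, 7), (640, 13), (5, 1), (4, 1), (1, 1),
    ])
    def test_sqrt_n_over_two_quartet(self, n, expected):
        assert perturbation_quantum(n) == expected

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            perturbation_quantum(0)


class TestTransitionRates:
    def test_half_activation_gives_symmetric_rates(self):
        r = transition_rates(0.5, 5.0)
        assert r.beta == r.gamma == pytest.approx(0.1)

    def test_full_activation_never_closes(self):
        assert transition_rates(1.0, 5.0).gamma == 0.0

    def test_hand_value(self):
        assert transition_rates(0.73106, 5.0).beta == pytest.approx(0.146212)

    @given(st.floats(0, 1), st.floats(min_value=0.05, max_value=100))
    @settings(max_examples=60, deadline=None)
    def test_rates_sum_to_inverse_time_constant(self, x, tau):
        r = transition_rates(x, tau)
        assert r.beta + r.gamma == pytest.approx(1.0 / tau)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            transition_rates(0.5, 0.0)


def _pop(n_total, n_open, tau=5.0):
    return ChannelPopulation(channel_type="BK", N_total=n_total,
                             N_open=n_open, g1=100.0, tau=tau)


class TestBinomialStep:
    def test_zero_rates_leave_population_unchanged(self):
        rng = np.random.default_rng(0)
        assert binomial_channel_step(_pop(10, 4), TransitionRates(0, 0), 0.01, rng) == 4

    def test_certain_closure_empties_population(self):
        rng = np.random.default_rng(0)
        rates = TransitionRates(beta=0.0, gamma=100.0)
        for _ in range(20):
            assert binomial_channel_step(_pop(10, 7), rates, 0.01, rng) == 0

    def test_probability_above_one_is_an_error_not_a_clamp(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="rate"):
            binomial_channel_step(_pop(10, 4), TransitionRates(150.0, 0.0), 0.01, rng)

    def test_mean_step_matches_analytic_drift(self):
        rng = np.random.default_rng(42)
        pop = _pop(200, 60)
        rates = transition_rates(0.4, 5.0)
        dt = 0.05
        draws = np.array([binomial_channel_step(pop, rates, dt, rng)
                          for _ in range(20000)], dtype=float)
        drift = (pop.N_total - pop.N_open) * rates.beta * dt \
            - pop.N_open * rates.gamma * dt
        se = draws.std() / np.sqrt(draws.size)
        assert (draws - pop.N_open).mean() == pytest.approx(drift, abs=4 * se)

    @given(st.integers(0, 50), st.integers(0, 50),
           st.floats(0, 1), st.floats(0, 1), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_count_stays_within_population(self, n_closed, n_open, pb, pg, seed):
        rng = np.random.default_rng(seed)
        pop = _pop(n_open + n_closed, n_open)
        new = binomial_channel_step(pop, TransitionRates(pb / 0.01, pg / 0.01),
                                    0.01, rng)
        assert 0 <= new <= pop.N_total


class TestStationaryDistribution:
    def test_chain_equilibrates_to_binomial(self):
        """Holding the activation fixed, the open-count chain is
        stationary-binomial with mean x_inf N and variance x_inf(1-x_inf)N."""
        rng = np.random.default_rng(7)
        N, x_inf, tau, dt = 20, 0.4, 1.0, 0.5
        rates = transition_rates(x_inf, tau)
        pop = _pop(N, 0, tau)
        thin = 8  # > 2 tau/dt, decorrelates successive samples
        samples = np.empty(120000, dtype=int)
        for i in range(samples.size):
            for _ in range(thin):
                pop.N_open = binomial_channel_step(pop, rates, dt, rng)
            samples[i] = pop.N_open
        counts = np.bincount(samples, minlength=N + 1)
        expected = stats.binom.pmf(np.arange(N + 1), N, x_inf) * samples.size
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 \
            / max(expected[~keep].sum(), 1.0)
        dof = keep.sum()  # pooled tail adds one cell, minus one constraint
        assert stats.chi2.sf(chi2, dof) > 1e-4
        assert samples.mean() == pytest.approx(N * x_inf, rel=0.02)
        assert samples.var() == pytest.approx(N * x_inf * (1 - x_inf), rel=0.06)

    def test_compiled_sampler_matches_binomial_distribution(self):
        """The kernel's inversion sampler and numpy's binomial agree."""
        st_ = np.zeros((1, 2), dtype=np.uint64)
        _kernel.seed_streams(
            st_, np.random.SeedSequence(3).generate_state(2, np.uint64).reshape(1, 2))
        n, prob = 20, 0.3
        draws = np.array([_kernel.binomial_draw(n, prob, st_[0])
                          for _ in range(100000)])
        counts = np.bincount(draws, minlength=n + 1)
        expected = stats.binom.pmf(np.arange(n + 1), n, prob) * draws.size
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 1e-4


class TestDeterministicLimit:
    def test_large_population_fraction_tracks_gating_ode(self):
        """At N = 10^4 and fixed rates, the open fraction follows the
        exponential relaxation x(t) = x_inf + (x0 - x_inf) e^(-t/tau)."""
        rng = np.random.default_rng(11)
        N, x_inf, tau, dt = 10000, 0.7, 5.0, 0.05
        rates = transition_rates(x_inf, tau)
        pop = _pop(N, 0, tau)
        sigma = np.sqrt(x_inf * (1 - x_inf) / N)
        for k in range(1, 1201):
            pop.N_open = o = binomial_channel_step(pop, rates, dt, rng)
            t = k * dt
            # forward-Euler solution of the ODE, the chain's exact mean
            expected = x_inf * (1.0 - (1.0 - dt / tau) ** k)
            assert o / N == pytest.approx(expected, abs=6 * sigma + 1e-3)
            assert abs(expected - (x_inf * (1 - np.exp(-t / tau)))) < 0.01
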