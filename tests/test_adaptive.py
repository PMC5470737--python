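"""Adaptive life-history model: transitions, dynamic programming, simulation, g4."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divdep import (
    LifeHistoryParams,
    StrategyTable,
    adaptive_g,
    simulate_population,
    solve_strategy,
    transition_distribution,
)
from divdep.adaptive import (
    ALIVE_STATES,
    AT_RISK,
    DEAD,
    MARRIED,
    SEEKING,
    U0,
    U1,
    _transition_tensor,
    measured_annual_divorce_hazard,
)


class TestTransitionDistribution:
    def test_at_risk_depressed_mode_reduces_divorce_raises_death(self):
        p = LifeHistoryParams()
        dist = transition_distribution(AT_RISK, U1, p)
        assert dist[SEEKING] == pytest.approx(0.063)
        assert dist[DEAD] == pytest.approx(0.0040, abs=5e-5)
        assert dist[MARRIED] == pytest.approx(p.d2)  # reconciliation branch

    def test_seeking_marries_at_quarterly_hazard(self):
        dist = transition_distribution(SEEKING, U0, LifeHistoryParams())
        assert dist[MARRIED] == pytest.approx(1.0 - (1.0 - 0.028) ** 0.25)

    def test_depressed_seeking_removes_marriage(self):
        p = LifeHistoryParams()
        assert transition_distribution(SEEKING, U1, p)[MARRIED] == 0.0
        toggled = LifeHistoryParams(rho_removed_when_depressed=False)
        assert transition_distribution(SEEKING, U1, toggled)[MARRIED] == toggled.rho

    def test_dead_is_absorbing(self):
        for mode in (U0, U1):
            dist = transition_distribution(DEAD, mode, LifeHistoryParams())
            assert dist[DEAD] == 1.0 and dist.sum() == 1.0

    def test_negative_residual_rejected(self):
        bad = LifeHistoryParams(d2=0.45, m=0.2)  # at_risk row mass exceeds 1
        with pytest.raises(ValueError):
            transition_distribution(AT_RISK, U0, bad)

    @given(
        m=st.floats(0.0, 0.05),
        z=st.floats(0.0, 0.05),
        s=st.floats(0.0, 0.05),
        rho=st.floats(0.0, 0.3),
        d1=st.floats(0.0, 0.3),
        d2=st.floats(0.05, 0.3),
    )
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, m, z, s, rho, d1, d2):
        params = LifeHistoryParams(m=m, z=z, s=s, rho=rho, d1=d1, d2=d2)
        for state, mode in product(range(4), (U0, U1)):
            dist = transition_distribution(state, mode, params)
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(dist >= 0.0)


class TestSolveStrategy:
    def test_value_invariants(self, solved, default_params):
        _strategy, values = solved
        V = values.V
        assert np.all(V[DEAD] == 0.0)
        assert np.all(V[:, default_params.T] == 0.0)
        assert np.all(np.diff(V, axis=1) <= 1e-12)  # nonincreasing in time

    def test_last_period_never_depressed(self, solved, default_params):
        strategy, _ = solved
        assert not strategy.u1_optimal()[:, default_params.T - 1].any()

    def test_depression_confined_to_at_risk_state(self, solved):
        u1 = solved[0].u1_optimal()
        assert not u1[SEEKING].any()
        assert not u1[MARRIED].any()
        # optimal in at_risk everywhere except a horizon-proximal tail
        col = u1[AT_RISK]
        assert col[:60].all()
        k = int(np.argmax(~col)) if (~col).any() else col.size
        assert np.all(~col[k:])  # once it switches off it stays off

    def test_high_mortality_cost_eliminates_depressed_mode(self):
        """z = 0.06 (about 38-fold mortality) makes u1 non-adaptive everywhere."""
        strategy, _ = solve_strategy(LifeHistoryParams(z=0.06))
        params = LifeHistoryParams(z=0.06)
        assert not strategy.u1_optimal().any()
        assert np.all(strategy.choice_prob <= params.delta)

    def test_benefit_monotonicity_in_s(self):
        sizes = []
        for s in (0.0005, 0.007, 0.02):
            strategy, _ = solve_strategy(LifeHistoryParams(s=s))
            sizes.append(int(strategy.u1_optimal().sum()))
        assert sizes[0] <= sizes[1] <= sizes[2]

    @pytest.mark.parametrize(
        "params",
        [
            LifeHistoryParams(T=3, delta=0.0, m=0.05, z=0.03, s=0.06, rho=0.3, d1=0.2, d2=0.2),
            LifeHistoryParams(T=4, delta=0.0, m=0.02, z=0.01, s=0.04, rho=0.1, d1=0.3, d2=0.25),
            LifeHistoryParams(T=4, delta=0.0, m=0.01, z=0.2, s=0.01, rho=0.4, d1=0.1, d2=0.15),
        ],
    )
    def test_matches_brute_force_policy_enumeration(self, params):
        """DP agrees with exhaustive search over all deterministic policies."""
        T = params.T
        P = _transition_tensor(params, 0)

        def value_of(policy):
            V = np.zeros((4, T + 1))
            for t in range(T - 1, -1, -1):
                fert = params.fertility_at(t)
                for x in ALIVE_STATES:
                    pay = fert if x in (MARRIED, AT_RISK) else 0.0
                    V[x, t] = pay + P[x, policy[x, t]] @ V[:, t + 1]
            return V

        best_V, best_policy = None, None
        for bits in product((0, 1), repeat=3 * T):
            policy = np.array(bits).reshape(3, T)
            V = value_of(policy)
            score = V[:3, 0].sum()
            if best_V is None or score > best_V[:3, 0].sum() + 1e-12:
                best_V, best_policy = V, policy
        strategy, values = solve_strategy(params)
        np.testing.assert_array_equal(strategy.u1_optimal().astype(int), best_policy)
        np.testing.assert_allclose(values.V, best_V, atol=1e-12)


class TestSimulatePopulation:
    def test_deterministic_for_fixed_seed(self, solved, default_params):
        strategy, _ = solved
        a = simulate_population(strategy, default_params, 2000, seed=3)
        b = simulate_population(strategy, default_params, 2000, seed=3)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.modes, b.modes)
        np.testing.assert_array_equal(a.divorce_period, b.divorce_period)

    def test_initial_distribution_multinomial(self, sim50k):
        counts = np.bincount(sim50k.states[:, 0], minlength=4)
        assert counts[3] == 0
        for count, p in zip(counts, (0.97, 0.02, 0.01, 0.0)):
            if p > 0:
                se = np.sqrt(p * (1 - p) * 50_000)
                assert abs(count - p * 50_000) < 4 * se

    def test_invalid_init_dist_rejected(self, solved, default_params):
        with pytest.raises(ValueError):
            simulate_population(solved[0], default_params, 100, init_dist=(0.5, 0.5, 0.5, 0))

    def test_dead_is_absorbing_in_trajectories(self, sim50k):
        dead = sim50k.states == DEAD
        assert not np.any(~dead[:, 1:] & dead[:, :-1])

    def test_transitions_follow_allowed_graph(self, sim50k):
        cur, nxt = sim50k.states[:, :-1], sim50k.states[:, 1:]
        # seeking can only go to seeking, married or dead
        assert not np.any((cur == SEEKING) & (nxt == AT_RISK))
        # married cannot divorce directly to seeking
        assert not np.any((cur == MARRIED) & (nxt == SEEKING))

    def test_baseline_mortality_one_in_eight(self, default_params):
        """Forced non-depressed behaviour reproduces the 1/8 mortality calibration."""
        all_u0 = StrategyTable(np.zeros((3, default_params.T)))
        sim = simulate_population(all_u0, default_params, 50_000, seed=21)
        frac_dead = float((sim.states[:, -1] == DEAD).mean())
        expected = 1.0 - (1.0 - default_params.m) ** default_params.T
        se = np.sqrt(expected * (1 - expected) / 50_000)
        assert abs(frac_dead - 1.0 / 8.0) < 3 * se + abs(expected - 1.0 / 8.0)

    def test_neutral_modes_leave_divorce_hazard_unchanged(self, default_params):
        """With s = z = 0 the mode has no effect on divorce-like transitions."""
        params = LifeHistoryParams(s=0.0, z=0.0, rho_removed_when_depressed=False)
        strategy, _ = solve_strategy(params)
        all_u0 = StrategyTable(np.zeros((3, params.T)))
        h1 = measured_annual_divorce_hazard(
            simulate_population(strategy, params, 30_000, seed=2)
        )
        h0 = measured_annual_divorce_hazard(
            simulate_population(all_u0, params, 30_000, seed=4)
        )
        assert h1 == pytest.approx(h0, rel=0.05)


class TestAdaptiveG:
    def test_events_near_boundaries_excluded(self, sim50k, default_params):
        g4 = adaptive_g(sim50k)
        td = sim50k.divorce_period
        usable = (td >= 20) & (td <= default_params.T - 20)
        assert g4.meta["n_events"] == int(usable.sum())
        assert g4.meta["n_events"] < int((td >= 0).sum())  # some events excluded

    def test_grid_is_41_point_divorce_centred(self, sim50k):
        g4 = adaptive_g(sim50k)
        assert g4.n == 41
        assert g4.times[0] == -60.0 and g4.times[-1] == 60.0

    def test_peak_close_to_one_without_rescaling(self, sim50k):
        g4 = adaptive_g(sim50k, shift=0)
        assert 0.95 < g4.values.max() <= 1.0

    def test_leftward_shift_moves_peak(self, sim50k):
        unshifted = adaptive_g(sim50k, shift=0)
        shifted = adaptive_g(sim50k, shift=1)
        assert shifted.times[np.argmax(shifted.values)] == (
            unshifted.times[np.argmax(unshifted.values)] - 3.0
        )

    def test_never_depressed_population_gives_flat_zero_curve(self, default_params):
        all_u0 = StrategyTable(np.zeros((3, default_params.T)))
        sim = simulate_population(all_u0, default_params, 20_000, seed=8)
        g4 = adaptive_g(sim)
        assert np.all(g4.values == 0.0)

    def test_no_usable_events_errors(self):
        params = LifeHistoryParams(T=30)  # exclusion windows leave nothing usable
        strategy, _ = solve_strategy(params)
        sim = simulate_population(strategy, params, 50, seed=1)
        with pytest.raises(ValueError):
            adaptive_g(sim, boundary_exclusion=16)
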