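"""Finite-volume transport: conservation, positivity, boundaries, detection."""

import math

import numpy as np
import pytest

from stemage import (
    FeedbackConfig,
    GridSpec,
    ModelParams,
    PopulationState,
    SegregationRule,
    Trace,
    cfl_dt,
    damage_marginal_at_division,
    death_rates,
    default_initial_state,
    delta_initial_state,
    detect_steady_state,
    make_grid,
    oracle_population_curve,
    simulate,
    step,
    synchronized_grid,
)


@pytest.fixture(scope="module")
def small_grid(base_params):
    return make_grid(base_params, GridSpec(32, 32, 16, 16))


def _gaussian_bump(grid, p0, a0, sigma):
    P, A = np.meshgrid(grid.p_centers_S, grid.a_centers_S, indexing="ij")
    return np.exp(-((P - p0) ** 2 + (A - a0) ** 2) / (2 * sigma**2))


class TestStep:
    def test_interior_advection_conserves_and_shifts(self, base_params, fb_none, small_grid):
        """A compact bump far from all boundaries advects by (V_p dt, v_a dt)
        with total mass unchanged to machine precision."""
        grid = small_grid
        rule = SegregationRule(alpha1=0.5, gamma1=0.1)
        S = _gaussian_bump(grid, 0.4, 0.4, 0.05)
        state = PopulationState(S=S, T=np.zeros((16, 16)), t=0.0)
        dt = cfl_dt(base_params, fb_none, grid)
        mass0 = S.sum()
        pbar0 = (S * grid.p_centers_S[:, None]).sum() / mass0
        abar0 = (S * grid.a_centers_S[None, :]).sum() / mass0
        new, diag = step(state, base_params, rule, fb_none, grid, dt)
        mass1 = new.S.sum()
        assert mass1 == pytest.approx(mass0, rel=1e-13)
        pbar1 = (new.S * grid.p_centers_S[:, None]).sum() / mass1
        abar1 = (new.S * grid.a_centers_S[None, :]).sum() / mass1
        assert pbar1 - pbar0 == pytest.approx(base_params.v_p * dt, rel=1e-10)
        assert abar1 - abar0 == pytest.approx(base_params.v_a * dt, rel=1e-10)
        assert diag["deaths_S"] == pytest.approx(0.0, abs=1e-20)
        assert diag["mothers"] == pytest.approx(0.0, abs=1e-20)

    def test_cfl_violation_rejected(self, base_params, fb_none, small_grid):
        rule = SegregationRule()
        state = default_initial_state(base_params, small_grid)
        dt = cfl_dt(base_params, fb_none, small_grid, safety=1.0)
        with pytest.raises(ValueError, match="CFL"):
            step(state, base_params, rule, fb_none, small_grid, 2.1 * dt)

    def test_positivity_for_random_initial_data(self, base_params, fb_none, small_grid, rng):
        rule = SegregationRule(alpha1=0.3, gamma1=0.2)
        state = PopulationState(
            S=rng.random((32, 32)), T=rng.random((16, 16)), t=0.0
        )
        dt = cfl_dt(base_params, fb_none, small_grid)
        for _ in range(50):
            state, _ = step(state, base_params, rule, fb_none, small_grid, dt)
        assert state.S.min() >= 0 and state.T.min() >= 0

    def test_bookkeeping_identity(self, base_params, fb_td, small_grid):
        """Cumulative births - mothers - deaths accounts for the population
        change in each compartment over a whole run."""
        rule = SegregationRule(alpha1=0.3, gamma1=0.3)
        trace = simulate(
            base_params, rule, fb_td, small_grid,
            init={"kind": "default", "total": 1e6},
            t_end=60.0, record_every=1.0, stop_on_steady=False,
            floor=0.0, ceiling=1e30,
        )
        dP_S = trace.P_S[-1] - 1e6
        budget_S = trace.cum_births_S - trace.cum_mothers - trace.cum_deaths_S
        assert dP_S == pytest.approx(budget_S, rel=1e-8)
        dP_T = trace.P_T[-1] - 0.0
        budget_T = trace.cum_births_T - trace.cum_deaths_T - trace.cum_escape_T
        assert dP_T == pytest.approx(budget_T, rel=1e-8)


class TestDeathRates:
    def test_uniform_density_closed_form(self, base_params, small_grid):
        """Uniform S density: r_S = v_a/a_star; uniform T: r_T = u_a/a_c."""
        s0 = 3.7
        state = PopulationState(S=np.full((32, 32), s0), T=np.full((16, 16), 2.2), t=0.0)
        r_S, r_T = death_rates(state, base_params, small_grid)
        assert r_S == pytest.approx(base_params.v_a / base_params.a_star, rel=1e-12)
        assert r_T == pytest.approx(base_params.u_a / base_params.a_c, rel=1e-12)

    def test_no_mass_near_boundary_gives_zero(self, base_params, small_grid):
        S = np.zeros((32, 32))
        S[:, :16] = 1.0
        state = PopulationState(S=S, T=np.ones((16, 16)), t=0.0)
        r_S, _ = death_rates(state, base_params, small_grid)
        assert r_S == 0.0

    def test_empty_compartment_is_nan_sentinel(self, base_params, small_grid):
        state = PopulationState(S=np.zeros((32, 32)), T=np.zeros((16, 16)), t=0.0)
        r_S, r_T = death_rates(state, base_params, small_grid)
        assert math.isnan(r_S) and math.isnan(r_T)


def _trace_from_series(t, P):
    n = np.asarray(P)
    z = np.full_like(n, np.nan, dtype=float)
    return Trace(
        times=np.asarray(t, dtype=float), P_S=n, P_T=n.copy(),
        r_S=z, r_T=z.copy(), delta1=z.copy(), delta2=z.copy(), delta3=z.copy(),
        termination="t_end", steady=None, final_state=None,
    )


class TestDetectSteadyState:
    def test_constant_series_is_steady(self):
        t = np.linspace(0, 100, 201)
        tr = _trace_from_series(t, np.full_like(t, 5.0))
        ok, vals = detect_steady_state(tr, rel_tol=1e-5, window=50.0)
        assert ok and vals["P_S"] == pytest.approx(5.0)

    def test_growing_series_is_not_steady(self):
        t = np.linspace(0, 100, 201)
        tr = _trace_from_series(t, np.exp(0.01 * t))
        ok, _ = detect_steady_state(tr, rel_tol=1e-5, window=50.0)
        assert not ok

    def test_damped_oscillation_becomes_steady(self):
        t = np.linspace(0, 400, 2001)
        P = 10.0 * (1 + 0.5 * np.exp(-t / 20) * np.cos(t))
        tr = _trace_from_series(t, P)
        ok_early, _ = detect_steady_state(
            _trace_from_series(t[t < 100], P[t < 100]), rel_tol=1e-4, window=50.0
        )
        ok_late, vals = detect_steady_state(tr, rel_tol=1e-4, window=50.0)
        assert not ok_early
        assert ok_late
        assert vals["P_S"] == pytest.approx(10.0, rel=1e-3)


class TestDamageMarginal:
    def test_point_mass_gives_point_marginal(self, base_params, small_grid):
        S = np.zeros((32, 32))
        S[-1, 7] = 4.2
        state = PopulationState(S=S, T=np.zeros((16, 16)), t=0.0)
        m, ok = damage_marginal_at_division(state, small_grid)
        assert ok
        assert m.sum() * small_grid.da_S == pytest.approx(1.0)
        assert np.count_nonzero(m) == 1 and m[7] > 0

    def test_empty_slice_flagged(self, base_params, small_grid):
        state = PopulationState(S=np.zeros((32, 32)), T=np.zeros((16, 16)), t=0.0)
        m, ok = damage_marginal_at_division(state, small_grid)
        assert not ok and np.all(m == 0)


class TestSimulate:
    def test_subcritical_renewal_hits_extinction_floor(self, base_params, fb_none):
        p = ModelParams(delta0=(0.2, 0.5, 0.3))
        grid, dt = synchronized_grid(p, n_p_min=12, n_p_T=8, n_a_T=8)
        trace = simulate(
            p, SegregationRule(alpha1=0.4, gamma1=0.1), fb_none, grid,
            init={"kind": "delta", "a0": 0.0, "total": 1.0},
            t_end=600.0, record_every=5.0, dt=dt, stop_on_steady=False,
        )
        assert trace.termination == "extinct"

    def test_pde_matches_oracle_exactly_on_synchronized_grid(self, base_params, fb_none):
        """With Courant number 1 the solver reduces to the exact branching map."""
        rule = SegregationRule(alpha1=0.4, gamma1=0.1)
        grid, dt = synchronized_grid(base_params, n_p_min=12, n_p_T=8, n_a_T=8)
        cycle = base_params.cycle_time
        trace = simulate(
            base_params, rule, fb_none, grid,
            init={"kind": "delta", "a0": 0.0, "total": 1.0},
            t_end=5 * cycle + 2 * dt, record_every=dt, dt=dt,
            stop_on_steady=False, floor=0.0, ceiling=1e30,
        )
        curve = oracle_population_curve([(0.0, 1.0)], base_params, rule, (0.6, 0.3, 0.1), 5)
        mid = (np.arange(5) + 0.5) * cycle
        P_mid = np.interp(mid, trace.times, trace.P_S)
        np.testing.assert_allclose(P_mid, curve.stem_weight.values[:5], rtol=1e-10)

    def test_steady_state_termination_under_td_feedback(self, base_params, fb_td):
        grid = make_grid(base_params, GridSpec(48, 48, 16, 16))
        trace = simulate(
            base_params, SegregationRule(alpha1=0.5, gamma1=0.1), fb_td, grid,
            t_end=2000.0, record_every=1.0, steady_rel_tol=1e-4,
        )
        assert trace.termination == "steady"
        assert trace.steady["P_T"] > trace.steady["P_S"] > 0
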