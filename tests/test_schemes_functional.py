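"""Functional-relationship schemes: deficit filling, allometric solver,
and their functional-balance behaviour."""

import math

import numpy as np
import pytest

from standalloc.core import AllocationVector, Environment, PoolState, TurnoverVector
from standalloc.diagnostics import diagnostics_table
from standalloc.driver import SimulationConfig, make_scheme, run_simulation
from standalloc.errors import InvalidArgumentError, NoGrowthError
from standalloc.schemes.functional import (
    Ed2Params,
    LpjParams,
    ed2_alloc,
    geometry_from_wood,
    lpj_alloc_annual,
    ocn_daily_alloc,
)
from standalloc.synthetic import duke_scenario, generate_forcing

ENV = Environment(co2=400, W=1.0, Nfac=1.0)


def _on_target_state(params: Ed2Params, env: Environment) -> PoolState:
    """Construct pools whose leaf and root sit exactly at their targets."""
    q = params.q_base + params.q_stress_gain * (1 - min(env.W, env.Nfac))
    denom = 1 + q + params.q_sw * params.height
    b_w = 5.0
    # solve B_f, B_r so B_f = (B_f+B_r+B_w)/denom and B_r = q*B_f
    b_f = b_w / (denom - 1 - q)
    return PoolState(B_f=b_f, B_w=b_w, B_r=q * b_f)


class TestEd2:
    def test_reserve_splits_70_30_when_pools_at_target(self):
        params = Ed2Params()
        state = _on_target_state(params, ENV)
        vec = ed2_alloc(state, ENV, e_t=1.0, params=params, growth_c=0.01)
        assert vec.a_w == pytest.approx(0.70, abs=1e-9)
        assert vec.a_rep == pytest.approx(0.30, abs=1e-9)

    def test_leaf_off_phenology_shuts_leaf_allocation(self):
        vec = ed2_alloc(PoolState(0.1, 5.0, 0.2), ENV, 0.0, Ed2Params(), 0.5)
        assert vec.a_f == 0.0

    @pytest.mark.parametrize("stress", [1.0, 0.5, 0.0])
    def test_root_share_non_decreasing_in_q(self, stress):
        # hand oracle: lowering min(W, N) raises q, raising the root
        # target and hence the root share at fixed pools and growth C
        params = Ed2Params()
        state = PoolState(0.3, 5.0, 0.2)
        env_lo = Environment(co2=400, W=1.0, Nfac=1.0)
        env_hi = Environment(co2=400, W=stress, Nfac=stress)
        a_lo = ed2_alloc(state, env_lo, 1.0, params, 0.5).a_r
        a_hi = ed2_alloc(state, env_hi, 1.0, params, 0.5).a_r
        assert a_hi >= a_lo - 1e-12

    def test_zero_growth_carbon_flagged(self):
        with pytest.raises(NoGrowthError):
            ed2_alloc(PoolState(0.1, 1.0, 0.1), ENV, 1.0, Ed2Params(), 0.0)

    def test_e_t_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ed2_alloc(PoolState(), ENV, 1.2, Ed2Params(), 0.5)


def _brute_force_leaf_increment(pools, available, ratio_fr, params, resolution=1e-6):
    """Exhaustive 1-D scan of the leaf increment; the balance constraint
    eliminates the root increment and the remainder goes to wood."""
    best_dc_f, best_gap = 0.0, math.inf
    n = int(1.0 / resolution)
    for i in range(n + 1):
        dc_f = available * i / n
        c_f = pools.B_f + dc_f
        dc_r = max(0.0, c_f / ratio_fr - pools.B_r)
        dc_w = available - dc_f - dc_r
        if dc_w < 0:
            break
        sa = geometry_from_wood(pools.B_w + dc_w, params).SA
        gap = abs(params.sla * c_f - params.k_la_sa * sa)
        if gap < best_gap:
            best_gap, best_dc_f = gap, dc_f
    return best_dc_f


class TestLpjSolver:
    def test_reproduction_gets_ten_percent_first(self):
        params = LpjParams()
        pools = PoolState(0.2, 8.0, 0.2)
        res = lpj_alloc_annual(pools, geometry_from_wood(8.0, params), 0.7, ENV, params)
        assert res.alloc.a_rep == pytest.approx(0.10, abs=1e-12)

    def test_solver_matches_brute_force_scan(self):
        # oracle: exhaustive 1-D scan at 1e-6 resolution on random stands
        rng = np.random.default_rng(42)
        params = LpjParams()
        for _ in range(20):
            pools = PoolState(
                B_f=float(rng.uniform(0.05, 0.6)),
                B_w=float(rng.uniform(2.0, 15.0)),
                B_r=float(rng.uniform(0.05, 0.6)),
            )
            env = Environment(
                co2=400, W=float(rng.uniform(0.4, 1.0)), Nfac=float(rng.uniform(0.4, 1.0))
            )
            npp = float(rng.uniform(0.2, 1.5))
            ratio = params.lr_max * min(env.Nfac, env.W)
            available = (1 - params.repro_fraction) * npp
            res = lpj_alloc_annual(pools, geometry_from_wood(pools.B_w, params), npp, env, params)
            dc_f_solver = res.alloc.a_f * npp
            dc_f_brute = _brute_force_leaf_increment(pools, available, ratio, params)
            assert dc_f_solver == pytest.approx(dc_f_brute, abs=available * 2e-5 + 1e-5)

    def test_constraints_hold_after_allocation(self):
        params = LpjParams()
        pools = PoolState(0.2, 8.0, 0.25)
        env = Environment(co2=400, W=0.9, Nfac=0.8)
        npp = 0.8
        res = lpj_alloc_annual(pools, geometry_from_wood(pools.B_w, params), npp, env, params)
        if res.on_allometry:
            c_f = pools.B_f + res.alloc.a_f * npp
            c_w = pools.B_w + res.alloc.a_w * npp
            c_r = pools.B_r + res.alloc.a_r * npp
            geom = geometry_from_wood(c_w, params)
            assert params.sla * c_f == pytest.approx(params.k_la_sa * geom.SA, rel=1e-6)
            assert geom.H == pytest.approx(params.k_allom2 * geom.D**params.k_allom3, rel=1e-9)
            assert c_f / c_r <= params.lr_max * min(env.Nfac, env.W) + 1e-9

    def test_small_npp_limit_preserves_leaf_root_ratio(self):
        # on allometry with N=W=1, an infinitesimal allocation keeps
        # C_f : C_r at lr_max : 1
        params = LpjParams()
        b_w = 8.0
        geom = geometry_from_wood(b_w, params)
        b_f = params.k_la_sa * geom.SA / params.sla
        pools = PoolState(B_f=b_f, B_w=b_w, B_r=b_f / params.lr_max)
        res = lpj_alloc_annual(pools, geom, 1e-6, ENV, params)
        c_f = pools.B_f + res.alloc.a_f * 1e-6
        c_r = pools.B_r + res.alloc.a_r * 1e-6
        assert c_f / c_r == pytest.approx(params.lr_max, rel=1e-6)

    def test_off_allometry_stand_flagged_without_negative_increments(self):
        params = LpjParams()
        # huge canopy on a tiny stem: no non-negative solution
        pools = PoolState(B_f=3.0, B_w=0.5, B_r=0.1)
        res = lpj_alloc_annual(pools, geometry_from_wood(0.5, params), 0.5, ENV, params)
        assert not res.on_allometry
        assert min(res.alloc.as_tuple()) >= 0.0

    def test_zero_year_flagged(self):
        params = LpjParams()
        with pytest.raises(NoGrowthError):
            lpj_alloc_annual(PoolState(0.1, 5, 0.1), geometry_from_wood(5, params), 0.0, ENV, params)


class TestOcnDaily:
    def test_requires_daily_mode(self):
        with pytest.raises(InvalidArgumentError):
            ocn_daily_alloc(
                PoolState(0.1, 5, 0.1), geometry_from_wood(5, LpjParams()),
                0.002, ENV, LpjParams(daily_mode=False),
            )

    def test_year_of_daily_steps_approximates_annual_allocation(self):
        # oracle: run both modes on identical forcing and compare the
        # component totals
        params_d = LpjParams(daily_mode=True)
        params_a = LpjParams()
        npp = 0.7
        pools = PoolState(0.2, 8.0, 0.22)

        res_a = lpj_alloc_annual(pools, geometry_from_wood(pools.B_w, params_a), npp, ENV, params_a)
        annual = {c: getattr(res_a.alloc, "a_" + c) * npp for c in ("f", "w", "r", "rep")}

        state = pools
        geom = geometry_from_wood(pools.B_w, params_d)
        daily = {c: 0.0 for c in ("f", "w", "r", "rep")}
        for _ in range(365):
            res = ocn_daily_alloc(state, geom, npp / 365, ENV, params_d)
            geom = res.geometry
            inc = {c: getattr(res.alloc, "a_" + c) * npp / 365 for c in daily}
            state = PoolState(
                state.B_f + inc["f"], state.B_w + inc["w"],
                state.B_r + inc["r"], state.B_rep + inc["rep"],
            )
            for c in daily:
                daily[c] += inc[c]

        for c in ("f", "w", "r", "rep"):
            assert daily[c] == pytest.approx(annual[c], rel=0.02, abs=0.02 * npp)

    def test_zero_npp_day_has_no_allocation(self):
        params = LpjParams(daily_mode=True)
        with pytest.raises(NoGrowthError):
            ocn_daily_alloc(PoolState(0.1, 5, 0.1), geometry_from_wood(5, params), 0.0, ENV, params)

    def test_declining_nitrogen_raises_cumulative_root_share(self):
        # finite-difference sign check: the same run with Nfac declining
        # ends with a larger cumulative root share than with Nfac = 1
        params = LpjParams(daily_mode=True)

        def cumulative_root(n_trajectory):
            state = PoolState(0.2, 8.0, 0.22)
            geom = geometry_from_wood(state.B_w, params)
            tot_r = tot = 0.0
            for day in range(2 * 365):
                env = Environment(co2=400, W=1.0, Nfac=n_trajectory(day))
                res = ocn_daily_alloc(state, geom, 0.8 / 365, env, params)
                geom = res.geometry
                inc = [getattr(res.alloc, "a_" + c) * 0.8 / 365 for c in ("f", "w", "r", "rep")]
                state = PoolState(
                    state.B_f + inc[0], state.B_w + inc[1],
                    state.B_r + inc[2], state.B_rep + inc[3],
                )
                tot_r += inc[2]
                tot += sum(inc)
            return tot_r / tot

        flat = cumulative_root(lambda day: 1.0)
        declining = cumulative_root(lambda day: max(0.3, 1.0 - 0.4 * day / 365))
        assert declining > flat


class TestFunctionalBalanceProperty:
    def test_stress_raises_equilibrium_root_to_leaf_ratio(self, evergreen_turnover):
        # paired 10-yr runs differing only in the N scalar
        scn = duke_scenario(noise_cv=0.0)
        params = LpjParams()

        def final_ratio(nfac):
            import numpy as np
            from standalloc.driver import Forcing, DAYS_PER_YEAR

            n = scn.n_years * DAYS_PER_YEAR
            f = generate_forcing(scn, "ambient")
            forcing = Forcing(
                npp=f.npp, co2=f.co2, W=f.W,
                Nfac=np.full(n, nfac), degree_days=f.degree_days,
            )
            cfg = SimulationConfig(
                initial_state=scn.initial_state, turnover=evergreen_turnover,
                sla=scn.sla, treatment="ambient",
            )
            sim = run_simulation(make_scheme("lpj", params), forcing, cfg)
            return sim.final_state.B_r / sim.final_state.B_f

        assert final_ratio(0.5) > final_ratio(1.0)
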