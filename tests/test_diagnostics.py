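"""Observation-convention diagnostics and their recovery behaviour."""

import math

import pytest

from standalloc.core import AllocationVector, PoolState, TurnoverVector, step_pools
from standalloc.diagnostics import (
    AnnualRecord,
    allocation_fractions,
    canopy_sla,
    co2_response_ratio,
    diagnostics_table,
    npp_retention,
    turnover_lifespan,
)
from standalloc.driver import SimulationConfig, make_scheme, run_simulation
from standalloc.errors import InvalidArgumentError
from standalloc.schemes.fixed import FixedSchemeParams
from standalloc.synthetic import duke_scenario, generate_forcing


def record(**kw):
    base = dict(
        year=0, npp_f=0.2, npp_w=0.6, npp_r=0.2, npp_rep=0.0,
        litter_f=0.1, litter_w=0.05, litter_r=0.1,
        bmax_f=0.4, bmax_w=8.0, bmax_r=0.3, lai_max=4.0,
    )
    base.update(kw)
    return AnnualRecord(**base)


class TestAllocationFractions:
    def test_normalised_components_pass_through(self):
        fr = allocation_fractions(record())
        assert (fr["f"], fr["w"], fr["r"]) == (0.2, 0.6, 0.2)

    def test_single_sink(self):
        fr = allocation_fractions(record(npp_f=0.0, npp_w=1.3, npp_r=0.0))
        assert fr["w"] == 1.0 and fr["f"] == fr["r"] == 0.0

    def test_zero_year_flagged_as_missing(self):
        with pytest.raises(InvalidArgumentError, match="missing"):
            allocation_fractions(record(npp_f=0, npp_w=0, npp_r=0, npp_rep=0))

    def test_missing_years_dropped_from_table_means(self):
        recs = [
            record(year=0),
            record(year=1, npp_f=0, npp_w=0, npp_r=0, npp_rep=0),
            record(year=2),
        ]
        table = diagnostics_table(recs)
        assert table.n_missing_years == 1
        assert table.mean_alloc["w"] == pytest.approx(0.6)


class TestTurnoverLifespan:
    def test_forced_arithmetic(self):
        rate, life = turnover_lifespan(record(bmax_w=2.0, litter_w=1.0), "w")
        assert rate == 0.5 and life == 2.0

    def test_zero_litter_gives_infinite_lifespan(self):
        rate, life = turnover_lifespan(record(litter_w=0.0), "w")
        assert rate == 0.0 and math.isinf(life)

    def test_simulated_turnover_recovered_near_equilibrium(self, closed_stand):
        # oracle: the stepper run with known u_f = 0.5 must yield a
        # diagnostic lifespan of 2.0 within 5% once pools equilibrate
        scn = duke_scenario(noise_cv=0.0, n_years=30)
        turn = TurnoverVector(u_f=0.5, u_w=0.02, u_r=0.5)
        cfg = SimulationConfig(initial_state=closed_stand, turnover=turn, sla=scn.sla)
        params = FixedSchemeParams(base=AllocationVector(0.3, 0.45, 0.25))
        sim = run_simulation(make_scheme("fixed", params), generate_forcing(scn, "ambient"), cfg)
        table = diagnostics_table(sim.records[20:])
        assert table.mean_lifespan["f"] == pytest.approx(2.0, rel=0.05)


class TestCanopySla:
    def test_forced_arithmetic_and_scale_invariance(self):
        assert canopy_sla(4.0, 0.2) == 20.0
        assert canopy_sla(8.0, 0.4) == 20.0

    def test_zero_foliage_rejected(self):
        with pytest.raises(InvalidArgumentError):
            canopy_sla(4.0, 0.0)


class TestResponseRatio:
    def test_identity_and_uniform_scaling(self):
        assert co2_response_ratio([1.0, 2.0], [1.0, 2.0]) == 1.0
        assert co2_response_ratio([1.2, 2.4], [1.0, 2.0]) == pytest.approx(1.2)

    def test_annual_maxima_of_monthly_series(self):
        # hand-rolled oracle: per-year max, then the ratio of means,
        # with differing peak months between treatments
        amb = [[1, 5, 2], [2, 3, 1]]
        ele = [[2, 1, 6], [4, 1, 2]]
        expected = ((6 + 4) / 2) / ((5 + 3) / 2)
        got = co2_response_ratio([max(y) for y in ele], [max(y) for y in amb])
        assert got == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            co2_response_ratio([1.0, 2.0], [1.0])


class TestNppRetention:
    def test_closed_system_retains_everything(self):
        # all extra NPP into a zero-turnover pool
        assert npp_retention(10.0, 12.0, 3.0, 5.0) == pytest.approx(100.0)

    def test_full_turnover_retains_nothing(self):
        assert npp_retention(10.0, 12.0, 3.0, 3.0) == pytest.approx(0.0)

    def test_matches_flux_bookkeeping_oracle(self):
        # 10-yr twin runs differing only in extra NPP to wood at
        # u_w = 0.02: retention must equal the cumulative-litter ledger
        alloc = AllocationVector(0.0, 1.0, 0.0)
        turn = TurnoverVector(0.0, 0.02, 0.0)
        dt = 1 / 365

        def run(npp):
            state = PoolState()
            cum_npp = cum_litter = 0.0
            for _ in range(10 * 365):
                res = step_pools(state, npp, alloc, turn, dt)
                state = res.state
                cum_npp += npp * dt
                cum_litter += res.litter_total
            return state, cum_npp, cum_litter

        s_a, npp_a, lit_a = run(1.0)
        s_e, npp_e, lit_e = run(1.2)
        got = npp_retention(npp_a, npp_e, s_a.total(), s_e.total())
        expected = 100.0 * (1.0 - (lit_e - lit_a) / (npp_e - npp_a))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_undefined_without_npp_difference(self):
        with pytest.raises(InvalidArgumentError):
            npp_retention(10.0, 10.0, 3.0, 4.0)


class TestMassBalanceClosure:
    def test_simulated_run_closes_through_the_diagnostics_path(self, closed_stand, evergreen_turnover):
        scn = duke_scenario(noise_cv=0.0)
        cfg = SimulationConfig(initial_state=closed_stand, turnover=evergreen_turnover, sla=scn.sla)
        params = FixedSchemeParams(base=AllocationVector(0.3, 0.45, 0.25))
        sim = run_simulation(make_scheme("fixed", params), generate_forcing(scn, "ambient"), cfg)
        npp_total = sum(r.npp_total for r in sim.records)
        litter_total = sum(r.litter_total for r in sim.records)
        assert npp_total == pytest.approx(sim.delta_biomass + litter_total, rel=1e-6)
        assert npp_total == pytest.approx(sim.cum_npp, rel=1e-9)
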