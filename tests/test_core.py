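"""Pool stepper and phenology clock."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from standalloc.core import (
    AllocationVector,
    Environment,
    PhenologyParams,
    PhenoPhase,
    PoolState,
    TurnoverVector,
    advance_phenology,
    step_pools,
)
from standalloc.errors import InvalidArgumentError, StabilityError

ZERO_U = TurnoverVector(0, 0, 0)


class TestStepPools:
    def test_identity_with_zero_npp_and_turnover(self):
        state = PoolState(0.4, 5.0, 0.3, 0.1)
        res = step_pools(state, 0.0, AllocationVector(0.25, 0.5, 0.25), ZERO_U, 1 / 365)
        assert res.state == state
        assert res.litter_total == 0.0

    def test_single_sink_growth(self):
        res = step_pools(
            PoolState(), 1.0, AllocationVector(1, 0, 0, 0), ZERO_U, 1.0
        )
        assert res.state.B_f == pytest.approx(1.0)
        assert res.state.B_w == res.state.B_r == res.state.B_rep == 0.0

    def test_steady_state_matches_closed_form(self):
        # oracle: long fixed-point iteration of the stepper itself must
        # converge to a_w*npp/u_w = 0.5*1.0/0.02 = 25.0
        alloc = AllocationVector(0.25, 0.5, 0.25)
        turn = TurnoverVector(0.5, 0.02, 0.5)
        state = PoolState()
        dt = 1 / 52
        for _ in range(52 * 800):  # 800 yr >> 1/u_w
            state = step_pools(state, 1.0, alloc, turn, dt).state
        assert state.B_w == pytest.approx(25.0, rel=1e-3)

    def test_linear_growth_without_turnover(self):
        alloc = AllocationVector(0.2, 0.5, 0.2, 0.1)
        state = PoolState()
        for _ in range(365 * 3):
            state = step_pools(state, 2.0, alloc, ZERO_U, 1 / 365).state
        # B_i(T) = a_i * npp * T exactly (sums of identical increments)
        assert state.B_f == pytest.approx(0.2 * 2.0 * 3, rel=1e-12)
        assert state.B_w == pytest.approx(0.5 * 2.0 * 3, rel=1e-12)
        assert state.B_rep == pytest.approx(0.1 * 2.0 * 3, rel=1e-12)

    @given(
        b=st.tuples(*[st.floats(0, 50)] * 4),
        a=st.tuples(*[st.floats(0, 1)] * 4),
        u=st.tuples(*[st.floats(0, 30)] * 3),
        npp=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_conservation_property(self, b, a, u, npp):
        total_a = sum(a)
        if total_a == 0:
            a = (0.25, 0.25, 0.25, 0.25)
            total_a = 1.0
        alloc = AllocationVector(*(x / total_a for x in a))
        state = PoolState(*b)
        dt = 1 / 365
        res = step_pools(state, npp, alloc, TurnoverVector(*u), dt)
        gain = npp * dt
        assert res.state.total() - state.total() == pytest.approx(
            gain - res.litter_total, rel=1e-9, abs=1e-12
        )
        for field in ("B_f", "B_w", "B_r", "B_rep"):
            assert getattr(res.state, field) >= 0

    def test_dt_refinement_converges(self):
        # halving dt changes a 10-yr trajectory by < 1% once dt <= 1 day
        alloc = AllocationVector(0.3, 0.45, 0.25)
        turn = TurnoverVector(0.5, 0.02, 0.7)

        def run(dt_inv):
            state = PoolState(0.1, 1.0, 0.1)
            for _ in range(10 * dt_inv):
                state = step_pools(state, 1.0, alloc, turn, 1 / dt_inv).state
            return state

        coarse, fine = run(365), run(730)
        for field in ("B_f", "B_w", "B_r"):
            c, f = getattr(coarse, field), getattr(fine, field)
            assert abs(c - f) / f < 0.01

    def test_rejects_invalid_arguments(self):
        alloc = AllocationVector(1, 0, 0)
        with pytest.raises(InvalidArgumentError):
            step_pools(PoolState(), -1.0, alloc, ZERO_U, 1.0)
        with pytest.raises(InvalidArgumentError):
            step_pools(PoolState(), 1.0, alloc, ZERO_U, 0.0)

    def test_stability_guard_names_component(self):
        with pytest.raises(StabilityError, match="'r'"):
            step_pools(
                PoolState(), 1.0, AllocationVector(1, 0, 0),
                TurnoverVector(0.5, 0.02, 400.0), 1 / 365,
            )


class TestDomainTypes:
    def test_allocation_vector_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            AllocationVector(0.5, 0.4, 0.2)

    def test_pools_must_be_non_negative(self):
        with pytest.raises(InvalidArgumentError):
            PoolState(B_f=-0.1)

    def test_environment_scalar_bounds(self):
        with pytest.raises(InvalidArgumentError):
            Environment(W=1.5)
        with pytest.raises(InvalidArgumentError):
            Environment(co2=0.0)

    def test_turnover_lifespan(self):
        t = TurnoverVector(0.5, 0.0, 2.0)
        assert t.lifespan("f") == 2.0
        assert t.lifespan("w") == math.inf


class TestPhenology:
    params = PhenologyParams()

    def env(self, doy=180, dd=500.0):
        return Environment(t_day=doy, degree_days=dd)

    def test_expansion_ends_at_half_max_lai(self):
        next_phase = advance_phenology(
            self.env(doy=150), lai=3.0, lai_max=6.0,
            params=self.params, prev=PhenoPhase.LEAF_EXPANSION,
        )
        assert next_phase is PhenoPhase.STEADY_GROWTH
        still = advance_phenology(
            self.env(doy=150), lai=2.9, lai_max=6.0,
            params=self.params, prev=PhenoPhase.LEAF_EXPANSION,
        )
        assert still is PhenoPhase.LEAF_EXPANSION

    def test_senescence_below_95pct_after_peak(self):
        assert advance_phenology(
            self.env(doy=230), lai=5.6, lai_max=6.0,
            params=self.params, prev=PhenoPhase.STEADY_GROWTH,
        ) is PhenoPhase.SENESCENCE
        # the same LAI before the peak must NOT trigger senescence
        assert advance_phenology(
            self.env(doy=150), lai=5.6, lai_max=6.0,
            params=self.params, prev=PhenoPhase.STEADY_GROWTH,
        ) is PhenoPhase.STEADY_GROWTH

    def test_dormant_until_budburst_degree_days(self):
        assert advance_phenology(
            self.env(doy=30, dd=20.0), lai=0.0, lai_max=6.0,
            params=self.params, prev=PhenoPhase.DORMANT,
        ) is PhenoPhase.DORMANT
        assert advance_phenology(
            self.env(doy=90, dd=150.0), lai=0.0, lai_max=6.0,
            params=self.params, prev=PhenoPhase.DORMANT,
        ) is PhenoPhase.LEAF_EXPANSION

    def test_forced_autumn_senescence(self):
        assert advance_phenology(
            self.env(doy=310), lai=5.9, lai_max=6.0,
            params=self.params, prev=PhenoPhase.STEADY_GROWTH,
        ) is PhenoPhase.SENESCENCE

    def test_evergreen_stays_in_steady_growth(self):
        p = PhenologyParams(evergreen=True)
        for prev in PhenoPhase:
            assert advance_phenology(
                self.env(doy=10, dd=0.0), lai=1.0, lai_max=6.0, params=p, prev=prev
            ) is PhenoPhase.STEADY_GROWTH

    def test_rejects_bad_lai(self):
        with pytest.raises(InvalidArgumentError):
            advance_phenology(self.env(), 1.0, 0.0, self.params, PhenoPhase.DORMANT)
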