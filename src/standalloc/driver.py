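"""Time-stepping driver: runs any allocation scheme against a forcing
series and aggregates observation-like annual records.

Daily schemes are stepped with explicit Euler at dt = 1/365 yr; annual
schemes accumulate the year's NPP and allocate it in one increment at
year end (turnover still acts daily).  Deciduous runs use the
phenology-phase clock, with foliage shed at an elevated rate during
senescence; evergreen runs stay in steady growth.

The driver is the single place where scheme calls, pool stepping,
phenology and annual bookkeeping meet; the synthetic-experiment
generator and the experiment entry point both run through it, so
simulated and "observed" tables share one computational path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Protocol

import numpy as np
import pandas as pd

from .core import (
    AllocationVector,
    Environment,
    PhenoPhase,
    PhenologyParams,
    PoolState,
    TurnoverVector,
    advance_phenology,
    step_pools,
)
from .diagnostics import AnnualRecord
from .errors import InvalidArgumentError, NoGrowthError
from .schemes.fixed import EalcoParams, FixedSchemeParams, ealco_alloc, fixed_alloc
from .schemes.functional import (
    Ed2Params,
    LpjParams,
    TreeGeometry,
    ed2_alloc,
    geometry_from_wood,
    lpj_alloc_annual,
    ocn_daily_alloc,
)
from .schemes.optimisation import OptimParams, optimal_lai, sdgvm_alloc
from .schemes.resource import (
    DaycentParams,
    IsamParams,
    TecoParams,
    daycent_alloc,
    isam_alloc,
    teco_alloc,
)

__all__ = [
    "Forcing",
    "SimulationConfig",
    "SimulationResult",
    "StepContext",
    "SchemeAdapter",
    "FixedScheme",
    "EalcoScheme",
    "Ed2Scheme",
    "LpjScheme",
    "OcnScheme",
    "IsamScheme",
    "TecoScheme",
    "DaycentScheme",
    "SdgvmScheme",
    "make_scheme",
    "run_simulation",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class Forcing:
    """Daily driver arrays spanning whole simulation years.

    ``npp`` is a rate (kg C m^-2 yr^-1) per day; co2 in μmol mol^-1;
    ``W`` and ``Nfac`` are 0-1 scalars; ``degree_days`` the accumulated
    temperature sum within each year.
    """

    npp: np.ndarray
    co2: np.ndarray
    W: np.ndarray
    Nfac: np.ndarray
    degree_days: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.npp)
        if n == 0 or n % DAYS_PER_YEAR != 0:
            raise InvalidArgumentError(
                f"forcing length {n} is not a whole number of {DAYS_PER_YEAR}-day years"
            )
        for name in ("co2", "W", "Nfac", "degree_days"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError(f"forcing array {name!r} length mismatch")

    @property
    def n_years(self) -> int:
        return len(self.npp) // DAYS_PER_YEAR

    def env(self, i: int) -> Environment:
        return Environment(
            co2=float(self.co2[i]),
            W=float(self.W[i]),
            Nfac=float(self.Nfac[i]),
            t_day=i % DAYS_PER_YEAR + 1,
            degree_days=float(self.degree_days[i]),
        )


@dataclass(frozen=True)
class StepContext:
    """Everything a scheme may read when asked for an allocation."""

    state: PoolState
    env: Environment
    phase: PhenoPhase
    lai: float
    growth_c: float  # kg C m^-2 available this step
    year: int  # 0-based simulation year
    treatment: str
    dt: float


class SchemeAdapter(Protocol):
    """Uniform surface the driver speaks to.

    ``timestep`` is "daily" or "annual"; ``allocate`` may raise
    :class:`NoGrowthError` when no vector is defined for a zero-carbon
    step (the driver then skips growth for that step).
    """

    timestep: str

    def allocate(self, ctx: StepContext) -> AllocationVector: ...


class FixedScheme:
    timestep = "daily"

    def __init__(self, params: FixedSchemeParams):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        return fixed_alloc(self.params, ctx.phase, ctx.treatment, ctx.year)


class FixedAnnualScheme(FixedScheme):
    """Fixed coefficients applied to the year's accumulated NPP."""

    timestep = "annual"


class EalcoScheme:
    timestep = "daily"

    def __init__(self, params: EalcoParams):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        return ealco_alloc(self.params, ctx.lai, ctx.year, ctx.treatment)


class Ed2Scheme:
    """Deficit-filling functional scheme; the leaf phenology scalar e(t)
    is 1 during expansion/steady growth and 0 otherwise."""

    timestep = "daily"

    def __init__(self, params: Ed2Params):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        e_t = (
            1.0
            if ctx.phase in (PhenoPhase.LEAF_EXPANSION, PhenoPhase.STEADY_GROWTH)
            else 0.0
        )
        return ed2_alloc(ctx.state, ctx.env, e_t, self.params, ctx.growth_c)


class LpjScheme:
    """Annual allometric-constraint scheme; carries geometry between years."""

    timestep = "annual"

    def __init__(self, params: LpjParams):
        self.params = params
        self.geometry: Optional[TreeGeometry] = None
        self.off_allometry_years: list[int] = []

    def allocate(self, ctx: StepContext) -> AllocationVector:
        if self.geometry is None:
            self.geometry = geometry_from_wood(ctx.state.B_w, self.params)
        res = lpj_alloc_annual(
            ctx.state, self.geometry, ctx.growth_c, ctx.env, self.params
        )
        self.geometry = res.geometry
        if not res.on_allometry:
            self.off_allometry_years.append(ctx.year)
        return res.alloc


class OcnScheme:
    """Daily variant of the allometric-constraint scheme."""

    timestep = "daily"

    def __init__(self, params: LpjParams):
        if not params.daily_mode:
            params = replace(params, daily_mode=True)
        self.params = params
        self.geometry: Optional[TreeGeometry] = None

    def allocate(self, ctx: StepContext) -> AllocationVector:
        if self.geometry is None:
            self.geometry = geometry_from_wood(ctx.state.B_w, self.params)
        res = ocn_daily_alloc(
            ctx.state, self.geometry, ctx.growth_c, ctx.env, self.params
        )
        self.geometry = res.geometry
        return res.alloc


class IsamScheme:
    timestep = "daily"

    def __init__(self, params: IsamParams):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        return isam_alloc(ctx.env, ctx.lai, self.params, ctx.phase)


class TecoScheme:
    timestep = "daily"

    def __init__(self, params: TecoParams):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        return teco_alloc(ctx.growth_c, ctx.lai, ctx.env, self.params)


class DaycentScheme:
    timestep = "daily"

    def __init__(self, params: DaycentParams):
        self.params = params

    def allocate(self, ctx: StepContext) -> AllocationVector:
        return daycent_alloc(ctx.env, ctx.lai, ctx.state.B_w, self.params)


class SdgvmScheme:
    """Canopy-optimisation scheme with its mandatory one-year lag.

    The LAI target used in year y is the optimum computed from year
    y-1's mean CO2; year 0 uses ``initial_lai_target``.  The
    top-of-canopy carbon gain responds to CO2 with the same logarithmic
    form as photosynthesis-driven NPP:
    ``a0_scalar = 1 + co2_beta*ln(co2/co2_ref)``.
    """

    timestep = "annual"

    def __init__(
        self,
        params: OptimParams,
        sla: float,
        co2_ref: float,
        co2_beta: float = 0.46,
        initial_lai_target: float = 2.0,
        foliage_loss_frac: float = 1.0,
    ):
        self.params = params
        self.sla = sla
        self.co2_ref = co2_ref
        self.co2_beta = co2_beta
        self._target = initial_lai_target
        self.foliage_loss_frac = foliage_loss_frac

    def allocate(self, ctx: StepContext) -> AllocationVector:
        alloc = sdgvm_alloc(
            self._target,
            ctx.growth_c,
            ctx.state,
            self.params,
            self.sla,
            self.foliage_loss_frac,
        )
        # optimum from this year's conditions becomes next year's target
        scalar = 1.0 + self.co2_beta * math.log(ctx.env.co2 / self.co2_ref)
        self._target = optimal_lai(self.params, max(scalar, 1e-6))
        return alloc


_SCHEME_REGISTRY: dict[str, Callable[..., SchemeAdapter]] = {
    "fixed": lambda params: FixedScheme(params),
    "fixed_annual": lambda params: FixedAnnualScheme(params),
    "ealco": lambda params: EalcoScheme(params),
    "ed2": lambda params: Ed2Scheme(params),
    "lpj": lambda params: LpjScheme(params),
    "ocn": lambda params: OcnScheme(params),
    "isam": lambda params: IsamScheme(params),
    "teco": lambda params: TecoScheme(params),
    "daycent": lambda params: DaycentScheme(params),
    "sdgvm": lambda params, **kw: SdgvmScheme(params, **kw),
}


def make_scheme(name: str, params, **kwargs) -> SchemeAdapter:
    """Construct a fresh scheme adapter by registry name."""
    try:
        factory = _SCHEME_REGISTRY[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scheme {name!r}; known: {sorted(_SCHEME_REGISTRY)}"
        ) from None
    return factory(params, **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Stand-level settings independent of the allocation scheme."""

    initial_state: PoolState
    turnover: TurnoverVector
    sla: float = 10.0  # converts B_f to LAI for scheme feedbacks
    deciduous: bool = False
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    lai_max_pheno: float = 6.0  # biome max LAI driving the phase thresholds
    senescence_shed_rate: float = 25.0  # foliage u during senescence (yr^-1)
    treatment: str = "ambient"

    def __post_init__(self) -> None:
        if self.sla <= 0:
            raise InvalidArgumentError("sla must be > 0")


@dataclass(frozen=True)
class SimulationResult:
    """Full output of one treatment run."""

    records: list[AnnualRecord]
    trajectory: pd.DataFrame
    initial_state: PoolState
    final_state: PoolState
    cum_npp: float
    cum_litter: float

    @property
    def delta_biomass(self) -> float:
        return self.final_state.total() - self.initial_state.total()


def run_simulation(
    scheme: SchemeAdapter,
    forcing: Forcing,
    cfg: SimulationConfig,
) -> SimulationResult:
    """Run one treatment simulation over the whole forcing series.

    Daily schemes allocate each day's carbon as it arrives; annual
    schemes bank the year's carbon and allocate it on the last day of
    the year against the annual-mean environment.  Turnover acts daily
    in both modes.  Annual records collect allocated component NPP,
    litter, within-year maximum biomass and maximum LAI.
    """
    state = cfg.initial_state
    initial_state = state
    dt = 1.0 / DAYS_PER_YEAR
    pheno = PhenoPhase.DORMANT if cfg.deciduous else PhenoPhase.STEADY_GROWTH
    pheno_params = replace(cfg.phenology, evergreen=not cfg.deciduous)

    annual = scheme.timestep == "annual"
    records: list[AnnualRecord] = []
    traj_rows: list[dict] = []
    cum_npp = 0.0
    cum_litter = 0.0

    for year in range(forcing.n_years):
        npp_alloc = {"f": 0.0, "w": 0.0, "r": 0.0, "rep": 0.0}
        litter = {"f": 0.0, "w": 0.0, "r": 0.0}
        bmax = {"f": state.B_f, "w": state.B_w, "r": state.B_r}
        lai_max_seen = cfg.sla * state.B_f
        banked = 0.0  # annual-mode carbon awaiting allocation
        env_w_sum = env_n_sum = env_co2_sum = 0.0

        for doy in range(DAYS_PER_YEAR):
            i = year * DAYS_PER_YEAR + doy
            env = forcing.env(i)
            lai = cfg.sla * state.B_f
            if cfg.deciduous:
                pheno = advance_phenology(env, lai, cfg.lai_max_pheno, pheno_params, pheno)
            growth_c = float(forcing.npp[i]) * dt
            cum_npp += growth_c
            env_w_sum += env.W
            env_n_sum += env.Nfac
            env_co2_sum += env.co2

            turnover = cfg.turnover
            if cfg.deciduous and pheno in (PhenoPhase.SENESCENCE, PhenoPhase.DORMANT):
                turnover = replace(turnover, u_f=max(turnover.u_f, cfg.senescence_shed_rate))

            if annual:
                banked += growth_c
                alloc = None
            else:
                try:
                    alloc = scheme.allocate(
                        StepContext(state, env, pheno, lai, growth_c, year, cfg.treatment, dt)
                    )
                except NoGrowthError:
                    alloc = None

            if alloc is None:
                # turnover only
                res = step_pools(
                    state, 0.0, AllocationVector(0, 0, 0, 1), turnover, dt
                )
            else:
                res = step_pools(state, growth_c / dt, alloc, turnover, dt)
                for comp, a in zip(("f", "w", "r", "rep"), alloc.as_tuple()):
                    npp_alloc[comp] += a * growth_c

            if annual and doy == DAYS_PER_YEAR - 1 and banked > 0:
                env_mean = Environment(
                    co2=env_co2_sum / DAYS_PER_YEAR,
                    W=env_w_sum / DAYS_PER_YEAR,
                    Nfac=env_n_sum / DAYS_PER_YEAR,
                    t_day=env.t_day,
                    degree_days=env.degree_days,
                )
                try:
                    alloc_y = scheme.allocate(
                        StepContext(
                            res.state, env_mean, pheno, cfg.sla * res.state.B_f,
                            banked, year, cfg.treatment, 1.0,
                        )
                    )
                except NoGrowthError:
                    alloc_y = None
                if alloc_y is not None:
                    grown = step_pools(res.state, banked, alloc_y, TurnoverVector(0, 0, 0), 1.0)
                    res = replace(res, state=grown.state)
                    for comp, a in zip(("f", "w", "r", "rep"), alloc_y.as_tuple()):
                        npp_alloc[comp] += a * banked
                banked = 0.0

            state = res.state
            litter["f"] += res.litter_f
            litter["w"] += res.litter_w
            litter["r"] += res.litter_r
            cum_litter += res.litter_total
            bmax["f"] = max(bmax["f"], state.B_f)
            bmax["w"] = max(bmax["w"], state.B_w)
            bmax["r"] = max(bmax["r"], state.B_r)
            lai_max_seen = max(lai_max_seen, cfg.sla * state.B_f)

            traj_rows.append(
                {
                    "year": year,
                    "doy": doy + 1,
                    "B_f": state.B_f,
                    "B_w": state.B_w,
                    "B_r": state.B_r,
                    "B_rep": state.B_rep,
                    "lai": cfg.sla * state.B_f,
                    "phase": pheno.value,
                    "npp_rate": float(forcing.npp[i]),
                    "litter": res.litter_total,
                }
            )

        records.append(
            AnnualRecord(
                year=year,
                npp_f=npp_alloc["f"],
                npp_w=npp_alloc["w"],
                npp_r=npp_alloc["r"],
                npp_rep=npp_alloc["rep"],
                litter_f=litter["f"],
                litter_w=litter["w"],
                litter_r=litter["r"],
                bmax_f=bmax["f"],
                bmax_w=bmax["w"],
                bmax_r=bmax["r"],
                lai_max=lai_max_seen,
            )
        )

    return SimulationResult(
        records=records,
        trajectory=pd.DataFrame(traj_rows),
        initial_state=initial_state,
        final_state=state,
        cum_npp=cum_npp,
        cum_litter=cum_litter,
    )
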