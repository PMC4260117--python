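"""Core state types, the pool stepper, and the phenology clock.

The stand is reduced to four live carbon pools — foliage, wood (stem,
branches and coarse roots lumped), fine roots, and a cumulative
reproduction sink.  Pool dynamics follow the standard ecosystem-model
balance

    dB_i/dt = a_i * NPP - u_i * B_i

where ``a_i`` are allocation coefficients summing to one and ``u_i`` are
first-order turnover rates (yr^-1).  NPP is an exogenous forcing: the
package concerns how growth carbon is divided, not how it is fixed.
Integration is explicit Euler at a configurable step (daily by default);
annual schemes apply allocation once per simulated year.

Reproduction is a terminal sink: carbon allocated to it never returns to
litter within a simulation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import InvalidArgumentError, StabilityError

__all__ = [
    "PoolState",
    "AllocationVector",
    "TurnoverVector",
    "Environment",
    "PhenoPhase",
    "PhenologyParams",
    "StepResult",
    "step_pools",
    "advance_phenology",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PoolState:
    """Live biomass per component (kg C m^-2)."""

    B_f: float = 0.0  # foliage
    B_w: float = 0.0  # wood incl. coarse roots
    B_r: float = 0.0  # fine roots
    B_rep: float = 0.0  # cumulative reproduction C

    def __post_init__(self) -> None:
        for name in ("B_f", "B_w", "B_r", "B_rep"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")

    def total(self) -> float:
        return self.B_f + self.B_w + self.B_r + self.B_rep


@dataclass(frozen=True)
class AllocationVector:
    """Fractions of growth C per component; must sum to 1."""

    a_f: float
    a_w: float
    a_r: float
    a_rep: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_f", "a_w", "a_r", "a_rep"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < -_SUM_TOL or v > 1 + _SUM_TOL:
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {v!r}")
        s = self.a_f + self.a_w + self.a_r + self.a_rep
        if abs(s - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"allocation fractions must sum to 1 (got {s!r})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a_f, self.a_w, self.a_r, self.a_rep)


@dataclass(frozen=True)
class TurnoverVector:
    """First-order turnover rates (yr^-1); lifespan_i = 1/u_i."""

    u_f: float
    u_w: float
    u_r: float

    def __post_init__(self) -> None:
        for name in ("u_f", "u_w", "u_r"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")

    def lifespan(self, component: str) -> float:
        u = getattr(self, "u_" + component)
        return math.inf if u == 0 else 1.0 / u


@dataclass(frozen=True)
class Environment:
    """Abiotic drivers read by the allocation schemes.

    ``W``, ``Nfac`` and ``L`` are dimensionless 0-1 availability scalars
    for soil water, nitrogen and light; they are prescribed forcings, not
    mechanistic budgets.
    """

    co2: float = 400.0  # μmol mol^-1
    W: float = 1.0
    Nfac: float = 1.0
    L: float = 1.0
    t_day: int = 1  # day of year, 1-based, no leap days
    degree_days: float = 0.0  # accumulated temperature sum (°C d)

    def __post_init__(self) -> None:
        if self.co2 <= 0:
            raise InvalidArgumentError(f"co2 must be > 0, got {self.co2!r}")
        for name in ("W", "Nfac", "L"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {v!r}")


class PhenoPhase(enum.Enum):
    """Phenological phase of a deciduous canopy.

    Deciduous simulations cycle DORMANT → LEAF_EXPANSION → STEADY_GROWTH
    → SENESCENCE → DORMANT; evergreen simulations sit in STEADY_GROWTH.
    """

    LEAF_EXPANSION = "leaf_expansion"
    STEADY_GROWTH = "steady_growth"
    SENESCENCE = "senescence"
    DORMANT = "dormant"


@dataclass(frozen=True)
class PhenologyParams:
    """Thresholds for the LAI-driven phase clock.

    expansion_end_frac and senescence_frac follow the deciduous
    resource-limitation convention: steady growth starts once LAI reaches
    half the biome maximum and ends once LAI falls below 95% of it.  The
    senescence test is only armed after ``peak_doy`` so that the spring
    rise through 0.95*lai_max cannot trigger it.
    """

    budburst_gdd: float = 100.0  # °C d to leave dormancy
    expansion_end_frac: float = 0.5
    senescence_frac: float = 0.95
    peak_doy: int = 200
    forced_senescence_doy: int = 300  # photoperiod/frost leaf-off backstop
    dormant_lai: float = 0.05  # LAI at/below which senescence completes
    evergreen: bool = False


@dataclass(frozen=True)
class StepResult:
    """Pool state after one step plus the carbon shed to litter in it."""

    state: PoolState
    litter_f: float = 0.0
    litter_w: float = 0.0
    litter_r: float = 0.0

    @property
    def litter_total(self) -> float:
        return self.litter_f + self.litter_w + self.litter_r


def step_pools(
    state: PoolState,
    npp: float,
    alloc: AllocationVector,
    turnover: TurnoverVector,
    dt: float,
) -> StepResult:
    """Advance the four pools one explicit-Euler step of length ``dt`` (yr).

    Parameters
    ----------
    state : PoolState
        Pools at the start of the step.
    npp : float
        Growth carbon supply rate over the step (kg C m^-2 yr^-1), >= 0.
    alloc : AllocationVector
        Division of ``npp`` among the components.
    turnover : TurnoverVector
        First-order loss rates; the step requires ``dt*u_i < 1`` for every
        component so pools cannot overshoot below zero.
    dt : float
        Step length in years, > 0.

    Returns
    -------
    StepResult
        Updated pools and per-component litter produced during the step.
    """
    if not math.isfinite(npp) or npp < 0:
        raise InvalidArgumentError(f"npp must be finite and >= 0, got {npp!r}")
    if not math.isfinite(dt) or dt <= 0:
        raise InvalidArgumentError(f"dt must be finite and > 0, got {dt!r}")
    for comp in ("f", "w", "r"):
        u = getattr(turnover, "u_" + comp)
        if dt * u >= 1.0:
            raise StabilityError(comp, u, dt)

    litter_f = turnover.u_f * state.B_f * dt
    litter_w = turnover.u_w * state.B_w * dt
    litter_r = turnover.u_r * state.B_r * dt
    new = PoolState(
        B_f=state.B_f + alloc.a_f * npp * dt - litter_f,
        B_w=state.B_w + alloc.a_w * npp * dt - litter_w,
        B_r=state.B_r + alloc.a_r * npp * dt - litter_r,
        B_rep=state.B_rep + alloc.a_rep * npp * dt,
    )
    return StepResult(state=new, litter_f=litter_f, litter_w=litter_w, litter_r=litter_r)


def advance_phenology(
    env: Environment,
    lai: float,
    lai_max: float,
    params: PhenologyParams,
    prev: PhenoPhase,
) -> PhenoPhase:
    """Return the next phenological phase given the canopy state.

    The clock is a deterministic state machine over the cyclic phase
    order.  Dormancy ends when the temperature sum passes the budburst
    threshold; leaf expansion ends when LAI reaches
    ``expansion_end_frac * lai_max``; steady growth ends when, after
    ``peak_doy``, LAI falls below ``senescence_frac * lai_max`` (or
    unconditionally after the photoperiod backstop
    ``forced_senescence_doy``); and senescence ends (back to dormancy)
    when LAI drops to ``dormant_lai``.
    """
    if lai_max <= 0:
        raise InvalidArgumentError(f"lai_max must be > 0, got {lai_max!r}")
    if lai < 0:
        raise InvalidArgumentError(f"lai must be >= 0, got {lai!r}")
    if params.evergreen:
        return PhenoPhase.STEADY_GROWTH

    if prev is PhenoPhase.DORMANT:
        if env.degree_days >= params.budburst_gdd:
            return PhenoPhase.LEAF_EXPANSION
        return PhenoPhase.DORMANT
    if prev is PhenoPhase.LEAF_EXPANSION:
        if lai >= params.expansion_end_frac * lai_max:
            return PhenoPhase.STEADY_GROWTH
        return PhenoPhase.LEAF_EXPANSION
    if prev is PhenoPhase.STEADY_GROWTH:
        if env.t_day > params.forced_senescence_doy:
            return PhenoPhase.SENESCENCE
        if env.t_day > params.peak_doy and lai < params.senescence_frac * lai_max:
            return PhenoPhase.SENESCENCE
        return PhenoPhase.STEADY_GROWTH
    # SENESCENCE
    if lai <= params.dormant_lai:
        return PhenoPhase.DORMANT
    return PhenoPhase.SENESCENCE
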