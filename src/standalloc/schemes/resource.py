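"""Resource-limitation allocation: coefficients computed from water,
light and nutrient limitation, with priority orders and caps.

Three variants:

* a light/water closed-form scheme (Arora & Boer 2005 form): wood
  allocation rises with light limitation (dense canopy), root allocation
  rises with water limitation, foliage takes the residual; in deciduous
  mode phenological phases override the coefficients (all-to-leaf during
  expansion, zero-to-leaf during senescence);
* a demand/cap scheme: foliage demand is the carbon needed to close the
  gap to a fixed maximum LAI, capped at 40% of available carbon; root
  demand rises as water availability falls, capped at 30%; wood takes
  the remainder;
* a priority scheme: fine roots claim 5-18% of NPP depending on the
  stronger of the water and nutrient limitations, foliage takes the rest
  until a wood-biomass-dependent maximum LAI is attained, and only then
  does wood receive carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..core import AllocationVector, Environment, PhenoPhase
from ..errors import InvalidArgumentError, NoGrowthError

__all__ = [
    "IsamParams",
    "TecoParams",
    "DaycentParams",
    "isam_alloc",
    "teco_alloc",
    "daycent_alloc",
]


@dataclass(frozen=True)
class IsamParams:
    """Light/water closed-form parameters.

    ``omega`` is the limitation sensitivity; ``eps_w`` and ``eps_r`` the
    base wood and root parameters (their sum must stay below 1 so the
    foliage residual is non-negative at zero limitation); ``k_ext`` the
    Beer-law extinction coefficient giving light availability
    L = exp(-k_ext * LAI); ``lai_max`` the biome maximum LAI used by the
    deciduous phase thresholds; ``deciduous`` enables phase overrides.
    """

    omega: float = 0.8
    eps_w: float = 0.30
    eps_r: float = 0.25
    k_ext: float = 0.5
    lai_max: float = 6.0
    deciduous: bool = False

    def __post_init__(self) -> None:
        if self.omega < 0 or self.eps_w < 0 or self.eps_r < 0:
            raise InvalidArgumentError("omega, eps_w, eps_r must be >= 0")
        if self.eps_w + self.eps_r >= 1.0:
            raise InvalidArgumentError("eps_w + eps_r must be < 1")
        if self.k_ext <= 0:
            raise InvalidArgumentError("k_ext must be > 0")


def isam_alloc(
    env: Environment,
    lai: float,
    params: IsamParams,
    phase: PhenoPhase = PhenoPhase.STEADY_GROWTH,
) -> AllocationVector:
    """Closed-form light/water-limitation allocation.

    With L = exp(-k_ext*lai) and W the soil-water scalar,

        a_w = (eps_w + omega*(1-L)) / (1 + omega*(2-L-W))
        a_r = (eps_r + omega*(1-W)) / (1 + omega*(2-L-W))
        a_f = 1 - a_w - a_r

    so wood allocation rises as the canopy closes and root allocation as
    water becomes limiting.  In deciduous mode the leaf-expansion phase
    sends everything to foliage and the senescence/dormant phases send
    nothing to it (wood and root scaled to sum to one).  A negative
    foliage residual is clipped to zero with renormalisation.
    """
    if lai < 0:
        raise InvalidArgumentError(f"lai must be >= 0, got {lai!r}")

    if params.deciduous:
        if phase is PhenoPhase.LEAF_EXPANSION:
            return AllocationVector(1.0, 0.0, 0.0)
        if phase in (PhenoPhase.SENESCENCE, PhenoPhase.DORMANT):
            light = math.exp(-params.k_ext * lai)
            denom = 1.0 + params.omega * (2.0 - light - env.W)
            a_w = (params.eps_w + params.omega * (1.0 - light)) / denom
            a_r = (params.eps_r + params.omega * (1.0 - env.W)) / denom
            s = a_w + a_r
            return AllocationVector(0.0, a_w / s, a_r / s)

    light = math.exp(-params.k_ext * lai)
    denom = 1.0 + params.omega * (2.0 - light - env.W)
    a_w = (params.eps_w + params.omega * (1.0 - light)) / denom
    a_r = (params.eps_r + params.omega * (1.0 - env.W)) / denom
    a_f = 1.0 - a_w - a_r
    if a_f < 0.0:
        s = a_w + a_r
        return AllocationVector(0.0, a_w / s, a_r / s)
    return AllocationVector(a_f, a_w, a_r)


@dataclass(frozen=True)
class TecoParams:
    """Demand/cap scheme parameters.

    Foliage demand is the carbon closing the gap to ``lai_max`` at the
    given ``sla``; it may take at most ``cap_f`` (40%) of the carbon
    available in a step.  Root demand rises with water limitation as
    ``(bmR/bmL)*(1-W)`` and may take at most ``cap_r`` (30%).  The
    maximum LAI is a constant here — it does not vary with stand state.
    """

    lai_max: float = 4.5
    sla: float = 10.0
    bmL: float = 1.0
    bmR: float = 0.5
    cap_f: float = 0.40
    cap_r: float = 0.30

    def __post_init__(self) -> None:
        if self.lai_max <= 0 or self.sla <= 0 or self.bmL <= 0 or self.bmR < 0:
            raise InvalidArgumentError("lai_max, sla, bmL must be > 0; bmR >= 0")
        if not (0 < self.cap_f < 1 and 0 <= self.cap_r < 1):
            raise InvalidArgumentError("caps must lie in (0, 1)")
        if self.cap_f + self.cap_r >= 1.0:
            raise InvalidArgumentError("cap_f + cap_r must be < 1")


def teco_alloc(
    growth_c: float,
    lai: float,
    env: Environment,
    params: TecoParams,
) -> AllocationVector:
    """Demand/cap allocation for one step of available carbon ``growth_c``
    (kg C m^-2)."""
    if growth_c < 0:
        raise InvalidArgumentError(f"growth_c must be >= 0, got {growth_c!r}")
    if growth_c == 0:
        raise NoGrowthError("no carbon available this step")
    if lai < 0:
        raise InvalidArgumentError(f"lai must be >= 0, got {lai!r}")

    foliage_demand = max(0.0, params.lai_max - lai) / (params.sla * growth_c)
    a_f = min(params.cap_f, foliage_demand)
    root_demand = (params.bmR / params.bmL) * (1.0 - env.W)
    a_r = min(params.cap_r, root_demand)
    a_w = 1.0 - a_f - a_r
    return AllocationVector(a_f, a_w, a_r)


@dataclass(frozen=True)
class DaycentParams:
    """Priority-scheme parameters.

    Fine-root share interpolates between ``root_min`` (5%) and
    ``root_max`` (18%) on the stronger of the water and nutrient
    limitations.  ``lai_max_coef`` and ``lai_max_exp`` define the
    allometric maximum LAI as a function of wood biomass,
    ``lai_max = coef * B_w**exp``.
    """

    root_min: float = 0.05
    root_max: float = 0.18
    lai_max_coef: float = 2.0
    lai_max_exp: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.root_min <= self.root_max < 1.0:
            raise InvalidArgumentError("need 0 <= root_min <= root_max < 1")
        if self.lai_max_coef <= 0:
            raise InvalidArgumentError("lai_max_coef must be > 0")

    def lai_max_fn(self, b_w: float) -> float:
        return self.lai_max_coef * max(b_w, 0.0) ** self.lai_max_exp


def daycent_alloc(
    env: Environment,
    lai: float,
    B_w: float,
    params: DaycentParams,
) -> AllocationVector:
    """Priority allocation: roots first, then foliage, wood last.

    Roots claim ``root_min + (root_max-root_min)*max(1-W, 1-Nfac)``.
    While LAI is below the wood-determined maximum, foliage takes the
    whole residual; once the maximum LAI is attained the residual goes
    to wood instead.
    """
    if lai < 0 or B_w < 0:
        raise InvalidArgumentError("lai and B_w must be >= 0")
    stress = max(1.0 - env.W, 1.0 - env.Nfac)
    a_r = params.root_min + (params.root_max - params.root_min) * stress
    residual = 1.0 - a_r
    if lai < params.lai_max_fn(B_w):
        return AllocationVector(residual, 0.0, a_r)
    return AllocationVector(0.0, residual, a_r)
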