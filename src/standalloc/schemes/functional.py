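"""Functional-relationship allocation: allometric and functional-balance
constraints among biomass pools.

Two schemes are provided.  The first is a deficit-filling scheme in the
style of age/size-gap models: leaf and fine-root pools are grown toward
targets set by a leaf:sapwood proportionality (pipe model) and a
root:leaf ratio ``q`` that rises with water or nitrogen limitation
(functional balance); whatever carbon remains ("reserve") is split at a
fixed 70:30 ratio between wood and reproduction.

The second is an allometric-constraint scheme: after a fixed fraction of
NPP goes to reproduction, the leaf, wood and root increments are solved
so that, post-increment,

  (i)   LAI = k_la_sa * SA          (constant LAI : sapwood-area ratio),
  (ii)  H   = k_allom2 * D**k_allom3 (height-diameter allometry), and
  (iii) C_f / C_r = lr_max * min(N, W)  (stress-dependent leaf:root balance),

with all increments non-negative (no disinvestment).  Constraint (iii)
eliminates the root increment and (i)-(ii) make the residual monotone in
the leaf increment, so a 1-D bisection solves the system.  The same
solver run per day, with targets approached incrementally, gives the
daily-timestep variant.

Sapwood area is derived from the wood pool as a cylinder of configured
wood density at the current allometric height (one effective stem per
m^2 ground); heartwood is not separated, consistently with the single
lumped wood pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..core import AllocationVector, Environment, PoolState
from ..errors import InvalidArgumentError, NoGrowthError

__all__ = [
    "Ed2Params",
    "LpjParams",
    "TreeGeometry",
    "LpjAllocation",
    "ed2_alloc",
    "lpj_alloc_annual",
    "ocn_daily_alloc",
]


# --------------------------------------------------------------------------
# Deficit-filling scheme (pipe model + functional balance + reserve split)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ed2Params:
    """Parameters of the deficit-filling functional scheme.

    q_sw
        Leaf:sapwood proportionality per metre of height (the pipe-model
        constant); peak leaf biomass relates to active biomass through
        ``q_sw * height``.
    q_base, q_stress_gain
        Root:peak-leaf ratio ``q = q_base + q_stress_gain*(1 - min(W, N))``
        — a linear rise of root demand with the more limiting of water
        and nitrogen.  The linear form is this package's
        parameterisation of "q increases with limitation".
    reserve_split_wood
        Fraction of reserve C sent to wood; the remainder is
        reproduction (0.70 : 0.30 by default).
    height
        Tree height (m), prescribed.
    """

    q_sw: float = 0.5
    q_base: float = 0.8
    q_stress_gain: float = 1.0
    reserve_split_wood: float = 0.70
    height: float = 15.0

    def __post_init__(self) -> None:
        if self.q_sw <= 0 or self.q_base <= 0:
            raise InvalidArgumentError("q_sw and q_base must be positive")
        if not 0.0 <= self.reserve_split_wood <= 1.0:
            raise InvalidArgumentError("reserve_split_wood must lie in [0, 1]")
        if self.height <= 0:
            raise InvalidArgumentError("height must be positive")


def ed2_alloc(
    state: PoolState,
    env: Environment,
    e_t: float,
    params: Ed2Params,
    growth_c: float,
) -> AllocationVector:
    """Deficit-filling allocation for one step.

    ``e_t`` is the 0-1 leaf phenology scalar: the leaf target is
    ``e_t`` times the peak leaf biomass implied by the active biomass and
    the pipe-model partition ``B_leaf_peak = B_a / (1 + q + q_sw*h)``.
    The root target is ``q`` times peak leaf biomass.  Leaf and root
    deficits are filled first (pro rata if carbon is short); any
    remainder is reserve, split wood : reproduction.
    """
    if not 0.0 <= e_t <= 1.0:
        raise InvalidArgumentError(f"e_t must lie in [0, 1], got {e_t!r}")
    if growth_c < 0:
        raise InvalidArgumentError(f"growth_c must be >= 0, got {growth_c!r}")
    if growth_c == 0:
        raise NoGrowthError("no carbon available this step")

    q = params.q_base + params.q_stress_gain * (1.0 - min(env.W, env.Nfac))
    b_active = state.B_f + state.B_r + state.B_w
    peak_leaf = b_active / (1.0 + q + params.q_sw * params.height)
    target_leaf = e_t * peak_leaf
    target_root = q * peak_leaf

    deficit_f = max(0.0, target_leaf - state.B_f)
    deficit_r = max(0.0, target_root - state.B_r)
    demand = deficit_f + deficit_r

    if demand >= growth_c:
        # pro-rata fill, nothing left for reserve
        c_f = growth_c * (deficit_f / demand) if demand > 0 else 0.0
        c_r = growth_c - c_f
        reserve = 0.0
    else:
        c_f, c_r = deficit_f, deficit_r
        reserve = growth_c - demand

    c_w = reserve * params.reserve_split_wood
    c_rep = reserve - c_w
    g = growth_c
    return AllocationVector(c_f / g, c_w / g, c_r / g, c_rep / g)


# --------------------------------------------------------------------------
# Allometric-constraint scheme
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LpjParams:
    """Parameters of the allometric-constraint scheme.

    k_la_sa
        Constant ratio of LAI to sapwood area (m^2 leaf per m^2 sapwood).
    k_allom2, k_allom3
        Height-diameter allometry: H = k_allom2 * D**k_allom3.
    lr_max
        Maximum leaf:root mass ratio; the realised target ratio is
        ``lr_max * min(N, W)`` (the more limiting resource scales it).
    sla
        Specific leaf area (m^2 per kg C) converting foliage carbon to LAI.
    repro_fraction
        Fraction of NPP taken off the top for reproduction (0.10).
    wood_density
        kg C m^-3, for the wood-cylinder sapwood-area bookkeeping.
    daily_mode
        Enables the per-day variant.
    stress_combination
        "min" (default) or "product": how N and W jointly scale lr_max.
    """

    k_la_sa: float = 500.0
    k_allom2: float = 40.0
    k_allom3: float = 0.67
    lr_max: float = 1.0
    sla: float = 10.0
    repro_fraction: float = 0.10
    wood_density: float = 200.0
    daily_mode: bool = False
    stress_combination: str = "min"

    def __post_init__(self) -> None:
        for name in ("k_la_sa", "k_allom2", "k_allom3", "lr_max", "sla", "wood_density"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0.0 <= self.repro_fraction < 1.0:
            raise InvalidArgumentError("repro_fraction must lie in [0, 1)")
        if self.stress_combination not in ("min", "product"):
            raise InvalidArgumentError("stress_combination must be 'min' or 'product'")

    def stress_scalar(self, n: float, w: float) -> float:
        return min(n, w) if self.stress_combination == "min" else n * w


@dataclass(frozen=True)
class TreeGeometry:
    """Effective-stem geometry: height H (m), diameter D (m), sapwood
    area SA (m^2 per m^2 ground)."""

    H: float
    D: float
    SA: float

    def __post_init__(self) -> None:
        for name in ("H", "D", "SA"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


def geometry_from_wood(c_w: float, params: LpjParams) -> TreeGeometry:
    """Geometry consistent with a wood pool of ``c_w`` kg C m^-2.

    The wood pool is a cylinder: C_w = rho * SA * H, with
    D = sqrt(4*SA/pi) (one effective stem per m^2) and
    H = k_allom2 * D**k_allom3.  Eliminating SA and D yields a closed
    form for H.
    """
    if c_w <= 0:
        return TreeGeometry(0.0, 0.0, 0.0)
    k2, k3, rho = params.k_allom2, params.k_allom3, params.wood_density
    # H**(1 + k3/2) = k2 * (4*C_w/(pi*rho))**(k3/2)
    h = (k2 * (4.0 * c_w / (math.pi * rho)) ** (k3 / 2.0)) ** (1.0 / (1.0 + k3 / 2.0))
    sa = c_w / (rho * h)
    d = math.sqrt(4.0 * sa / math.pi)
    return TreeGeometry(H=h, D=d, SA=sa)


@dataclass(frozen=True)
class LpjAllocation:
    """Solver output: the allocation vector, updated geometry, and
    whether the pools could be brought exactly onto allometry
    (``on_allometry=False`` flags a constrained best solution)."""

    alloc: AllocationVector
    geometry: TreeGeometry
    on_allometry: bool


_BISECT_TOL = 1e-10
_BISECT_MAX_ITER = 200


def _leaf_residual(
    dc_f: float, pools: PoolState, available: float, ratio_fr: float, params: LpjParams
) -> float:
    """Signed gap  sla*C_f' − k_la_sa*SA(C_w')  at a trial leaf increment.

    Monotonically increasing in dc_f: more leaf C both raises the LHS and
    (by diverting C from wood) lowers the sapwood area on the RHS.
    """
    c_f = pools.B_f + dc_f
    dc_r = max(0.0, c_f / ratio_fr - pools.B_r)
    dc_w = available - dc_f - dc_r
    c_w = pools.B_w + max(0.0, dc_w)
    return params.sla * c_f - params.k_la_sa * geometry_from_wood(c_w, params).SA


def _solve_increments(
    pools: PoolState, available: float, ratio_fr: float, params: LpjParams
) -> tuple[float, float, float, bool]:
    """Split ``available`` kg C among (leaf, wood, root) increments so the
    post-increment pools satisfy the three constraints, or return the
    constrained best (never-negative) split with a False flag."""
    # Largest leaf increment leaving a non-negative wood increment:
    # dc_f + max(0, (B_f+dc_f)/ratio - B_r) = available  (piecewise linear).
    if (pools.B_f + available) / ratio_fr - pools.B_r <= 0:
        dc_f_hi = available
    else:
        dc_f_hi = (available + pools.B_r - pools.B_f / ratio_fr) / (1.0 + 1.0 / ratio_fr)
        dc_f_hi = min(max(dc_f_hi, 0.0), available)

    r_lo = _leaf_residual(0.0, pools, available, ratio_fr, params)
    r_hi = _leaf_residual(dc_f_hi, pools, available, ratio_fr, params)

    if r_lo >= 0.0:
        # Leaf already at/above the pipe-model cap: no leaf growth.
        dc_f = 0.0
        on_allometry = r_lo <= 1e-8
    elif r_hi <= 0.0:
        # Even all C to leaf+root leaves the canopy under the cap.
        dc_f = dc_f_hi
        on_allometry = r_hi >= -1e-8
    else:
        lo, hi = 0.0, dc_f_hi
        for _ in range(_BISECT_MAX_ITER):
            mid = 0.5 * (lo + hi)
            if _leaf_residual(mid, pools, available, ratio_fr, params) < 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo < _BISECT_TOL:
                break
        dc_f = 0.5 * (lo + hi)
        on_allometry = True

    dc_r = max(0.0, (pools.B_f + dc_f) / ratio_fr - pools.B_r)
    dc_r = min(dc_r, available - dc_f)
    dc_w = max(0.0, available - dc_f - dc_r)
    return dc_f, dc_w, dc_r, on_allometry


def lpj_alloc_annual(
    pools: PoolState,
    geom: TreeGeometry,
    annual_npp: float,
    env_annual: Environment,
    params: LpjParams,
) -> LpjAllocation:
    """Annual allometric-constraint allocation.

    A fixed ``repro_fraction`` (10% by default) of NPP goes to
    reproduction first; the remainder is divided into non-negative leaf,
    wood and root increments satisfying the pipe-model, height-diameter
    and leaf:root-balance constraints.  When no exact non-negative
    solution exists (pools far off allometry), the closest constrained
    split is returned and flagged.
    """
    if annual_npp < 0:
        raise InvalidArgumentError(f"annual_npp must be >= 0, got {annual_npp!r}")
    if annual_npp == 0:
        raise NoGrowthError("no carbon available this year")
    stress = params.stress_scalar(env_annual.Nfac, env_annual.W)
    ratio_fr = max(params.lr_max * stress, 1e-6)

    c_rep = params.repro_fraction * annual_npp
    available = annual_npp - c_rep
    dc_f, dc_w, dc_r, ok = _solve_increments(pools, available, ratio_fr, params)

    new_geom = geometry_from_wood(pools.B_w + dc_w, params)
    alloc = AllocationVector(
        dc_f / annual_npp, dc_w / annual_npp, dc_r / annual_npp, c_rep / annual_npp
    )
    return LpjAllocation(alloc=alloc, geometry=new_geom, on_allometry=ok)


def ocn_daily_alloc(
    pools: PoolState,
    geom: TreeGeometry,
    daily_npp: float,
    env: Environment,
    params: LpjParams,
) -> LpjAllocation:
    """Daily variant of the allometric-constraint scheme.

    Identical constraint targets, approached incrementally with each
    day's carbon; requires ``params.daily_mode``.  A zero-NPP day has no
    defined allocation and raises :class:`NoGrowthError`.
    """
    if not params.daily_mode:
        raise InvalidArgumentError("ocn_daily_alloc requires params.daily_mode=True")
    return lpj_alloc_annual(pools, geom, daily_npp, env, params)
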