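"""Canopy-optimisation allocation: choose the LAI at which the lowest
canopy layer just breaks even, fund the foliage needed to realise it,
and split the remaining carbon between wood and roots at fixed
fractions.

The canopy-uptake model is deliberately minimal: Beer-law light decay
with a linear conversion to carbon gain, so a layer at depth LAI earns
``a0 * co2_scalar * exp(-k_ext*LAI)`` per unit leaf area and year, and
costs ``leaf_cost`` (construction plus respiration folded together).
The optimal LAI is the deepest layer that still pays for itself.  The
optimisation uses the *previous* year's conditions — a one-year lag is
integral to the scheme — so under a step CO2 increase the foliage
fraction falls (NPP is enhanced more than the LAI target), while the
wood:root ratio of the remainder stays exactly at the fixed split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ..core import AllocationVector, PoolState
from ..errors import InvalidArgumentError, NoGrowthError

__all__ = ["OptimParams", "optimal_lai", "sdgvm_alloc"]


@dataclass(frozen=True)
class OptimParams:
    """Canopy-optimisation parameters.

    a0
        Top-of-canopy gross C gain per unit leaf area (kg C m^-2 leaf
        yr^-1); scaled multiplicatively by the CO2 response.
    leaf_cost
        Annual C cost per unit leaf area (construction + respiration).
    wood_root_split
        Fixed wood fraction of the non-foliage carbon.
    layer_dlai
        LAI discretisation step of the layered canopy (<= 0.1).
    lai_cap
        Hard upper bound on the optimised LAI.
    """

    k_ext: float = 0.5
    a0: float = 2.0
    leaf_cost: float = 0.4
    wood_root_split: float = 0.7
    layer_dlai: float = 0.05
    lai_cap: float = 12.0

    def __post_init__(self) -> None:
        for name in ("k_ext", "a0", "leaf_cost", "layer_dlai", "lai_cap"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0.0 <= self.wood_root_split <= 1.0:
            raise InvalidArgumentError("wood_root_split must lie in [0, 1]")
        if self.layer_dlai > 0.1:
            raise InvalidArgumentError("layer_dlai must be <= 0.1")


def optimal_lai(params: OptimParams, co2_scalar: float = 1.0) -> float:
    """Largest LAI (in ``layer_dlai`` increments) whose deepest layer has
    a non-negative net carbon balance:

        a0 * co2_scalar * exp(-k_ext * LAI) >= leaf_cost.

    Returns 0 when even the top layer cannot pay for itself; the result
    never exceeds ``lai_cap``.
    """
    if co2_scalar <= 0:
        raise InvalidArgumentError(f"co2_scalar must be > 0, got {co2_scalar!r}")
    gain0 = params.a0 * co2_scalar
    if gain0 <= params.leaf_cost:
        return 0.0
    n_layers = int(math.floor(params.lai_cap / params.layer_dlai + 1e-12))
    best = 0.0
    for i in range(1, n_layers + 1):
        lai = i * params.layer_dlai
        if gain0 * math.exp(-params.k_ext * lai) >= params.leaf_cost:
            best = lai
        else:
            break
    return best


def sdgvm_alloc(
    prev_year_lai_target: float,
    annual_npp: float,
    pools: PoolState,
    params: OptimParams,
    sla: float,
    foliage_loss_frac: float = 1.0,
) -> AllocationVector:
    """Annual allocation funding the previous year's optimal LAI.

    Foliage receives the carbon needed to realise
    ``prev_year_lai_target`` given ``sla``, accounting for the surviving
    foliage pool (``foliage_loss_frac`` is the annual fraction of
    foliage lost to turnover; 1 means full replacement, the deciduous
    case).  The foliage fraction is capped at 1; the remainder is split
    wood : root at the fixed fraction.
    """
    if annual_npp <= 0:
        raise NoGrowthError("annual_npp must be > 0 for an allocation to be defined")
    if prev_year_lai_target < 0:
        raise InvalidArgumentError("prev_year_lai_target must be >= 0")
    if sla <= 0:
        raise InvalidArgumentError("sla must be > 0")
    if not 0.0 <= foliage_loss_frac <= 1.0:
        raise InvalidArgumentError("foliage_loss_frac must lie in [0, 1]")

    surviving = pools.B_f * (1.0 - foliage_loss_frac)
    need = max(0.0, prev_year_lai_target / sla - surviving)
    a_f = min(1.0, need / annual_npp)
    rest = 1.0 - a_f
    a_w = rest * params.wood_root_split
    a_r = rest - a_w
    return AllocationVector(a_f, a_w, a_r)
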