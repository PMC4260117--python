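"""Fixed-coefficient allocation and its phenological-phase variants.

Pure fixed schemes allocate constant fractions of NPP to each component
regardless of environment, so a CO2 treatment cannot change their annual
allocation — unless coefficients differ by phenological phase, in which
case a treatment that redistributes NPP across the season (e.g. a
drought-year CO2 interaction) shifts the NPP-weighted annual mean even
though every within-phase coefficient is fixed.  The prescribed-ratio
variant instead sends all growth C to foliage until a prescribed maximum
LAI is reached, then splits it between wood and fine roots at a fixed
ratio (60:40 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from ..core import AllocationVector, PhenoPhase
from ..errors import ConfigurationError, InvalidArgumentError

__all__ = ["FixedSchemeParams", "EalcoParams", "fixed_alloc", "ealco_alloc"]


@dataclass(frozen=True)
class FixedSchemeParams:
    """Parameters for fixed-coefficient allocation.

    base
        Allocation used when no phase table applies.
    phase_table
        Optional mapping of phenological phase to an allocation vector;
        when present it must cover every phase queried.
    treatment_override
        Optional vector applied under the elevated treatment from
        ``override_start_year`` on — the deciduous prescribed-shift
        device, in which a change takes effect one year late because
        growth follows the previous year's accumulated productivity.
    """

    base: AllocationVector
    phase_table: Optional[Mapping[PhenoPhase, AllocationVector]] = None
    treatment_override: Optional[AllocationVector] = None
    override_start_year: int = 2


def fixed_alloc(
    params: FixedSchemeParams,
    phase: PhenoPhase,
    treatment: str,
    year: int,
) -> AllocationVector:
    """Look up the fixed allocation for (phase, treatment, year).

    Depends on nothing but the stored tables: no pool state, no
    environment.  ``treatment`` is ``"ambient"`` or ``"elevated"``.
    """
    if treatment not in ("ambient", "elevated"):
        raise InvalidArgumentError(f"unknown treatment {treatment!r}")
    if (
        params.treatment_override is not None
        and treatment == "elevated"
        and year >= params.override_start_year
    ):
        return params.treatment_override
    if params.phase_table is not None:
        try:
            return params.phase_table[phase]
        except KeyError:
            raise ConfigurationError(
                f"phase table has no entry for phase {phase.value!r}"
            ) from None
    return params.base


# Canonical three-phase table: 80% foliage during leaf expansion
# (10% each wood/roots), base coefficients during steady growth, and a
# 55:45 wood:root split with zero leaf growth in the final phase.
def cable_style_params(
    steady: AllocationVector = AllocationVector(0.35, 0.40, 0.25),
) -> FixedSchemeParams:
    return FixedSchemeParams(
        base=steady,
        phase_table={
            PhenoPhase.LEAF_EXPANSION: AllocationVector(0.80, 0.10, 0.10),
            PhenoPhase.STEADY_GROWTH: steady,
            PhenoPhase.SENESCENCE: AllocationVector(0.0, 0.55, 0.45),
            PhenoPhase.DORMANT: AllocationVector(0.0, 0.55, 0.45),
        },
    )


@dataclass(frozen=True)
class EalcoParams:
    """Prescribed-relationship allocation parameters.

    tissue_ratio
        Foliage:sapwood:fine-root maintenance target (1:0.75:0.5 for
        conifers, 1:3:2 for deciduous trees).  The annual outcome of the
        scheme does not depend on it (foliage allocation is set by the
        prescribed LAI and the wood:root split is fixed), but it is kept
        for completeness of the parameterisation.
    post_max_split
        (wood, fine-root) fractions applied once LAI has reached the
        prescribed maximum; must sum to 1.
    lai_max_by_year
        Prescribed maximum LAI per (year, treatment), emulating the use
        of observed site LAI as a driver.
    """

    tissue_ratio: tuple[float, float, float] = (1.0, 0.75, 0.5)
    post_max_split: tuple[float, float] = (0.60, 0.40)
    lai_max_by_year: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tissue_ratio):
            raise InvalidArgumentError("tissue_ratio entries must be positive")
        if abs(sum(self.post_max_split) - 1.0) > 1e-9:
            raise InvalidArgumentError("post_max_split must sum to 1")


def ealco_alloc(
    params: EalcoParams,
    lai: float,
    year: int,
    treatment: str,
) -> AllocationVector:
    """Allocate all growth C to foliage until the prescribed maximum LAI
    for (year, treatment) is reached, then split it wood:root."""
    if lai < 0:
        raise InvalidArgumentError(f"lai must be >= 0, got {lai!r}")
    try:
        lai_cap = params.lai_max_by_year[(year, treatment)]
    except KeyError:
        raise ConfigurationError(
            f"no prescribed maximum LAI for year {year}, treatment {treatment!r}"
        ) from None
    if lai < lai_cap:
        return AllocationVector(1.0, 0.0, 0.0, 0.0)
    w, r = params.post_max_split
    return AllocationVector(0.0, w, r, 0.0)
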