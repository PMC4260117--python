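"""Assumption-centred diagnostics computed identically from simulated or
observation-style annual tables.

All metrics operate on annual records with component NPP, litter
(including mortality), annual maximum biomass and annual maximum LAI:

* allocation fractions — component NPP over total NPP;
* turnover rate — annual litter over annual maximum biomass; lifespan is
  its inverse, and multi-year lifespans average the *annual lifespans*
  (not the annual rates);
* whole-canopy SLA — LAI over foliage biomass;
* CO2 response ratio — mean over years of the elevated series over the
  ambient mean (for biomass and LAI the annual value is the within-year
  maximum);
* NPP retention — the percentage of the eCO2-induced extra cumulative
  NPP still present in live biomass at the end of the run.  Values above
  100% or below 0% are legitimate (they arise from turnover-time or
  allocation shifts between treatments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "AnnualRecord",
    "ANNUAL_RECORD_COLUMNS",
    "DiagnosticsTable",
    "allocation_fractions",
    "turnover_lifespan",
    "canopy_sla",
    "co2_response_ratio",
    "npp_retention",
    "diagnostics_table",
]

ANNUAL_RECORD_COLUMNS = (
    "year",
    "npp_f",
    "npp_w",
    "npp_r",
    "npp_rep",
    "litter_f",
    "litter_w",
    "litter_r",
    "bmax_f",
    "bmax_w",
    "bmax_r",
    "lai_max",
)

_COMPONENTS = ("f", "w", "r")


@dataclass(frozen=True)
class AnnualRecord:
    """One year of observation-like outputs (units: kg C m^-2 [yr^-1] and
    m^2 m^-2)."""

    year: int
    npp_f: float
    npp_w: float
    npp_r: float
    npp_rep: float
    litter_f: float
    litter_w: float
    litter_r: float
    bmax_f: float
    bmax_w: float
    bmax_r: float
    lai_max: float

    def __post_init__(self) -> None:
        for name in ANNUAL_RECORD_COLUMNS[1:]:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def npp_total(self) -> float:
        return self.npp_f + self.npp_w + self.npp_r + self.npp_rep

    @property
    def litter_total(self) -> float:
        return self.litter_f + self.litter_w + self.litter_r


def allocation_fractions(rec: AnnualRecord) -> dict[str, float]:
    """Annual allocation coefficients: component NPP / total NPP.

    Returns ``None`` values are never produced — a zero total NPP year is
    flagged by raising; table-level code treats such years as missing and
    drops them from means.
    """
    total = rec.npp_total
    if total <= 0:
        raise InvalidArgumentError(f"year {rec.year}: total NPP is zero — missing year")
    return {
        "f": rec.npp_f / total,
        "w": rec.npp_w / total,
        "r": rec.npp_r / total,
        "rep": rec.npp_rep / total,
    }


def turnover_lifespan(rec: AnnualRecord, component: str) -> tuple[float, float]:
    """Annual turnover rate (litter / max biomass, yr^-1) and lifespan
    (max biomass / litter, yr) for one component.

    Zero litter gives an infinite lifespan (and zero rate), reported as
    ``math.inf`` rather than an error.
    """
    if component not in _COMPONENTS:
        raise InvalidArgumentError(f"unknown component {component!r}")
    bmax = getattr(rec, "bmax_" + component)
    litter = getattr(rec, "litter_" + component)
    if bmax <= 0:
        raise InvalidArgumentError(
            f"year {rec.year}: max biomass of component {component!r} is zero"
        )
    if litter == 0:
        return 0.0, math.inf
    return litter / bmax, bmax / litter


def canopy_sla(lai_max: float, b_f_at_peak: float) -> float:
    """Whole-canopy specific leaf area: LAI / foliage biomass (m^2 kg^-1 C)."""
    if b_f_at_peak <= 0:
        raise InvalidArgumentError("foliage biomass must be > 0 to define SLA")
    if lai_max < 0:
        raise InvalidArgumentError("lai_max must be >= 0")
    return lai_max / b_f_at_peak


def co2_response_ratio(
    series_elev: Sequence[float], series_amb: Sequence[float]
) -> float:
    """Mean of the elevated annual values over the mean of the ambient
    annual values (for biomass and LAI, feed in within-year maxima)."""
    elev = np.asarray(series_elev, dtype=float)
    amb = np.asarray(series_amb, dtype=float)
    if elev.shape != amb.shape:
        raise InvalidArgumentError(
            f"series length mismatch: {elev.shape} vs {amb.shape}"
        )
    mean_amb = float(np.mean(amb))
    if mean_amb <= 0:
        raise InvalidArgumentError("ambient mean must be > 0")
    return float(np.mean(elev)) / mean_amb


def npp_retention(
    cum_npp_amb: float,
    cum_npp_elev: float,
    d_biomass_amb: float,
    d_biomass_elev: float,
) -> float:
    """Percentage of the eCO2-induced extra cumulative NPP retained in
    live biomass at the end of the experiment:

        100 * (ΔB_elev − ΔB_amb) / (ΣNPP_elev − ΣNPP_amb)

    The statistic is undefined when the treatments' cumulative NPP do
    not differ; it may exceed 100 or fall below 0.
    """
    extra_npp = cum_npp_elev - cum_npp_amb
    if extra_npp <= 0:
        raise InvalidArgumentError(
            "cumulative NPP under elevated CO2 must exceed ambient for the "
            "retention statistic to be defined"
        )
    return 100.0 * (d_biomass_elev - d_biomass_amb) / extra_npp


@dataclass(frozen=True)
class DiagnosticsTable:
    """Per-year and summary diagnostics for one treatment run."""

    per_year: pd.DataFrame  # year, alloc_f/w/r/rep, rate_f/w/r, lifespan_f/w/r, sla
    mean_alloc: dict[str, float]  # NPP-weighted over non-missing years
    mean_lifespan: dict[str, float]  # mean of annual lifespans
    mean_rate: dict[str, float]
    mean_sla: float
    cum_npp: float
    n_missing_years: int


def diagnostics_table(records: Iterable[AnnualRecord]) -> DiagnosticsTable:
    """Compute the full per-year and summary diagnostics for a sequence
    of annual records.

    Mean allocation coefficients are NPP-weighted means of the annual
    coefficients (equivalently, summed component NPP over summed total
    NPP); mean lifespans average the annual lifespans, skipping infinite
    years; years with zero total NPP are dropped from all means and
    counted.
    """
    recs = list(records)
    if not recs:
        raise InvalidArgumentError("no records supplied")

    rows = []
    n_missing = 0
    for rec in recs:
        row: dict[str, float] = {"year": rec.year}
        try:
            fr = allocation_fractions(rec)
        except InvalidArgumentError:
            n_missing += 1
            fr = {k: math.nan for k in ("f", "w", "r", "rep")}
        for k, v in fr.items():
            row["alloc_" + k] = v
        for comp in _COMPONENTS:
            rate, life = turnover_lifespan(rec, comp)
            row["rate_" + comp] = rate
            row["lifespan_" + comp] = life
        row["sla"] = canopy_sla(rec.lai_max, rec.bmax_f) if rec.bmax_f > 0 else math.nan
        rows.append(row)
    per_year = pd.DataFrame(rows)

    valid = [r for r in recs if r.npp_total > 0]
    cum_by_comp = {
        c: sum(getattr(r, "npp_" + c) for r in valid) for c in ("f", "w", "r", "rep")
    }
    cum_total = sum(cum_by_comp.values())
    mean_alloc = {c: cum_by_comp[c] / cum_total for c in cum_by_comp}

    mean_lifespan: dict[str, float] = {}
    mean_rate: dict[str, float] = {}
    for comp in _COMPONENTS:
        lives = per_year["lifespan_" + comp]
        finite = lives[np.isfinite(lives)]
        mean_lifespan[comp] = float(finite.mean()) if len(finite) else math.inf
        mean_rate[comp] = float(per_year["rate_" + comp].mean())

    return DiagnosticsTable(
        per_year=per_year,
        mean_alloc=mean_alloc,
        mean_lifespan=mean_lifespan,
        mean_rate=mean_rate,
        mean_sla=float(per_year["sla"].mean()),
        cum_npp=sum(r.npp_total for r in recs),
        n_missing_years=n_missing,
    )
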