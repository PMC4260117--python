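# standalloc

Stand-level carbon **alloc**ation and turnover simulation, built for
asking a specific question: *when elevated CO2 boosts forest
productivity, where does the extra carbon go — and how much of it
stays?*  The answer depends on how a model divides growth carbon among
foliage, wood and fine roots, and on how fast each tissue cycles back
to litter.  `standalloc` packages the machinery needed to probe that
question at desk scale: a minimal stand carbon model, pluggable
allocation schemes spanning the four families used by ecosystem models,
the observation-convention diagnostics used at forest FACE (free-air
CO2 enrichment) experiments, and a seeded synthetic FACE-experiment
generator so every analysis is reproducible without any site data.

It is aimed at ecosystem modellers and ecophysiologists who want to
study allocation-scheme behaviour in isolation — separated from
photosynthesis, water balance and nutrient cycling, which enter only as
prescribed forcings.

## The model

Each biomass pool *B<sub>i</sub>* (foliage *f*, wood *w* including
coarse roots, fine roots *r*, plus a cumulative reproduction sink)
follows

&nbsp;&nbsp;&nbsp;&nbsp;d*B<sub>i</sub>*/d*t* = *a<sub>i</sub>*·NPP − *u<sub>i</sub>*·*B<sub>i</sub>*

where the allocation coefficients *a<sub>i</sub>* sum to one and the
*u<sub>i</sub>* are first-order turnover rates (yr⁻¹, lifespan =
1/*u<sub>i</sub>*).  NPP is an exogenous forcing.  The allocation
coefficients come from a pluggable scheme:

| class | scheme(s) | idea |
|---|---|---|
| fixed coefficients | `fixed`, `fixed_annual`, `ealco` | constant fractions, optionally differing by phenological phase or prescribed per treatment |
| functional relationships | `ed2`, `lpj`, `ocn` | maintain pipe-model (leaf:sapwood) and functional-balance (leaf:root, stress-dependent) relations among *biomass pools* |
| resource limitation | `isam`, `teco`, `daycent` | compute the *coefficients* from light/water/nutrient limitation, with caps and priority orders |
| canopy optimisation | `sdgvm` | choose the LAI at which the lowest canopy layer breaks even; fixed wood:root split of the rest |

Diagnostics follow the field conventions: allocation fractions as
component NPP over total NPP; turnover rate as annual litter over
annual maximum biomass (lifespan its inverse, averaged over years);
whole-canopy SLA as LAI over foliage biomass; CO2 response ratios as
means of annual (maximum) values, elevated over ambient; and the NPP
retention rate, 100·(ΔB<sub>elev</sub> − ΔB<sub>amb</sub>)/(ΣNPP<sub>elev</sub> − ΣNPP<sub>amb</sub>),
the share of the CO2-induced extra carbon still in live biomass at the
end of the experiment.

## Worked example

`examples/duke_fixed.yaml` describes a 10-year paired experiment on an
evergreen stand (+200 μmol mol⁻¹ CO2 step, noise off) under a pure
fixed-coefficient scheme with foliage/wood/root fractions 0.30/0.45/0.25
and lifespans of about 2/125/3.6 years:

```bash
standalloc run --config examples/duke_fixed.yaml
cat results/duke_fixed/report.txt
```

```
Paired FACE-style experiment — scheme 'fixed', seed 1

                             ambient    elevated
mean alloc f                  0.3000      0.3000
mean alloc w                  0.4500      0.4500
mean alloc r                  0.2500      0.2500
mean alloc rep                0.0000      0.0000
mean lifespan f                 2.04        2.06
mean lifespan w               127.54      128.00
mean lifespan r                 3.78        3.81

npp_ratio                       1.1988
foliage_biomass_ratio           1.1786
lai_ratio                       1.1032
sla_ratio                       0.9360
alloc_f_response                0.0000
alloc_w_response               -0.0000
alloc_r_response               -0.0000
npp_retention_percent            57.59
```

Reading it: elevated CO2 raises NPP by ~20% but the fixed scheme, by
construction, shows exactly zero allocation response.  The diagnosed
lifespans sit near the imposed 1/*u* (slightly above, because the stand
is still growing, so annual-maximum biomass exceeds the mean biomass
that generated the litter).  Foliage biomass rises almost as much as
NPP, but the 6.4% observation-layer SLA reduction under elevated CO2
(sla_ratio 0.936) damps the LAI response to ~10%.  58% of the extra
carbon is still in live biomass after a decade — most of it parked in
slow-turnover wood.

Other entry points: `standalloc diagnose` (tables-only mode for
external annual-record CSVs), `standalloc synth` (emit synthetic
observation tables plus their truth ledger), `standalloc recover`
(diagnostic-recovery report against the ledger).  The numbered scripts
under `analysis/` run the full scheme intercomparison: synthetic sites,
allocation responses per scheme, lifespan tables, carbon-storage
consequences, and Monte-Carlo recovery validation, each writing a CSV
under `results/`.

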