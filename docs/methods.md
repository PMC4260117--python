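# Methods

## Pool model and integration

The stand is four carbon pools — foliage, wood (stem, branches and
coarse roots lumped), fine roots, and a cumulative reproduction sink —
obeying dB_i/dt = a_i·NPP − u_i·B_i.  NPP is a prescribed forcing:
the package's scope is the division of growth carbon, not its
acquisition, so photosynthesis, water balance and nitrogen cycling are
represented only by the CO2 concentration and the 0–1 water (W),
nitrogen (N) and light (L) availability scalars that schemes read.
Labile/storage pools are out of scope; allocation acts directly on the
carbon supplied each step.  Reproduction is a terminal sink with no
turnover pathway back to litter.

Integration is explicit Euler.  Daily schemes use dt = 1/365 yr;
annual schemes (the annual allometric-constraint scheme and the canopy
optimiser, plus the annual fixed variant) bank the year's carbon and
allocate it on the last day against the annual-mean environment, while
turnover always acts daily.  A stability guard rejects dt·u ≥ 1, which
keeps pools non-negative; halving dt changes 10-year trajectories by
well under 1% at the daily step (checked in the suite).  Calendar:
years are indexed from treatment start, days of year are 1-based, no
leap days.

## Allocation schemes

**Fixed coefficients.**  A constant vector; optionally a table per
phenological phase (80/10/10 during leaf expansion, a steady-growth
vector, 0/55/45 wood:root in the final phases), and optionally a
prescribed elevated-treatment override from a configurable start year
(default year 2 — deciduous growth follows the previous year's
accumulated productivity, so a prescribed treatment shift appears one
year late).  The prescribed-relationship variant allocates everything
to foliage until a per-year, per-treatment maximum LAI is reached and
then splits carbon 60:40 wood:root.

**Functional relationships.**  The deficit-filling scheme grows leaf
and root pools toward targets derived from the pipe-model partition
B_leaf_peak = B_a/(1 + q + q_sw·h) of active biomass B_a, with the
leaf target scaled by a 0–1 phenology factor e(t) and the root target
q·B_leaf_peak, q = q_base + q_stress_gain·(1 − min(W, N)); surplus
("reserve") carbon is split 70:30 between wood and reproduction.  The
linear stress dependence of q is this package's parameterisation of
"root demand rises with limitation".  Because the lumped wood pool
makes B_a much larger than a sapwood-only active pool, the default
q_sw (0.5 per m of height) is set so that targets are attainable for a
closed-canopy stand; with a literal sapwood-scale constant the targets
would sit permanently out of reach and wood would never be funded.

The allometric-constraint scheme takes 10% of NPP for reproduction and
solves for non-negative leaf/wood/root increments such that, after the
increment, (i) LAI = k_la_sa·SA, (ii) H = k_allom2·D^k_allom3, and
(iii) C_f/C_r = lr_max·min(N, W) (a "product" combination of N and W
is selectable).  Geometry treats the wood pool as a cylinder of
configured density at the allometric height with one effective stem
per m²; sapwood area follows as SA = C_w/(ρ·H), which gives a closed
form for H(C_w).  Constraint (iii) eliminates the root increment and
the residual sla·C_f′ − k_la_sa·SA(C_w′) is strictly increasing in the
leaf increment, so bisection (tolerance 1e-10 kg C m⁻², ≤200
iterations) solves the system; when no exact non-negative solution
exists (stands far off allometry) the closest constrained split is
returned and flagged, never a negative increment.  The daily variant
applies the same solver to each day's carbon.

**Resource limitation.**  The light/water closed form is
a_w = (ε_w + ω(1−L))/(1 + ω(2−L−W)), a_r = (ε_r + ω(1−W))/(1 + ω(2−L−W)),
a_f the residual (clipped at zero with renormalisation), with
L = exp(−k·LAI); deciduous mode overrides it by phase (all-to-leaf
during expansion, nothing-to-leaf during senescence).  The demand/cap
scheme gives foliage the carbon needed to close the gap to a fixed
maximum LAI, at most 40% of the step's carbon, and roots a demand
(bmR/bmL)(1−W) capped at 30%, wood taking the rest; the cap values are
the scheme's defining constants.  The priority scheme gives fine roots
5–18% of NPP on the stronger of the two stresses max(1−W, 1−N), then
foliage the whole residual until a wood-biomass-dependent maximum LAI
(coef·B_w^exp) is attained, then wood.  Because its call signature
carries neither SLA nor the step's carbon, the foliage demand cannot
be metered in carbon units; the priority is implemented as a switch
(all residual to foliage below the LAI cap, all to wood at it), which
matches the verbal priority order and both boundary behaviours.

**Canopy optimisation.**  Beer-law light decay with linear conversion
to carbon gain: a layer at depth LAI earns a0·s·exp(−k·LAI) per unit
leaf area and year (s the CO2 scalar) and costs leaf_cost
(construction + respiration folded together).  The optimal LAI is the
deepest layer, on a layer_dlai grid, that still pays for itself.
Allocation funds the *previous* year's optimum (the one-year lag is
integral; year 0 uses a configured starting target), accounting for
surviving foliage through an annual foliage-loss fraction (default 1,
the deciduous case); the remainder is split wood:root at a fixed
fraction.  The CO2 scalar on a0 uses the same logarithmic form as the
NPP fertilisation response, 1 + β·ln(CO2/CO2_ref): a raw concentration
ratio would overstate the canopy response relative to NPP and invert
the scheme's characteristic foliage-fraction decline.

## Phenology

A deterministic state machine: DORMANT until the degree-day sum passes
budburst (default 100 °C d); LEAF_EXPANSION until LAI reaches half the
biome maximum; STEADY_GROWTH until, after a peak-arming day (default
day 200), LAI falls below 95% of the biome maximum — plus an
unconditional photoperiod/frost backstop at day 300, without which a
canopy that never drops below the 95% line would never shed at all;
SENESCENCE (foliage shed at 25 yr⁻¹) until LAI ≤ 0.05, then DORMANT.
Evergreen runs stay in STEADY_GROWTH.  The 0.5 and 0.95 thresholds are
the deciduous resource-limitation convention; the peak-arming day
exists because the same 95% line is crossed on the way up in spring.

## Synthetic FACE experiments

The generator emulates a paired ambient/elevated forest FACE
experiment.  Daily NPP is
npp0 · fert · W · N · season · noise_year, with
fert = 1 + β·(1 + α·(1−W))·ln(CO2/CO2_ambient).  Defaults: 10 years,
370 → 570 μmol mol⁻¹ (a +200 step), β = 0.46 so the NPP enhancement is
≈20%, baseline NPP 0.8 kg C m⁻² yr⁻¹, evergreen; the deciduous preset
uses 11 years, 395 → 547 μmol mol⁻¹, β = 0.61 (same ≈20% target),
npp0 = 0.9, a sin² growing-season shape over days 110–300, and a
progressive nitrogen limitation of 0.03 yr⁻¹ applied to the elevated
treatment only.  The drought option lowers W to 0.4 over days 150–280
of stated years — after leaf expansion, in the wood-heavy part of the
season — and the amplification factor α (default 1) strengthens the
CO2 response under low W; both together produce the phase × CO2
interaction through which even a phased *fixed* scheme shows an annual
allocation response.  A water-saving option raises elevated-treatment
W toward 1 (stomatal-closure emulation, used for the demand/cap scheme
signature).  SLA (10 m² kg⁻¹ C evergreen, 20 deciduous) converts
foliage carbon to LAI; the elevated-treatment SLA reductions (6.4%
evergreen preset, 5.3% deciduous preset) are applied only when
converting biomass to the *reported* LAI — schemes always see a
constant SLA, as most models assume.

Randomness: one integer seed; the year-level NPP noise substream is
shared between treatments (so β = 0 gives bit-identical treatments)
and the observation-noise substreams are per treatment.  Observation
noise is mean-1 multiplicative lognormal (default CV 0.05) on annual
component NPP and litter, independent across years and components —
the error model is a declared convention, not an estimate.  Every
table ships with a truth ledger (per-year true coefficients, pre-noise
records, effective SLA, cumulative NPP, biomass increment) keyed by a
run id, and the recovery report compares diagnostics on the noisy
tables against it.  Turnover "truth" in that report follows the same
litter/max-biomass convention computed on the pre-noise records, so
the comparison isolates observation noise from within-year biomass
variation.

What the generator does *not* emulate: real meteorology, storms and
ice damage, stand demography and self-thinning (mortality can only be
injected as exogenous events), multi-species canopies, and any
mechanistic N or water budget.  Passing tests therefore show that the
schemes and diagnostics behave as designed under clean, known forcing —
not that any scheme is right about real forests.

## Problem sizes and numerical choices

Default runs are 10–11 years at a daily step (3650–4015 steps); the
conservation suite draws 100 random scheme/turnover/stand
configurations across all ten scheme variants and checks
ΣNPP = ΔB + Σlitter to 1e-6 relative (explicit Euler conserves mass to
rounding by construction; the check guards the bookkeeping).  Recovery
bias is estimated over 100 seeds at CV 0.05 in the suite and 60 seeds
in the acceptance script.  Mean allocation coefficients are
NPP-weighted (summed component NPP over summed total NPP), which is
what makes phase × CO2 interactions visible; time-weighted means would
hide them.  Multi-year lifespans average annual lifespans, not annual
rates, and zero-litter years report an infinite lifespan and are
skipped in the mean.  Years with zero total NPP are flagged missing,
dropped from means, and counted.

## Known limitations

Lifespan diagnostics read high on growing stands (annual maximum
biomass exceeds the mean biomass that produced the litter) — a real
property of the observation convention, reproduced deliberately.  The
NPP retention rate is numerically fragile when the cumulative NPP
enhancement is small (denominator near zero); it is reported as
undefined/NaN when the enhancement is non-positive.  The
allometric-constraint scheme's single lumped wood pool conflates
sapwood and heartwood, so its geometry constants are effective, not
anatomical.  The prescribed-LAI input mode of the light/water scheme
is a configuration stub only; simulated LAI is always used.
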