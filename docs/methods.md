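# Model description and methods

## Scope and state variables

`trichodiel` simulates one 12-h light period of a single cylindrical
*Trichodesmium* trichome, followed by a single algebraic end-of-day
biosynthesis step. All cellular quantities are normalized to carbon
biomass, so neither absolute biomass nor cell number enters the equations;
the only place the carbon density Q_C = 18,333 mol C m⁻³ appears is the
conversion of biological O₂ fluxes into the intracellular concentration
equation. State variables:

| symbol | meaning | units |
|---|---|---|
| CH₂O | carbohydrate pool | mol C (mol C)⁻¹ |
| CS | carbon-skeleton pool | mol C (mol C)⁻¹ |
| N | fixed nitrogen pool | mol N (mol C)⁻¹ |
| O₂ | intracellular O₂ (one per compartment) | mol m⁻³ |

Initial conditions are empty pools at dawn (yesterday's stores went into
biomass overnight) and O₂ equilibrated to the ambient 0.213 mol m⁻³. The
night contributes no fluxes other than the biosynthesis solve.

## Energy supply and allocation

Irradiance follows I(t) = I_max·sin(πt/T_light). The light-limited PET
potential is v_PETmax·(1 − e^(−α_I·I)) — the same saturating-exponential
form the respiratory-protection rate uses — and realized PET is inhibited
by respiratory protection, V_PET = V_PET,I·e^(−β·V_RP), a coarse stand-in
for plastoquinone-pool feedback on photosystem II.

Each electron through linear PET yields 0.65 ATP, 0.5 NADPH, and 0.25 O₂;
each electron through the Mehler-type alternative route (AET) yields
0.65 ATP and no net NADPH or O₂. Since ATP yield is identical on both
routes, the AET fraction f_AET only tunes the NADPH (and O₂) yield; the
fraction required to hit an ATP:NADPH demand ratio r is

    f_AET(r) = 1 − q_ATP,LPET / (q_NADPH,LPET · r) = 1 − 1.3/r,

giving the two reference values 56.7% (pure N₂ fixation, r = 9/3 = 3) and
31.6% (pure carbon fixation incl. CCM, r = 3.8/2 = 1.9).

Neither currency is stored. At each instant the allocator (i) serves the
regulated N₂-fixation demand first, capped by the full ATP budget and by
the NADPH available at the 56.7% reference split, (ii) gives the entire
ATP residual to carbon fixation, and (iii) solves f_AET in closed form so
NADPH supply exactly equals demand. Maintenance is a multiplicative
surcharge γ_MT = 10% on all process ATP, during the day and at night
alike. Because the surcharge raises every effective demand ratio above the
pure-LPET 1.3, the closed-form f_AET always lies inside (0, 1): the
operating endpoints are 1 − 1.3/2.09 ≈ 0.378 (pure carbon fixation) and
1 − 1.3/3.3 ≈ 0.606 (pure N₂ fixation), while the 56.7%/31.6% values are
the maintenance-free reference stoichiometry. ATP produced by respiratory
protection is wasted as heat and never enters the ledger. When AET is
ablated, f_AET is pinned at 0 and whichever currency is in surplus is
discarded (recorded explicitly in the budget).

The maximal N₂-fixation potential uses the printed reference split,
V_NFmax = V_PET·(1 − 0.567)·0.5/3, and is then regulated by
carbon-skeleton availability, the N storage ceiling, and Michaelis–Menten
O₂ inhibition whose factor is k_O₂NF/(O₂ + k_O₂NF).

## Respiratory protection and O₂

RP respires carbohydrate at up to v_RPmax, stimulated by intracellular O₂
(same half-saturation k_O₂NF as the inhibition term, as the model reuses
the symbol), by light, and by the same N₂-fixation demand signals (CS and
unfilled N storage); stoichiometry is 1 mol O₂ per mol C (carbohydrate
combustion). A steep carbohydrate-availability factor
CH₂O/(CH₂O + 10⁻⁶) shuts RP off smoothly as the pool empties — a purely
numerical regularization that keeps pools non-negative inside the stiff
integrator without a discontinuous switch.

O₂ exchange across the multilayer cell envelope and diffusive boundary
layer uses cylindrical log-resistance geometry with the membrane
resistance inflated by 1/ε (ε = 10⁻⁴, membrane:seawater diffusivity
ratio). The boundary-layer thickness follows the configurable rule
L_b = k_b·(R + L_g) with default k_b = 1024; the default is kept
overridable because the multiplier is uncertain, but at ε ≤ 10⁻³ the
membrane term dominates the series resistance and the result is
insensitive to k_b.

In the segregated variant each cell type keeps its own O₂ and exchanges
with a thin, well-mixed O₂ layer wrapped around the whole trichome
(interface areas partitioned by cell fraction), which in turn exchanges
with the far field through the boundary layer. The mixed layer is treated
as quasi-steady — its concentration is the conductance-weighted mean that
closes the instantaneous balance — so total O₂ is conserved exactly by
construction. Diazocytes produce no O₂ but retain RP capability.

## Spatial segregation and transfer losses

Diazocytes make up f_D = 15% of the cells; PET, carbon fixation, and
carbon-skeleton synthesis run in the other 85%, N₂ fixation only in
diazocytes (a `nf_in_photo` switch relaxes this for the reduction check
below). Carbohydrate, carbon skeleton, and fixed N are shared pools;
whole-trichome rates are biomass-weighted sums of per-compartment rates.

A loss fraction λ ∈ [0, 0.8] applies to *transferred* material:

- fixed N: the diazocyte-retained f_D share is loss-free, so one mol fixed
  adds f_D + (1−f_D)(1−λ) to the pool;
- carbohydrate respired in diazocytes: the f_D share of the evenly
  distributed pool already resides there, the rest transfers in, so one
  mol respired draws f_D + (1−f_D)/(1−λ);
- ATP/NADPH consumed by N₂ fixation: produced only in photosynthetic
  cells and never stored, so the whole demand transfers at cost 1/(1−λ).
  (This deliberately differs from the carbohydrate rule: an unstored
  currency has no locally resident share.)

Losses are applied instantaneously at production/consumption time; there
is no explicit extracellular pool.

## Biosynthesis, growth, budgets

At dusk the N-limited biomass is Bio_N = N/0.159 and the C-limited biomass
solves Bio_C·q_BIO·(1+γ_MT) = CH₂O_resp·q_RESP together with
Bio_C = CH₂O − CH₂O_resp + CS, i.e. Bio_C = (CH₂O+CS)/1.44 at the default
stoichiometry (q_BIO = 2, q_RESP = 5). If the implied respiration exceeds
the carbohydrate pool, all carbohydrate is respired and the carbon
skeleton is usable only up to the energy that affords (flagged in the
result). Bio = min(Bio_C, Bio_N) and G = ln(1 + Bio)/1 day.

Gross C fixation, gross N₂ fixation, RP carbon, and transfer losses are
carried as quadrature states inside the integrator, so the daily carbon
and nitrogen ledgers close at solver tolerance rather than output-grid
tolerance. The daily ATP allocation ledger spans the whole diel cycle:
daytime process ATP plus the night biosynthesis ATP and its maintenance
surcharge — with that convention the carbon-fixation share of ATP is 81%
(unified) and 73% (segregated) at the defaults. The reported daily AET
fraction is electron-weighted, ∫f_AET·V_PET dt / ∫V_PET dt.

## Numerics

The ODE system (4–5 pool states + 4 quadrature states) is stiff: the O₂
relaxation time through the membrane is ≲ 1 s while the light period is
43,200 s. It is integrated with LSODA at rtol 10⁻⁶ (absolute tolerances
10⁻¹⁰ for pools, 10⁻⁹ for O₂) with minute-resolution dense output; one
diel integration takes ~0.1 s, so the full experiment suite runs in
minutes. Tightening tolerances tenfold changes G by < 0.1% (tested).
Degenerate inputs (zero light, zero PET, empty pools) produce zero rates
with a limitation flag rather than errors; f_AET is clipped to [0, 1].

The multistart optimizer draws Latin-hypercube starts over the documented
bounds (half-saturations in [0, 1]; maximal rates in [0, 5×10⁻⁴] s⁻¹, the
PSII O₂-production potential) and refines each with a bounded Nelder–Mead
simplex on parameters rescaled to the unit box, since the raw scales span
five orders of magnitude. Defaults: 64 starts, seed 42, relative growth
tolerance 10⁻⁶; everything is deterministic given the seed. The segregated
variant re-optimizes only v_RPmax (1-D bounded search after a unimodality
grid pre-scan), reflecting the lower RP demand when nitrogenase sits in
low-O₂ diazocytes.

## Calibrated constants

The stoichiometric quotas, elemental ratios, k_O₂NF = 10⁻² mol m⁻³,
ε = 10⁻⁴, f_D = 0.15, and ambient O₂ are biochemistry- or
literature-constrained. The light-curve, feedback, storage-ceiling, and
geometry constants are **not**; they are set by
`experiments.calibrate_unknowns`, a bounded least-squares fit (log-scaled
knobs, relative residuals) of the unified model at the published optimized
free-parameter values against three published daily outputs:

| target | value | tolerance |
|---|---|---|
| gross C fixation | 2.24 mol C (mol C)⁻¹ d⁻¹ | ±0.15 |
| gross C:N fixation ratio | 49 | ±2 |
| growth rate | 0.25 d⁻¹ | ±0.03 |

v_PETmax = 2×10⁻³ mol e⁻ (mol C)⁻¹ s⁻¹ is fixed beforehand from the
documented parameter bound: the 5×10⁻⁴ ceiling on the maximal rates is the
PSII O₂-production potential, and O₂ yield is 0.25 per LPET electron.
I_max = 2000 µmol photons m⁻² s⁻¹ is a typical tropical noon irradiance
(only the product α_I·I_max matters for the light response). The fitted
knobs, frozen as package defaults and clearly labelled calibrated (the
`CALIBRATED` set in `params.py`):

| constant | calibrated default | role |
|---|---|---|
| α_I | 4.99×10⁻⁴ (µmol m⁻² s⁻¹)⁻¹ | P–I curve initial slope |
| β | 2.0×10⁴ s | RP inhibition of PET |
| N_max | 0.1536 mol N (mol C)⁻¹ | fixed-N storage ceiling |
| CS_max | 0.739 mol C (mol C)⁻¹ | carbon-skeleton ceiling |
| R | 6.90 µm | cytoplasm radius |

The remaining geometry (membrane thickness 50 nm, trichome length 1 mm,
d_O₂ = 2.1×10⁻⁹ m² s⁻¹) uses literature-typical magnitudes; the diffusive
coupling depends on them only through the lumped conductance, which the
radius knob absorbs. The calibration residual at these defaults is ~10⁻³
relative on all three targets.

Quantities *not* targeted by the calibration land close to their published
counterparts, which is the main internal validation: daily AET electron
fraction 38.9% (published 39%), biomass share of gross fixed C 12.7%
(13%), NADPH-to-carbon-fixation share 97.0%/93.8% (97%/93%), ATP share
81.5%/72.7% (81%/71%), segregated-variant growth 0.49 d⁻¹ and gross N
0.100 (0.51, 0.11), re-optimized weak-inhibition endpoint
(k_O₂NF = 10⁻¹) growth 0.52 d⁻¹ with C:N 23 (0.53, 23), and a cold
multistart recovers the published free-parameter optimum
(0.060, 3.8×10⁻⁶, 0.59, 4.5×10⁻⁴ vs 0.06, 3.7×10⁻⁶, 0.58, 4.5×10⁻⁴).

Derived quantities checked against published values in
`tests/test_acceptance.py` inherit calibration-level tolerances rather
than printing precision: daily rates at the tolerances above, allocation
fractions ±2–4 percentage points, the lossless segregation growth ratio
2.04 ± 0.25, and the transfer-loss crossover at λ = 0.5 ± 0.2 (it falls
near 0.41 here). Two known quantitative departures, both documented rather
than tuned away: the no-AET ablation reduces growth by 87% here versus a
published 62% (its O₂-production and RP responses, +50% and +12%, match
the published +56% and +11%), and the crossover sits slightly below 0.5.
Both are sensitive to the calibrated light curve; the corresponding tests
assert the response pattern and the stated bands.

## What the model deliberately omits

No nighttime dynamics beyond the single biosynthesis solve; no multi-day
spin-up (G is defined per day); no nitrate/ammonium uptake (N₂ fixation is
the sole N source); no photoinhibition, photosystem state transitions, or
explicit plastoquinone pool; no colony/particle microenvironments,
attached heterotroph respiration, or time-varying ambient O₂; no dynamic
membrane-permeability (hopanoid) regulation. Consequently, agreement of
the diel patterns here says nothing about trichomes embedded in colonies
or about taxa whose N₂ fixation lacks temporal structure; the model's
temporal segregation is an optimality result under these closures, not a
prediction for every culture condition.
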