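# Methods

## Model structure

`sedcarb` couples two mass balances at a daily step: a completely mixed
reach reactor for water-column constituents and a two-layer sediment bed
for deposited organic carbon.

### Sediment diagenesis

The bed is a 1 mm aerobic layer (thickness H₁) over a 10 cm anaerobic
layer (H₂). Organic carbon enters the anaerobic layer by settling and is
partitioned into three reactivity classes with fixed fractions
(f_G1, f_G2, f_G3) = (0.65, 0.20, 0.15). Each pool evolves as

    H₂ dPOC_Gi/dt = J_dep,Gi − J_res,Gi − J_min,Gi − J_bury,Gi

* Mineralization: first order with Arrhenius-type temperature
  correction, J_min = k_Gi·θ_Gi^(T−20)·POC_Gi·H₂, with
  k_G1 = 0.035 day⁻¹ (θ = 1.10), k_G2 = 0.0018 day⁻¹ (θ = 1.15), and
  k_G3 ≡ 0 (inert pool). These are the standard defaults of the
  Di Toro / QUAL2K sediment-flux lineage for settled organic matter.
* Burial: J_bury = w_b·POC_Gi with w_b = 6.85×10⁻⁶ m day⁻¹, the riverbed
  value of that same lineage (about 2.5 mm yr⁻¹; lake/estuary models
  often use 100× more, which is the main reason buried carbon is a small
  term here).
* Resuspension: J_res = POC_Gi/(ρ_sed·10⁶)·J_SED_R — the pool's carbon
  content per gram of bulk sediment (ρ_sed = 1.0 Mg m⁻³ by default) times
  the resuspended bulk-sediment mass flux supplied by the channel
  sediment balance.

Mineralized carbon J_C = J_min,G1 + J_min,G2, less an optional
denitrification sink J_C,den (zero by default; nitrogen cycling is out of
scope, but a constant forcing flux can be supplied), becomes dissolved
methane. Methane is poorly soluble, so the dissolved pathway saturates:
the dissolved delivery to the aerobic layer is capped at a transport
capacity and the excess leaves directly as bubbles,

    J_CH4,d = min(J_C − J_C,den, v_diff·CH4_sat(T)),   J_CH4,gas = excess
    CH4_sat(T) = CH4_sat,ref · θ_sat^(20−T)

with CH4_sat,ref = 37.5 gC m⁻³ (100 g O₂ m⁻³ at 2.67 gO₂/gC) and
θ_sat = 1.024. The aerobic layer then balances delivered CH₄ against
diffusion to the overlying water (v_diff·CH₄, v_diff = 0.1 m day⁻¹),
oxidation to CO₂ (k_ox·θ_ox^(T−20)·CH₄·H₁, k_ox = 100 day⁻¹,
θ_ox = 1.079; the product k_ox·H₁ = 0.1 m day⁻¹ is an effective oxidation
velocity) and resuspension. Oxidized CH₄ leaves the sediment as CO₂ gas,
so the total inorganic release to the water column is
J_CH4,w + J_CH4,gas + J_CH4,o.

The bubbling threshold and the oxidation/diffusion closure are the one
genuinely open part of this formulation: the sediment-flux literature the
parameterization descends from resolves them inside a more elaborate
porewater model. The closure above is the minimal one that preserves the
qualitative behavior (saturation-limited dissolved transport, bubbling
under high diagenesis, warm water holding less methane); all five
constants are exposed in the `[diagenesis]` config section, and the
budget-level results are insensitive to the split between the three
inorganic pathways because they are summed in the release term.

### Numerics

The anaerobic pools use explicit Euler at dt = 1 day; their fastest rate
(k_G1 + w_b/H₂ ≈ 0.035 day⁻¹) makes the step well-conditioned, and the
Euler fixed point coincides with the ODE steady state, so long-run pool
levels are exact. Sinks are evaluated at start-of-step concentrations and
proportionally rescaled whenever one step would overdraw a pool
(deposition counts as same-day supply), which guarantees nonnegative
pools without silently creating or destroying mass.

The aerobic methane layer is stiff (v_diff/H₁ = 100 day⁻¹), so its linear
sinks are integrated by backward Euler: the update divides by
(1 + dt·Σrates) and evaluates all sink fluxes at the end-of-step
concentration. This is unconditionally stable, keeps CH₄ ≥ 0, shares the
exact fixed point, and satisfies the same per-step conservation identity
as the explicit scheme, to rounding error.

Per step and per run, the ledger

    deposition = Δstorage + resuspension + burial + inorganic + denitrification

closes to better than 10⁻⁹ relative (in practice ~10⁻¹⁴); the test suite
asserts this on randomized forcing.

### Reach routing

The reach is one completely mixed reactor (default 50 km × 40 m of bed,
standing in for the channel network of a ~220 km² watershed; depth and
velocity vary daily with flow). Constituents: labile and refractory POC,
DOC tagged by source, suspended sediment. Per day and per constituent:
inflow (upland loads; POC split 50/50 labile/refractory), outflow Q·C,
settling V·C over the bed area, POC dissolution to DOC
(k_poc_diss = 0.005 day⁻¹), DOC mineralization (k_doc_min = 0.01 day⁻¹).
The two DOC tags never mix: upland DOC stays allochthonous, and the
autochthonous tag is fed only by in-reach POC dissolution plus an
optional algal-mortality source (zero by default). The rate constants are
modest literature-magnitude values chosen so autochthonous DOC stays a
few percent of allochthonous input, the regime observed in small
agricultural watersheds; both are configurable.

Suspended sediment exchanges with an erodible bed store under the
stream-power capacity C_max = SPCON·(PRF·v)^SPEXP (v in m s⁻¹; SPCON
carries the unit convention, g m⁻³ at PRF·v = 1). Excess concentration
deposits; deficit resuspends, limited by the bed store, and the resulting
bulk flux J_SED_R drives the carbon resuspension terms. With the
calibrated channel defaults (SPCON = 0.003238, SPEXP = 1.1975,
PRF = 0.022) the capacity is tiny, so the reach is deposition-dominated
and carbon resuspension is a trace term — the regime the sensitivity
analysis confirms.

Stepping is on masses (g), with concentrations derived from the daily
volume; this is what makes whole-run conservation exact under a moving
water level. Sinks share the same proportional-rescale guard as the
sediment model. Organic carbon resuspended from the bed re-enters the
refractory POC pool on the following day (one-day lag, carried as an
explicit in-flight storage term in the ledger); treating returned bed
carbon as refractory is a choice — it has been through the labile pools
once — and is the conservative reading where the fate of returned G3
carbon is concerned.

### Budgets, evaluation, sensitivity

Daily whole-watershed masses (kgC day⁻¹) are summed to average annual
fluxes per hectare (kgC ha⁻¹ yr⁻¹ = 0.1 gC m⁻² yr⁻¹). Only complete
calendar years enter the average by default; a span-length mode
(`calendar_complete = false`) is available because multi-year monitoring
records often end mid-year. Ratios are reported rounded to the printed
precision of the tables they are compared against, with full precision
retained internally; zero denominators yield missing values, not
exceptions. The benthic budget expresses resuspension, burial, inorganic
release and the accumulated remainder as percentages of deposition,
summing to 100 before rounding; the resuspension share includes porewater
CH₄ carried up with bed material so the partition closes exactly.

Evaluation uses NS and P_bias with the standard conventions (NS = 1
perfect, 0 equals the observed-mean predictor; P_bias positive =
underestimation), computed on calendar-month sums of daily loads.
Global sensitivity regresses the NS of each ensemble run on the sampled
parameter values and t-tests each coefficient (two-sided, α = 0.05),
ranking by ascending p-value. Parameter ensembles are Latin-hypercube
draws. Two degenerate regimes are handled explicitly: a constant
objective reports p = 1 for everything (a flat response surface is
insensitive by definition), and a numerically exact linear fit judges
coefficients by their contribution to the objective rather than by
t-tests on rounding noise. Note the t-test is only approximate when the
true response is nonlinear in the influential parameters: irrelevant
parameters can be spuriously flagged at α = 0.05, which is why the robust
product of this analysis is the ranking, not the individual p-values.

### Synthetic forcing

The generator emulates the statistical structure the coupled model needs
from an upland watershed model, not any particular record: storms arrive
as a Poisson process (0.1 day⁻¹) with exponential peak magnitudes (mean
8 m³ s⁻¹) and exponential recession (0.3 day⁻¹) over a 2 m³ s⁻¹ baseflow;
water temperature is a sinusoid (mean 15.4 °C, amplitude 10 °C, minimum
clipped at 0.1 °C); sediment yield follows a rating curve on storm flow
(5th-largest storms dominate, rc_coef = 4.4 Mg day⁻¹ per (m³ s⁻¹)^1.5);
upland POC is eroded sediment × soil organic carbon fraction (0.015 gC
g⁻¹) × enrichment ratio (2.98); DOC is proportional to runoff depth
(0.060 kgC ha⁻¹ mm⁻¹) with lognormal noise; hydraulic depth and velocity
are power laws of flow. The load coefficients were calibrated once, with
the budget module as the yardstick, so a default four-year run delivers
upland POC and DOC in the tens of kgC ha⁻¹ yr⁻¹ (POC ≈ 25–45,
DOC ≈ 38–50 across seeds) — the regime of a small, flat, agricultural
Mid-Atlantic-type watershed — and the simulated budget lands near the
observed structure (Out/WC ≈ 0.67, deposition ≈ 30 % of input,
~75 % of deposited carbon mineralized).

What the generator does *not* emulate: spatial heterogeneity and network
routing (one reach stands in for the channel network), snow, baseflow
recession dynamics, hysteresis in sediment rating, autocorrelated
temperature anomalies, and algal production (the algal-debris forcing
column defaults to zero). Passing tests therefore demonstrate internal
consistency, conservation, and qualitative regime reproduction — not
predictive skill on any real watershed, which requires a full terrestrial
model and observed forcing.

## Default problem sizes

Simulations in the tests and in `scripts/acceptance.py` use a single
reach at daily resolution: four synthetic years (1461 days) for budget
and sensitivity runs, two years for the recovery experiment, k = 100
ensemble members for the sensitivity ranking and a 9 × 8 grid for
parameter recovery. These sizes were chosen as the smallest that exercise
multi-year budget accounting and give stable rankings.

## Known limitations

* The CH₄ saturation/bubbling closure is one defensible reading of an
  under-determined formulation (see above); only the summed inorganic
  release is robust to it.
* Explicit coupling (settling computed from start-of-day concentrations,
  resuspended carbon returned next day) introduces O(dt) splitting error —
  immaterial at the default rates but visible if settling velocities
  approach the daily water depth.
* Denitrification is a constant user-supplied sink, not a nitrate model.
* No dissolved-oxygen feedback: sediment oxygen demand can be derived
  from the inorganic release (2.67 gO₂/gC) for reporting, but it does not
  alter diagenesis rates.
* The sensitivity t-test inherits the usual caveat of regression-based
  global sensitivity: p-values are exact only under a linear response
  with homoscedastic noise.
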