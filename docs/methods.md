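# Methods

This note documents the model equations as implemented, the default
parameter values and why they were chosen, what the synthetic study
generator does and does not emulate, and the numerical and design choices
made where the problem was genuinely open.

## Model structure

### Hydraulic pathway

The soil–plant–atmosphere continuum is three conductance nodes in series,
all expressed per unit leaf area. Soil water potential follows Campbell's
retention curve, Ψ_soil = ψ_e · (θ/θ_sat)^(−b), and soil-to-root
conductance scales as k_sr = k_sr,max · (θ/θ_FC)^(2+3b), capped at
k_sr,max above field capacity. Root-to-canopy conductance is
k_rc = k_rc,max · k_norm(Ψ_canopy,m), where k_norm is the fitted
vulnerability response. The potential cascade is explicit and lagged: the
hour-t root and canopy potentials use the transpiration flux and
conductances of hour t−1, with a gravimetric offset hρg·10⁻⁶ (0.0195 MPa
for a 2 m sapling). The predawn canopy potential assumes zero flux, and all
within-day xylem computations use the dampened canopy potential — the mean
of the instantaneous and predawn values — as the xylem-potential proxy.
There is no plant capacitance and no within-canopy light gradient
(big-leaf).

### Vulnerability response functions

Three forms are implemented, written with |Ψ| ratios so non-integer
exponents of negative arguments never arise:

* Weibull (`WB`): k = exp(−(|Ψ|/|Ψ_ref|)^a). k(0) = 1 exactly; Ψ_ref is the
  potential at k = e⁻¹ ≈ 0.37; the half-loss point is
  Ψ_ref·(ln 2)^(1/a).
* Sigmoid-exponential (`SE`): k = 1 − 1/(1+exp(a(Ψ−Ψ50))).
* Rational sigmoid (`SOXf`): k = 1/(1+(|Ψ|/|Ψ50|)^a).

All three are strictly decreasing in |Ψ| with closed-form inverses. The
default engine parameterization is WB(−3.01 MPa, 2.85), the
combined-posterior median of the five-sample fit, implying 50% conductance
loss at −2.65 MPa. Percent loss of root-to-canopy conductance is reported
as PLk_rc = 100·(1 − k_norm(Ψ_canopy,PD)); although one source formula
reads as percent *remaining*, the loss convention is the only one
consistent with trajectories that rise toward 100% during a dry-down.

### Photosynthesis and non-stomatal limitations

Net assimilation is FvCB: A_n = min(A_vc, A_j) − R_d, with Arrhenius
scaling for Γ*, K_c, K_o, peaked Arrhenius (E_a, E_d, S; normalized so the
25 °C reference is exact) for V_cmax and J_max, and Q10 = 2 for R_d. Leaf
temperature is taken equal to air temperature. Electron transport follows a
non-rectangular hyperbola with curvature θ = 0.9 and quantum yield α = 0.3
mol e⁻ mol photon⁻¹; at the saturating light of the A/Ci protocol
(PAR ≥ 1200) J ≈ J_max, so results are insensitive to these two defaults.
The O₂ mole fraction is 210,000 μmol mol⁻¹. R_d,25 is tied to capacity as
0.015·V_cmax,25.

Non-stomatal limitations multiply the apparent V_cmax,25 and J_max,25 by a
Tuzet sigmoid f(Ψ) = (1+e^{aΨ_ref})/(1+e^{a(Ψ_ref−Ψ)}) of the dampened
canopy potential; f(0) = 1 exactly and the default posterior-median
parameters (Ψ_ref,Tuz = −1.72 MPa, a_Tuz = 2.92) put half-strength
limitation at −1.72 MPa — above (wetter than) the xylem half-loss point, so
photosynthetic down-regulation leads embolism.

### Stomatal optimization

Stomata maximize carbon gain times hydraulic cost. The implemented optimum
is the closed form g_s = ½·g·(√(4ξ/g+1) − 1) with g = ∂A_n/∂C_i (central
differences, step 1 μmol mol⁻¹) and the cost term
ξ = 2 / [(|dk/dΨ|/k)·(r_plant,min/k)·1.6·VPD], evaluated at the dampened
potential, dk/dΨ by central differences (step 0.01 MPa), and ξ capped at
100 mol m⁻² s⁻¹ to guard the vanishing-slope limit near Ψ = 0. A floor
g_min (default 2 mmol m⁻² s⁻¹) represents cuticular leakiness and
imperfect closure; at night (PAR < 1) g_s = g_min.

Two unit conventions deserve explicit statement. **(1) VPD in ξ is in
kPa** — the literal form of the source cost expression. Converting it to a
mole fraction (dividing by P_atm ≈ 93 kPa) inflates ξ ~100-fold, which with
the published posterior magnitudes (r_plant,min ≈ 4.9 MPa m² s mol⁻¹)
yields g_s > 1 mol m⁻² s⁻¹ and tens of kg of daily transpiration —
irreconcilable with the observations those same parameters were calibrated
against. **(2) The transpiration flux** uses the physically required mole
fraction: E = 1.6·g_s·VPD/P_atm per unit leaf area, P_atm = 93 kPa
(≈708 m a.s.l.), with g_s a CO₂-basis conductance and 1.6 the
H₂O:CO₂ diffusivity ratio. Whole-tree daily transpiration is
Σ_hours E·LA·0.018 kg mol⁻¹·3600 s.

A first-principles check (tests/gs_oracle.py) shows the closed form is the
exact argmax of A_n(g_s)·k_norm(Ψ(g_s)) when the potential perturbation
enters through the dampened potential (hence the factor 4 rather than 2
under the root) *and* the marginal cost is frozen at Ψ_m — i.e., for
log-linear k (Weibull with a = 1), where grid search and closed form agree
to a median 0.2%. With the fitted curvature (a = 2.85) and the kPa cost
convention the within-step perturbation is large and the frozen-cost
linearization leaves a median ~15–20% (worst ~2×) gap to the brute-force
argmax; the closed form is therefore documented as a first-order optimum,
and the strict 10% agreement is asserted only in the log-linear limit.

### Ci equilibrium

A_n and g_s are solved jointly each daylight hour by iterating
C_i ← C_a − A_n/g_s with Newton-style adaptive damping: the raw map has
slope −g/g_s, so the update is divided by (1 + g/g_s). A fixed 0.5 damping
diverges when g_s sits at the g_min floor; the adaptive factor converges
for all g_s. Convergence at |ΔC_i| < 0.01 μmol mol⁻¹ or 100 iterations
(the last iterate is accepted with a warning-free fall-through; typical
hours converge in < 20 iterations). C_a = 400 μmol mol⁻¹.

### Soil water: driver vs bucket

Soil water content is by default a prescribed hourly driver (as in
calibration, where it is a measurement). In **bucket mode** the pot is a
sealed 120 L store: hourly extraction E·LA·3600·0.018 kg depletes θ by
mass/(120 L), giving exact mass-balance closure (tested to 0.1%). Scenario
ensembles run in bucket mode because it is the only pathway by which
leaf-area dynamics can feed back on water status: per-leaf-area fluxes and
conductances are unchanged by shedding, but a smaller canopy extracts less
water per tree, keeping the shared soil store wetter. This feedback is the
mechanistic content of the "leaf shedding protects conductance"
hypothesis in the model.

### Leaf shedding

Daily multiplicative decay: LA_i = LA_{i−1}·(1−rate), with rate = 0.002
day⁻¹ (basal turnover) while PLk_rc < 50% and 0.0055 day⁻¹ (drought
shedding) at or above the threshold (boundary inclusive). Over 54 days the
rule sheds at most ~26% of leaf area even if triggered on day one; the
reference run sheds ~21%.

## Bayesian machinery

Vulnerability curves are fit per sample (Gaussian likelihood on PLC with
the residual scale σ a uniform(0.1, 20) nuisance; uniform priors
Ψ ∈ [−3.5, −1.5], a ∈ [1, 8]) and the five per-curve posteriors are merged
by drawing 1000 samples each with replacement. Formulations are ranked by
pooled RMSE, with a pseudo-R² from the squared Spearman correlation.

The gas-exchange calibration samples 3 (Hydraulic: k_sr,max, k_rc,max,
r_plant,min) or 5 (Hydraulic+NSL: + Ψ_ref,Tuz, a_Tuz) parameters plus a
half-normal(0.3 kg day⁻¹) observation-error σ, against daily transpiration
over the first 19 days minus the two cold-front days, with Gaussian
priors truncated to physical domains. The sampler is an affine-invariant
ensemble (emcee) behind a narrow interface; "iterations" count posterior
draws per chain (walkers × steps), several independently seeded runs serve
as chains, and the classic between/within-chain potential-scale-reduction
statistic (implemented here, cross-checked against arviz) must stay below
1.1. Reported defaults are 3 chains × 30k draws with 20k burn-in; the test
and acceptance harnesses use 3 × 10k with the first two-thirds discarded,
which reaches R̂ < 1.07 on the reference study. Posterior-predictive
evaluation regresses observations on the median prediction with an AR(1)
residual structure (statsmodels GLSAR) and reports RMSE, Cox–Snell
pseudo-R², and the relative daily error series.

A structural feature worth knowing: fitting the Hydraulic-only
configuration to data generated with NSL produces a compensating posterior
with substantial mass at the k_sr,max lower prior bound (0.01) — the soil–
root conductance collapse is the only hydraulic mechanism able to mimic the
NSL shutdown's timing. The posterior is bimodal, with a second mode that
instead inflates r_plant,min.

## Synthetic study conditions

The generator emulates a 54-day greenhouse dry-down of ~2 m potted pine
saplings (leaf area 1.35 m², 120 L pots, DOY 212–265), with everything
deterministic given one seed:

* **Drivers**: half-sine PAR (06:00–20:00, midday ~900 μmol m⁻² s⁻¹,
  ±12% day-to-day), diurnal temperature (nights ~15 °C, days ~30 °C,
  clipped to 10–35 °C) and VPD (0.4–2.0 kPa typical peak); days 5–6
  (DOY 216–217) are a cold, dark, low-VPD dip whose daily maximum VPD is
  below every other day's.
* **Truth parameters**: the published posterior medians (k_sr,max 0.77,
  k_rc,max 0.035 mol m⁻² s⁻¹ MPa⁻¹, r_plant,min 4.87 MPa m² s mol⁻¹,
  Ψ_ref,Tuz −1.72 MPa, a_Tuz 2.92, WB(−3.01, 2.85), V_cmax,25 33.3,
  J_max,25 51).
* **Substrate retention**: ψ_e = −0.35 MPa, b = 3.0 (configurable). The
  paper-style study gives only bulk density and field capacity; these two
  values were fixed once so that the truth run lands inside the observed
  envelopes — initial transpiration 1–2.6 kg tree⁻¹ day⁻¹, a sustained
  fall below 10% of the initial value on day ~15, drought shedding
  triggered at ~51% conductance loss. A consequence of the Campbell power
  law is a steep dry-end dΨ/dθ, so end-of-run soil water sits near
  θ ≈ 0.19 rather than the ~0.1 a real substrate with residual water would
  show; see Limitations.
* **Soil water driver**: the truth run's own bucket trajectory (coupled,
  mass-closed), so prescribed-SWC calibration is exactly self-consistent
  with the generating model.
* **Observations**: daily transpiration + iid N(0, 0.1 kg) noise; weekly
  shed-fraction collections with 10% lognormal mass noise; five
  vulnerability curves at 0.5 MPa spacing with per-sample parameter
  variation (σ_Ψ 0.12 MPa, σ_a 0.2) and 3-PLC-point noise; nineteen A/Ci
  curves at C_i ≈ (240, 420, 600, 780, 900) μmol mol⁻¹ — C_i/C_a rising
  from ~0.6 to ~0.75 along the five C_a steps, as in real gas exchange —
  with ~9% per-tree capacity variation and 0.3 μmol m⁻² s⁻¹ noise.

What the generator does **not** emulate: sensor physics (heat-balance sap
flow drift, SWC probe recalibration), between-tree variance in the
transpiration mean (observations are one noisy series, not six trees),
weather regimes beyond the smooth diurnal envelope, and any soil
evaporation. Passing tests therefore demonstrate internal consistency of
the full analysis chain under realistic magnitudes — not that the model
would fit any particular real greenhouse record.

## A/Ci fitting

Per-curve maximum likelihood over uniform supports (V_cmax,25 ∈ [10, 80],
J_max,25 ∈ [30, 140]) with R_d tied to V_cmax. Because the tied R_d opens a
broad shallow ridge (large V_cmax mimicked by J_max and R_d adjustments)
beside the narrow true basin, differential evolution alone can settle on
the ridge; the fit therefore also polishes locally from a data-informed
start (V_cmax from the lowest-C_i point under Rubisco limitation, J_max
from the most CO₂-saturated point) and keeps the lower-SSE solution. On the
19-curve reference population the estimated medians recover the generating
medians within 5% and the median J/V ratio is ~1.6.

## Scenario ensembles and the shedding benefit

Three 54-day bucket-mode scenarios: (1) Hydraulic posterior + observed
leaf-area decline; (2) Hydraulic+NSL posterior, constant leaf area;
(3) Hydraulic+NSL posterior + observed decline. Each is 500 independent
posterior draws; reported are daily medians and 95% bands of PLk_rc,
transpiration and leaf area. The shedding benefit is the running mean of
the daily no-shed minus shed PLk_rc difference; for the g_min sensitivity
(2 vs 3 mmol m⁻² s⁻¹, shed vs constant, 2×2) the shed and no-shed
ensembles are sampled independently, per-day distributions are compared
with a two-sample KS test at α = 0.05, and the onset day is the first day
whose benefit 2.5th percentile exceeds zero. With honest posterior spread
(~±4 pp between draws) against a ~1 pp median benefit, the onset criterion
does not fire in the reference study — the distribution-level orderings
(higher benefit and earlier KS separation at g_min = 3) are the robust
findings.

## Limitations

* The scaled-down scenario contrasts are larger than the original study's
  (end-of-run Hydraulic-minus-NSL ≈ 13–15 pp rather than ~6): the Campbell
  retention has no residual-water tail, so the ~2–3 kg of extra mid-phase
  extraction by the no-NSL configuration converts to ~1 MPa of extra
  end-of-run soil-potential decline. A retention with a shallow dry end and
  steep mid-range (e.g., van Genuchten) cannot be expressed in the Campbell
  form this model family specifies.
* The closed-form stomatal optimum is first-order accurate under the
  implemented cost convention (see above); simulated g_s is exact only in
  the log-linear vulnerability limit.
* The engine treats conductance losses as instantaneously reversible with
  Ψ (no embolism hysteresis or refilling dynamics) and ignores plant
  capacitance, so sub-daily potential dynamics are schematic.
* Numerical guards: soil water floored at 0.01 m³ m⁻³ in bucket mode
  (never reached in the reference runs); ξ capped at 100 mol m⁻² s⁻¹;
  k_sr floored at 10⁻¹² to keep the lagged division finite; C_i clipped to
  [1, 4·C_a] inside the fixed point.
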