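# Methods

## The model

Roasting is represented as a closed chemical system of 13 mass fractions
(%w/w on a dry-weight basis): caffeine (CF), tartaric acid (TA), acetic acid
(AA), citric acid (CA), trigonelline (TR), the pooled chlorogenic acids
(CGA = 3-CGA + 5-CGA + 3,5-diCGA), ferulic acid (FA), lipids (LP), sucrose
(SUC), fructose (FRU), glucose (GLC), free amino acids (FAM), and a sink OTH
holding everything not individually tracked. Fifteen reaction channels connect
them:

* first-order thermal losses into OTH for CF, TA, CA, TR and FA;
* sucrose inversion SUC → FRU and SUC → GLC;
* the lumped phenolic pathway CGA → FA;
* caramelisation of FRU and GLC (first-order losses into OTH);
* Maillard channels FRU + FAM and GLC + FAM into OTH, and the acetic-acid
  forming variants FRU + FAM → 2 AA and GLC + FAM → 2 AA;
* the Strecker channel LP + FAM → OTH.

Concentrations are mass fractions, so a bimolecular channel consumes one mass
unit of each precursor and produces **two** units of product; the factor 2 is
mass bookkeeping, not molar stoichiometry. Every column of the 13×15 signed
coefficient matrix sums to zero, hence d/dt Σc = 0 structurally and the total
mass stays at 100 %w/w for all parameter values — the integration error
against this invariant is the solver diagnostic reported per run.

Rate constants follow the Arrhenius law in reference form,
k_i(T) = k_ref,i · exp[−(E_a,i/R)(1/T − 1/T_ref)], with R = 8.314×10⁻³
kJ/(mol·K). The algebraically equivalent pre-exponential form
α_i = k_ref,i · exp(E_a,i/(R·T_ref)) is available but the reference form is
used throughout because it decorrelates the two parameters per channel and
keeps both on interpretable scales.

## Reference temperature

T_ref is the temperature at which the fitted k_ref are quoted and at which the
admissible bounds (below) bite. The package anchors T_ref at the roast's
**yellow-phase marker temperature** (onset of the main reactive phase;
423–429 K for the packaged roasts), one anchor per batch, overridable through
`T_ref=` / `--tref`. Two reasons:

1. Internal consistency: forward-simulating the packaged calibrated parameter
   sets against the packaged measurements pins the anchor — the five
   structurally decoupled first-order species (CF, TA, CA, TR, CGA) each
   independently imply the same T_ref per roast to within 0.01 K, and it is
   the yellow-phase temperature in every case.
2. Feasibility: anchoring much hotter (e.g. at 473 K) rescales the admissible
   k_ref boxes so that the late-roast ferulic-acid turnover saturates its
   bound and the measured FA endpoint becomes unreachable; the yellow-phase
   anchor leaves the optimum of every packaged roast inside the box.

## Temperature profile

The roaster log gives five markers: charge, turning point, yellow phase,
first crack, drop. The charge reading is drum temperature, so the bean profile
T_b(t) interpolates the assumed ambient start (25 °C at t = 0) together with
the four bean markers using monotone shape-preserving piecewise cubic Hermite
interpolation (pchip). On monotone node temperatures this is C¹,
non-decreasing and never overshoots the node range. No thermocouple lag or
heat-transfer model is included: the thermal history is prescribed data, and
the calibration acts on kinetic parameters only. The 25 °C start is an
assumption that mainly affects early-time kinetics, where rates are smallest.

## Integration

The initial value problem is integrated with LSODA (ODEPACK): variable-step,
variable-order, with a stiff phase using backward differentiation formulas of
orders 1–5, supplied with the analytic state Jacobian. Defaults rtol = 1e-10,
atol = 1e-12. Non-negativity is enforced by clamping negative state entries to
zero inside the right-hand side before forming reaction fluxes (so integrator
micro-undershoots cannot produce wrong-signed fluxes), plus a post-hoc
assertion that no stored state lies below −10·atol. Dense output is sampled on
a 200-point uniform grid united with the profile nodes, which pins the grid
over which the conservation maximum is taken. On the packaged roasts the
maximum relative mass drift is ~1e-13 %, comfortably inside the 1e-8 % target.

## Calibration

The unknown is θ = (k_ref,1..15, E_a,1..15), bounded by: 0 < k_ref ≤ 0.1 s⁻¹
for the ten first-order channels, 0 < k_ref ≤ 0.001 (%w/w)⁻¹s⁻¹ for the five
second-order channels, and 40 ≤ E_a ≤ 150 kJ/mol for all channels (the span
typical of food-matrix degradation and Maillard chemistry). A strictly
positive floor of 1e-12 replaces the open bound at zero so that logarithmic
sampling stays defined.

Residuals are logarithmic, r_j = log(c_j(τ)/c̄_j(τ)) over the eight measured
species, and the objective is F = ‖r‖². Log residuals are scale-invariant
(the measured species span 4e-3 to 12 %w/w) and approximate relative errors
near a good fit. The minimisation is Levenberg–Marquardt with a forward
finite-difference Jacobian (relative step 1e-6, floored at 1e-3 of the box
width per component; residuals come from an ODE solve, so no analytic
parameter Jacobian is available), with every trial iterate projected
componentwise onto the box, P(θ) = min(max(θ, ℓ), u), before the residual is
evaluated. Stopping: 300 iterations, 5×10⁴ residual evaluations, function
tolerance 1e-10 (relative decrease of F), and step tolerance 1e-10 applied to
the **componentwise scaled** step max_j |δ_j|/max(|θ_j|, 1e-3·width_j). The
scaled form matters: an unscaled norm test is dominated by the E_a components
(scale ~100) and would stop while the k_ref components (scale ~1e-4) are still
converging, which caps the attainable fit quality orders of magnitude short of
the ~1e-10 relative errors the well-posed roasts support.

With 30 unknowns against 8 residuals the problem is underdetermined; the
damping makes each step well-defined, but distinct parameter vectors reach the
same endpoint fit, so fitted θ values are *a* solution, not *the* solution.
The landscape is non-convex, so the local search is restarted from S = 30
starts (default): k_ref components drawn log-uniformly over [max(ℓ, u/10⁶), u]
(rate constants span orders of magnitude), E_a uniformly. The best converged
start wins; ties go to the lowest start index, and a fixed seed makes the
whole procedure reproducible. One full calibration is a few minutes on one
CPU (~10⁴–10⁵ stiff solves of ~1 ms each).

## What the misfits mean

The lipid misfits of the Mexico and Nicaragua roasts are structural, not
numerical. The only lipid sink is the Strecker channel, which consumes equal
masses of LP and FAM, so LP(τ) ≥ LP₀ − FAM₀ for any admissible parameters.
The amino-acid pool must also feed the acetic-acid channels (2 units of AA
per unit of FAM), so at the optimum the pool splits between matching AA and
depressing LP, and the attainable lipid error is pinned slightly above the
brute-force floor (Mexico ≈ 18.2 %, Rwanda ≈ 5.7 %, Nicaragua ≈ 42.3 %). The
same trade-off fixes the small non-zero AA errors. The Indonesia roast's
measured endpoint is reachable exactly, and the calibration drives all eight
errors below 1e-8 %.

## Synthetic data

`generate_synthetic_dataset` forward-simulates a known admissible θ_true on a
real thermal profile and emits the measured-species finals as a dataset,
optionally with multiplicative log-normal noise of given relative sd. At
noise 0 the calibration's global optimum is exactly zero residual, which makes
the generator the oracle for self-consistency testing (F* ≤ 1e-10 must be
reached) — note this validates the *optimiser*, not identifiability: θ is not
recovered uniquely, only the endpoint fit. What the generator does not
emulate: measurement noise structure of the real assays (replicate sds are
carried as metadata only), moisture dynamics, and any intra-roast sampling.
Passing synthetic tests therefore says nothing about model adequacy at
intermediate times, where no measurements exist.

## Numerical conventions and edge cases

* mg/kg → %w/w conversion is the pure factor 10⁴; measurements are taken as
  already dry-basis (no moisture figure exists for the roasted powders, so no
  moisture correction is applied; the choice is isolated in one function).
* Single-valued composition ranges are their own midpoints; OTH is the
  complement to 100 and must stay positive.
* Simulated finals are floored at 1e-300 inside the residual so that a fully
  depleted species yields a large finite residual instead of −∞.
* Measured finals must be strictly positive (log residuals); zero
  measurements are rejected at dataset construction.
* The temperature kernel clamps evaluation to [0, τ] (stiff solvers may probe
  marginally outside the span while stepping).
* Evaluating the profile outside [0, τ] through the public API is an error —
  no extrapolation.

## Problem sizes used in the checks

The test suite and the acceptance script run the full procedure at the study
scale: all four packaged roasts, S = 30 starts, the solver tolerances above.
Self-consistency runs use S = 5 starts, which is enough for several starts to
reach the zero-residual optimum on noise-free data.

## Known limitations

* Fitted parameters are not identifiable (8 residuals, 30 unknowns); only
  endpoint predictions and the structurally pinned quantities are stable
  across seeds.
* Initial states are literature midpoints, not measurements; the sugar/FAM
  block in particular inherits their uncertainty.
* Intermediate-time trajectories are model predictions without experimental
  confirmation.
* No heat/mass transfer inside the bean: the profile is imposed, and effects
  like moisture flash-off at first crack enter only through the markers.
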