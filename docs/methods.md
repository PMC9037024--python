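# Methods

This note documents the models, estimators and numerical choices behind
`cdsorb`, and what the synthetic validation does and does not demonstrate.

## Units and conventions

Temperatures are kelvin throughout; Celsius appears only at I/O boundaries.
Instrument set points are round Celsius values quoted as rounded kelvin
(283 K ≡ 10 °C), so the Kelvin↔Celsius offset is taken as 273 exactly.
Pressures are Pa, loadings mmol per gram of *dry* sorbent (the only basis
consistent with pre-drying the sample), heating rates K min⁻¹, conversion
rates s⁻¹, heat flows mW with endotherms negative.

Every `ln(rate) vs 1/T` regression reports the activation energy as
`|slope|·R` in kJ/mol. Water uptake on β-CD is anti-Arrhenius (the rate
constant falls with temperature), and the magnitude convention is the one
under which the apparent adsorption activation energy is quoted; the signed
slope is retained on the result object so no information is lost.

Saturation vapor pressure uses the Arden Buck correlation over liquid water
(0.01–0.02% against reference values at 283/298/313 K); the latent heat it
implies, `R·T²·d(ln Psat)/dT ≈ 44 kJ/mol` near room temperature, is the
reference point for interpreting isosteric heats.

## Isosteric heat (Clausius–Clapeyron)

At each point of a loading grid, the equilibrium pressure of every isotherm
is interpolated **linearly in ln P against q** (standard DVS practice;
pressures span decades while loadings do not) and ln P is regressed on 1/T.
`Q(q) = −slope·R`, positive for exothermic adsorption. The default grid is
20 evenly spaced points over the common loading range, endpoints excluded;
grid points covered by fewer than two isotherms are dropped with a warning.
Two-temperature fits are exact two-point slopes (R² reported as 1).
The adsorption branch is used by default; hysteresis is quantified
separately as the loading gap q_des − q_ads interpolated on a common
relative-humidity grid, with its trapezoidal integral as a summary area.

## Uptake kinetics and the initial-rate method

The stage rate law `dq/dt = k·P_i·(1 − P_i(q)/P_i)` separates a kinetic term
k·P_i from a thermodynamic driving term that decays as the equilibrium
pressure P_i(q) rises toward the stage set point. Immediately after a
humidity step, P_i(q) still sits near the previous set point, so the initial
slope is k·(P_i − P_{i−1}). The estimator is an unweighted OLS slope over
the **first 10 samples** of the stage ("top 10" convention; `n_points` is a
parameter). Stage constants are `k = rate/(P_i − P_{i−1})`; when a humidity
window is aggregated, the window-mean rate divided by the window-mean
driving force is also reported, since published values are window means.
The Arrhenius regression of the stage constants is unweighted OLS.

**Known bias.** The initial-rate slope is a secant, not a tangent: it
underestimates the t=0 rate by roughly `w/(2τ)` where `w` is the fit-window
duration and `τ` the stage relaxation time (τ ≈ (dq/dP)/k, ~15 min at 283 K
and ~3 min at 313 K under the default conditions). The synthetic defaults
sample at dt = 0.05 min (3-s DVS sampling), which keeps per-stage recovery
within ~5%; because the bias grows with temperature, the demo pipeline's
recovered adsorption E_a (~8.7 kJ/mol) sits above the value implied by its
generating constants (7.4). The suite contains a convergence test showing
the recovered E_a approaches the truth as dt → 0.

## TG analysis and Friedman isoconversional kinetics

Water content is `(m0 − m_final)/m0` with m0 the first sample (or the mean
over a configurable reference window) and m_final a short tail mean. The
end temperature is where the trace enters its dry plateau: all later masses
within `plateau_tol` (default 0.1%) of the final mass, evaluated on a
7-sample moving average so balance noise comparable to the tolerance cannot
defer detection to the end of the run; a run that never plateaus is an
error. The hydration stoichiometry is `n = (w/(1−w))·(M_βCD/M_water)` with
M_water = 18.02 and M_βCD = 1135 g/mol.

Conversion is `α = (m0 − m)/(m0 − m∞)`, clipped to [0,1] and made
non-decreasing. Derivatives (dα/dT and DTG curves) use a Savitzky–Golay
filter — local quadratic over an odd window, default 11 samples — because
raw finite differences amplify noise; `dα/dt = (β/60)·dα/dT`.

The Friedman estimator interpolates each curve at fixed α (linearly in T,
linearly in ln dα/dt between bracketing samples) and regresses ln(dα/dt) on
1/T across heating rates; `E(α) = |slope|·R`, with the intercept ln[A·f(α)]
and per-α R² reported. It is differential and model-free; integral methods
(Kissinger–Akahira–Sunose, Ozawa–Flynn–Wall) are out of scope. Curves that
do not reach a conversion level are excluded at that level with a warning;
levels left with fewer than two curves are dropped.

## DSC enthalpy

The pipeline is linear-baseline subtraction → trapezoidal integration of
|heat flow| over time (dt = dT/β) → division by sample mass (J/g) →
conversion to kJ per mol water via the TG water fraction.

Baseline handling distinguishes two situations:

* **A pre-event plateau exists.** The default anchors bracket the detected
  event (onset/offset where the residual against a provisional edge-to-edge
  line exceeds 3× the quiet-edge noise SD, floored at 0.1% of the peak), and
  the baseline is the straight line through the trace at the anchors. Anchor
  values are means over symmetric 11-sample neighborhoods, which damps point
  noise and keeps the correction exactly idempotent on a uniform grid.
* **The event is already active at the start of the ramp** — the usual case
  for ambient-hydrated β-CD, whose dehydration endotherm has no cold-side
  plateau inside a 303–473 K program. A bracketing line anchored at the
  first sample would clip the active cold tail (several percent of the
  peak). Instead the linear instrument baseline is estimated by iterative
  asymmetric clipping: fit a line, discard samples far *below* it (the
  endotherm is one-sided), refit until stable, seeding the inlier set with
  the detected post-event plateau. This uses every quiet sample at both
  ends and the whole trace is integrated.

Explicit anchors always take the plain two-anchor path. Sigmoidal baselines
and overlapping-event deconvolution are out of scope.

## The synthetic-data generator

The generator defines the study conditions: isotherms at 283/298/313 K over
5–95% RH, uptake staircases of 10% RH steps, and TG/DSC ramps over
303–473 K at 5/10/15/20 K min⁻¹ on a ~10 mg sample with 12.0% water.

* **Isotherms** follow a GAB model `q = q_m·c·k·x/((1−kx)(1+(c−1)kx))` with
  a van't Hoff energy constant `c(T) = c0·exp(Q_c·1000/RT)`. With c < 1 the
  shape is type III (convex), as observed for water on β-CD. Defaults
  (q_m = 6 mmol/g, c0 = 0.053, Q_c = 5 kJ/mol, k = 0.75) give c(298) ≈ 0.40,
  loadings of a few mmol/g at mid humidity, and a built-in isosteric heat in
  the mid-40s kJ/mol — the physisorption-plus-hydrogen-bonding regime. The
  built-in heat has a closed analytic form (implicit differentiation of the
  GAB relation plus the Buck latent heat), which is the oracle for the
  recovery tests. Hysteresis is a phenomenological ≥1 multiplier on the
  desorption branch; no pore or cavity model is implied.
* **Uptake traces** integrate the stage rate law with `P_i(q)` from the
  closed-form GAB inversion (the stable root of its quadratic), using an
  adaptive Runge–Kutta integrator at tight tolerance.
* **TG ramps** use single-event first-order Arrhenius kinetics
  `dα/dt = A·e^{−E/RT}(1−α)`; α along the ramp is computed from the exact
  exponential-integral form with refined-grid quadrature (verified against
  a brute-force Euler oracle). Defaults E = 55 kJ/mol, ln A = 12.637 s⁻¹:
  E sits at the top of the activation-energy band observed for β-CD
  dehydration — the onset tail of a first-order event is controlled by E,
  and this choice keeps the event contained inside the 303–473 K program at
  all four heating rates — while ln A pins the 5 K min⁻¹ DTG peak at 365 K,
  from which the 10/15/20 K min⁻¹ peaks follow at 378/386/392 K. A mid-band
  parameterization (E = 45) is exercised separately in the tests. The
  estimator never assumes first-order kinetics, which is what makes
  recovery of E a meaningful model-free check.
* **DSC traces** release heat proportional to the instantaneous molar water
  desorption rate (endotherm negative, peak co-located with the DTG peak),
  plus a linear baseline drift and Gaussian noise. Noise magnitudes default
  to zero; the "realistic" preset (0.02 mW/K drift, 0.03 mW heat-flow noise,
  3 µg balance noise) represents a well-behaved heat-flux DSC.

All generators take an explicit seed; identical seeds reproduce traces
bit-for-bit, and the report pipeline derives per-stage sub-seeds from a
single config seed so whole runs are byte-deterministic.

**What recovery does not show.** The synthetic traces share the estimators'
structural assumptions up to the points deliberately broken (model-free
Friedman vs first-order truth; interpolation vs closed-form isotherms).
Passing recovery therefore validates the estimator implementations and their
noise robustness, not the adequacy of GAB or first-order kinetics for any
particular real sample; real β-CD dehydration is narrower than a first-order
event of matching peak temperature, and real instrument baselines need not
be linear.

## Degenerate inputs and tie-breaks

Flat rate sets fit with zero slope and R² reported as 1 (no residual);
two-point regressions likewise report R² = 1. Equal DTG maxima resolve to
the lowest temperature with a warning. A constant-mass thermogram has
w = 0 and T_end at the first sample; conversion is undefined and an error.
Loadings outside an isotherm's measured range raise rather than extrapolate.
Negative initial-rate slopes are returned as-is with a warning. File
validation reports the offending row and line number for non-monotone
temperature or time columns.

## Problem sizes

The default validation suite uses 19-point isotherms at 3 temperatures,
uptake staircases of 6–9 stages sampled at 3-s intervals, and TG/DSC ramps
of ~500–2000 samples at 4 heating rates; these sizes resolve every feature
the estimators rely on (initial-rate windows, DTG peaks, conversion grids)
while keeping a full pipeline run to a few seconds.
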