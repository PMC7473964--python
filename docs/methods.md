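# Methods

## Models

### Two-compartment disposition

Plasma kinetics follow a linear two-compartment model parameterized by
clearance `CL` (L/h/kg), central volume `V` (L/kg), distribution clearance
`CL2` (L/h/kg) and peripheral volume `V2` (L/kg). The hybrid constants are
the roots of `s² − (k10+k12+k21)s + k10·k21` with `k10 = CL/V`,
`k12 = CL2/V`, `k21 = CL2/V2`; `β` is computed from `α` via the Vieta
product to avoid cancellation. Every dosing event contributes a sum of
`c·(t−t0)^p·e^{−λ(t−t0)}` terms:

* IV bolus: biexponential with unit-dose coefficients
  `A = (α−k21)/(V(α−β))`, `B = (k21−β)/(V(α−β))`, so `Cp(0⁺) = D/V`;
* constant-rate infusion: the time-shifted integral of the bolus response
  (an infusion switched on at `t0` minus one switched on at `t0+T`);
* extravascular (SC) dose: flip-flop triexponential with absorption rate
  `ka` and bioavailable fraction `F`.

Solutions superpose exactly across events, so concentrations are linear in
dose by construction.

### Effect site and response

The biophase concentration obeys `dCe/dt = ke0·(Cp − Ce)` with `Ce(0)=0`.
Because `Cp` is a sum of polynomial-times-exponential terms, `Ce` is
obtained by exact convolution with the `ke0·e^{−ke0 t}` kernel, term by
term. The response is the hyperbolic Emax model
`E = E0 + Emax·Ce/(EC50 + Ce)` with `E0 = 0` and `Emax = 100 %` fixed —
percent inhibition of an odor-evoked imaging response (or of a nociceptive
withdrawal score) saturates at complete block, and baselines are
normalized to zero by the percent-inhibition endpoint itself.

**Coinciding rates.** When two exponential rates agree to within a
relative 1e−9 (`ka` hitting a disposition exponent, or `ke0` hitting any
plasma rate), the generic partial-fraction coefficients blow up; the code
switches to the analytic resonant limit, which raises the polynomial
order: `c·t^p e^{−λt} → c·ke0·t^{p+1}/(p+1)·e^{−ke0 t}`. The convolution
handles arbitrary polynomial order by recursion, so even double
coincidences evaluate finitely.

## Fitting

All fits are *naive-pooled*: observations from all animals and dose groups
are stacked and fitted as one subject. This deliberately replaces the
mixed-effects (FOCE) estimation used with commercial software in the
original workflow — only population-level parameter values feed the
downstream translation steps, and the pooled objective keeps the fits
dependency-free and fast. Consequences: between-animal variability is
absorbed into the residual, so residual SDs overstate assay noise and
parameter SEs are approximate (they are still useful as a relative
confidence screen, which is how the CV% filter consumes them).

* **In vitro 4PL** (`fit_ic50_4pl`): asymptotes fixed at 0/100, `IC50` and
  Hill slope fitted on the log scale. A warning (and `converged=False`) is
  raised when the data never cross 50 % inhibition, since the IC50 is then
  an extrapolation.
* **PK** (`fit_pk_naive_pooled`): sum of squared *log* residuals
  (log-additive error; concentrations span decades and errors are
  multiplicative). Observations must be positive — below-quantification
  values are removed upstream (pipeline default LLOQ 1e−4 µM).
* **Effect compartment** (`fit_effect_compartment`): additive error on the
  percent scale, PK fixed per study, free parameters `EC50` and `ke0` on
  the log scale. No transform is applied to percent inhibition, and
  noise-driven negative observations are kept: the additive-error model
  expects them, and discarding them would bias low-effect dose groups.
* **Pooled exposure-response** (`fit_pooled_emax`): one free parameter,
  the dimensionless `EC50` (scaling factor), additive error, fitted on
  individual-animal points (group means are for plotting only).

**Optimization.** Derivative-based least squares (`scipy.optimize.
least_squares`, ftol 1e−8) seeded by a multi-start: candidate start points
on a 5-point log grid per free parameter are scored by objective value and
the best three are polished locally. Standard errors come from
`s²·(JᵀJ)⁻¹` at the optimum with `s²` the residual variance;
`CV% = 100·SE/|estimate|` exactly. Log-scale SEs are mapped to the natural
scale by the delta method (`SE = SE_log · estimate`).

## IVIVC

Unbound in vivo potency is `EC50 · fu,p`. Compounds enter the correlation
only if both `EC50` and `ke0` CV% are ≤ 50 — the comparison is inclusive
so that a CV printed exactly at the threshold (a value just under 50
before rounding) passes; applied to the published fit table this retains
exactly the 7 reported compounds. The regression of unbound in vivo EC50
on in vitro IC50 defaults to log10–log10 space (potencies span more than a
decade and errors are multiplicative; linear space is available by flag).
Slope SE, R² and the two-sided t-test p value are standard OLS. The
published regression numbers themselves (slope 1.057, R² 0.7831) derive
from unrounded fitted estimates and are not recomputable from rounded
table values; the package instead verifies the *property* they express —
unity slope on panels generated with unbound EC50 ≡ IC50.

## Simulation

Trajectories are evaluated analytically on a dense grid (default step
1e−3 h) and peaks located by grid argmax plus bounded local refinement —
robust for multi-event regimens where derivative root-finding is awkward.
The effect-peak delay `tmax(Ce) − tmax(Cp)` decreases in `ke0`; under the
default PK and SC absorption assumptions, the published range of `ke0`
values (0.55–3.74 1/h) produces delays on the 0.3–1.5 h scale, matching
the hour-scale hysteresis seen in vivo.

PK-prediction qualification compares simulated plasma against sparse
observed means by per-time fold error `max(sim/obs, obs/sim)`, with the
simulated curve interpolated linearly in *log* concentration (profiles are
piecewise-exponential). The pass boundary is inclusive: exactly 2-fold
passes. Zero observed concentrations cannot define a fold error and are
excluded with a warning.

SC projections assume first-order absorption with `ka = 1 h⁻¹` (times in
this workflow are in hours) and complete bioavailability, per the
absorption behavior of the chemical series; the recommended single
sampling time is the effect-site tmax, where a one-sample design has
maximal power to see the peak effect.

## Synthetic data: what it emulates and what it does not

Generators reproduce the *designs* of the source studies:

* in vitro: 10 log-spaced concentrations bracketing the IC50, additive
  Gaussian noise (default SD 5 %);
* satellite PK: IV bolus, 9 samples from 2 min to 24 h, per-animal
  parameters lognormal around the population truth (default CV 30 %),
  multiplicative residual (default CV 20 %);
* olfaction imaging: 1 h baseline, loading bolus + 1 h infusion (bolus
  `Css·V`, rate `Css·CL`, `Css = dose/(V + CL·T)` — the split that holds
  plasma near-flat, which the source design assumed but never printed),
  percent inhibition every 0.2 h (triple-averaged 4-min measurements; 5
  baseline, 5 on-infusion, 5 per washout hour, default washout 2 h), two
  plasma samples (end of infusion, end of study); PD noise additive
  (default SD 8 %);
* thermode: SC dose groups plus vehicle, single readout at the projected
  effect-site tmax, withdrawal scores scaled down from a baseline score of
  1.5 (0–2 scale) in proportion to the predicted effect;
* compound panels: IC50 lognormal over ~2 decades (0.1–20 µM scale),
  fu,p logit-normal around ~0.08, true total EC50 =
  `ratio · IC50 / fu,p · (lognormal dispersion)`, ke0 lognormal around
  1.3 h⁻¹.

Noise magnitudes are assumptions — the source studies publish none — and
are configurable; the defaults above were chosen once as plausible for
patch-clamp, LC-MS bioanalysis and imaging endpoints respectively.
Animal-level *PD* variability (random EC50/ke0 per animal) is supported in
principle but defaults off, matching the naive-pooled estimator, which
cannot attribute it anyway. The generators start at the
percent-inhibition endpoint: voxel time courses, anesthesia effects,
odor-delivery physiology and assay drift are outside the model, so
passing recovery tests demonstrates statistical identifiability under the
stated designs, not robustness to those real-world effects.

Default PK truth where a study needs one: `CL = 0.5`, `V = 0.5`,
`CL2 = 0.3`, `V2 = 1.0` (terminal half-life ≈ 2.7 h) — typical rhesus
small-molecule disposition; the source studies print no PK parameter
values. With the 1-h loading regimen this gives `Css` numerically equal to
the dose in µmol/kg, which keeps worked examples legible.

## Problem sizes and numerical choices

* Multi-dose imaging recovery uses the published compound-24 design
  (15 animals, 20 observations each); the single-dose design uses 3
  animals. Under these designs and default noise, EC50 recovers to within
  a few percent (multi-dose) and `ke0` to ~10 % (multi-dose) — but `ke0`
  from a *single* dose group is weakly identified (the published
  single-dose fit itself reports a 31 % CV), so no tight recovery claim is
  made for it.
* The pooled scaling-factor dataset uses 27 compounds × 1–3 dose groups ×
  3 animals (~160 points), exposures log-uniform over 0.1–100 normalized
  units, within-group exposure scatter CV 25 %.
* End-to-end panel recovery (generate → fit PK → fit PD → IVIVC) runs 7
  compounds with reduced group sizes (2 animals/group) across 10 seeds in
  the test suite; slope convergence to unity is assessed on the mean.
* Oracle comparisons integrate the ODE system with `solve_ivp` at rtol
  1e−11 and assert agreement at rtol 1e−6 with an absolute floor of 1e−6
  of the profile maximum.
* Ties/degenerate inputs: zero-amount events contribute nothing; empty
  regimens, non-positive parameters, unordered times, out-of-range fu,p
  and unknown CSV vocabulary all fail fast with named errors.

## Known limitations

* Naive-pooled SEs understate design effects (repeated measures per
  animal); CV% values are a screening heuristic, not inferential
  statements.
* Linear kinetics only — no saturable clearance, no three-compartment
  disposition, no inter-occasion variability.
* The effect-site model is empirical: `ke0` aggregates every source of
  delay (tissue distribution, binding kinetics) into one rate, and its
  value need not transfer across effect sites (olfactory epithelium vs
  peripheral nerve).
* The pooled single-timepoint analysis is biased high when hysteresis is
  present (the mean on-infusion effect lags the concurrent exposure);
  that bias is reproduced, not corrected, by this package — it is the
  reason the staged workflow graduates compounds to the
  effect-compartment model.
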