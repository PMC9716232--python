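# Methods

This note documents the models, default parameters and design choices behind
`fhces`: what the pipeline computes, what the synthetic-data generator
emulates, and where the genuinely open decisions were made.

## Readout models

**C3b binding (SPR).** Traces follow the 1:1 Langmuir model. During
association at analyte concentration C,
R(t) = R_eq·(1 − e^{−(k_a·C + k_d)t}) with R_eq = R_max·C/(C + K_D) and
K_D = k_d/k_a; after the injection stops, R decays at k_d. The binding
readout is the mean response over a trailing 5-s window ending at t_eq =
220 s (a window mean rather than a single sample, for noise robustness; the
window is configurable and `window=0` reduces to a point read). The
component entering the score is the variant/control ratio of this readout.
Traces are assumed reference-subtracted; an optional pre-injection
baseline-zeroing step (mean of the 10 s before injection) is provided. No
bulk-shift or drift correction is attempted, and only the 1:1 model is
supported — no heterogeneous-ligand or mass-transport-limited variants.

**Decay accelerating activity (SPR).** Convertase decay is modeled as
R(t) = R₀·e^{−(k_i + m·k_f)t}, where k_i is the inherent C3bBb decay rate,
k_f the FH-attributable rate added by the control protein, and m the
variant's rate multiplier (m = 1 control-like, m = 0 inactive). The readout
is the FH-attributable response loss at t = 175 s,
ΔR = R_intrinsic(175) − R_FH(175), i.e. the decay beyond what the convertase
does on its own; the component is the variant/control ratio of ΔR, which
runs from 1 (control-like) down to 0 (no decay acceleration). Defining the
readout relative to the inherent-decay trace keeps this orientation; a raw
response ratio would invert it. Note ΔR is nonlinear in m:
ratio(m) = (1 − e^{−m·k_f·T})/(1 − e^{−k_f·T}), which tends to m only as
k_f·T → 0. `expected_daa_ratio` / `daa_mult_from_ratio` give this mapping
and its exact inverse, and recovery tests compare against the exact mapping
rather than pretending the readout is linear.

**Dose–response assays (4PL).** Curves are fit with the four-parameter
logistic y = y₀ + (y_inf − y₀)/(1 + (EC50/x)^h), h > 0, where y₀ is the
zero-dose plateau; decreasing curves (AP immunoassay, hemolysis) swap the
plateau roles rather than flipping the hill sign, keeping h > 0 invariant.
Replicates enter the fit as individual points (preserving the triplicate
error structure); least squares is unweighted, with no 5PL asymmetry and no
outlier rejection. Initialization is deterministic — plateaus from the
min/max of dose-mean responses, EC50 from the dose nearest the half-span
crossing, h = 1 — so fits are reproducible. A fit whose EC50 falls outside
[min_conc/10, max_conc·10], or that fails to converge, is flagged
unreliable; unreliable EC50s propagate as missing score components (strict
mode errors; partial mode renormalizes 100/k over the k available
components and flags the result). For the AP assay, EC50s are taken by
interpolating the fitted curve at 50% inhibition; by default the 50% level
is defined on the control's fitted span (shared-plateau mode) and located
on each curve by closed-form inversion, with a per-curve mode available.
Cofactor and AP components are control/variant EC50 ratios, so < 1 means
the variant needs more protein for half-maximal effect.

**Hemolysis ternary rule.** Because between-day variability makes hemolysis
EC50s unreliable, the assay contributes a three-way call. The quantitative
rule (the published analysis states only severe/marginal/negligible):
protection is the drop from the no-FH lysis level (control zero-dose
plateau) to a curve's high-dose plateau. A variant is *negligible* (score
1) if its maximal protection is ≥ 90% of the control's **and** its
control/variant EC50 ratio is ≥ 0.75; *severe* (score 0) if protection is
< 50% of the control's **or** the variant enhances lysis above the no-FH
level (> 5% tolerance, the Gly1194Asp-type behavior); *marginal* (0.5)
otherwise. A control suppressing less than 10% of lysis is rejected as
carrying no signal. All thresholds are configurable; the rule is monotone —
degrading a curve never raises the score.

**Kinetic confirmation.** `fit_langmuir` fits k_a, k_d, R_max globally over
≥ 3 traces at distinct concentrations (both phases), in log space for
positivity, with deterministic linearized initial estimates (k_d from the
dissociation tail log-slope, k_obs-versus-C regression for k_a). Degenerate
input yields a failure report, never a crash.

## The score

CES = 100/6 × (binding_vc + CA_cv + DAA_vc + AP_cv + yield_vc + hemolysis).
The yield component is the variant/control ratio — orienting it
control/variant would reward poor secretion, and the published yield range
(0.26–1.3, variant over control) fixes the direction. Components above 1
are not capped (the observed minimal-impact group extends above 100, which
capping would forbid). Classification: > 84 minimal impact, < 75 defective,
both boundaries inclusive to marginal (the published rules are strict
inequalities). Ranks ascend from the lowest CES; ties break
lexicographically by variant name. The pipeline floors measured binding and
DAA ratios at zero: a negative FH-attributable decay is measurement noise
with no physical meaning. Cross-assay concordance uses Spearman rank
correlation over the five continuous components by default (the ternary
hemolysis score is excluded; Pearson is available); a constant column is
reported as undefined (NaN), never zero. No differential assay weighting
and no uncertainty propagation into CES intervals are offered — the score
is a point summary by construction.

## What the generator emulates

`simulate_variant_panel` produces, per protein: a binding sensorgram (1:1
kinetics, variant R_max scaled by `binding_mult`), an FH-decay sensorgram
(rate scaled by `daa_mult`) plus one shared inherent-decay trace, three
dose–response tables (cofactor increasing, AP and hemolysis decreasing,
EC50s scaled by the respective multipliers, hemolysis distorted by class),
and a log-normal yield. Noise is additive Gaussian and homoscedastic per
assay — the simplest model consistent with symmetric triplicate error bars.
Per-protein sub-seeds derive deterministically from one master seed
(`numpy.random.SeedSequence`), so identical calls are byte-identical.

Default study conditions: 250 nM injections, association 220 s /
dissociation 60 s, decay window 200 s read at 175 s, dt = 1 s; control
kinetics k_a = 1e5 M⁻¹s⁻¹, k_d = 1e-2 s⁻¹ (K_D = 100 nM), R_max = 120 RU;
decay R₀ = 100 RU, k_i = 8e-4 s⁻¹ (inherent half-life ≈ 14 min), k_f =
ln2/175 s⁻¹ (control FH halves the remaining convertase signal over the
readout window); sensorgram noise 1 RU; triplicate dose–response noise at
3% of curve span; control yield 83 mg/L with log-normal sigma 0.10 chosen
as a realistic repeat-production spread (the original yield comparison was
a single run, so no empirical variance exists to calibrate against).
Concentration grids are log-spaced and deliberately wider than a single
figure's plotting window — cofactor 0.01–10 µM, AP 0.02–100 µM, hemolysis
0.01–10 µM — because variants shifted 14-fold (cofactor) or 100-fold (AP)
in EC50 are unidentifiable on a grid that brackets only the control's
curve; any assay that produced such ratios must have covered the shifted
curves. Hemolysis classes map to curve distortions: negligible = control
curve, marginal = EC50 shifted twofold right, severe = protection plateau
reduced to 40% of the control's.

The default 21-variant truth table (`DEFAULT_TARGET_RATIOS`) is a
**synthetic reconstruction**, not deposited data: per-assay target ratios
were chosen once to honor the published per-assay extremes (binding
0.65–1.27, DAA 0.08–1.01, cofactor 0.07–1.13, AP 0.01–1.05, yield
0.26–1.3), each variant's qualitative per-assay impact calls, and the
published group structure — 10 minimal-impact / 3 marginal / 8 defective,
the defective eight in the published decreasing-CES order, minimal-group
scores within 86–104, and the yield-omission swap in which Arg1210Cys
leaves the bottom eight and Arg303Gln enters. Passing tests on this panel
show the pipeline recovers what the generator encodes under the stated
noise model; they do not validate the assays against laboratory data, and
the generator deliberately omits instrument artifacts (bulk refractive
index jumps, drift, regeneration effects), day effects, and any mechanistic
ODE model of the AP cascade — readouts are phenomenological.

## Numerical choices

Fits use tight tolerances (xtol/ftol/gtol = 1e-14) so that zero-noise
self-fits recover parameters to ~1e-9 relative error and the end-to-end
zero-noise CES matches the truth mapping to < 1e-6. SPR readouts at grid
times are linear interpolations (exact at sample points with dt = 1 s).
Degenerate inputs fail loudly: non-positive controls raise, flat Langmuir
traces return a non-converged report, hemolysis scoring falls back to
empirical high-dose plateaus when a variant curve cannot be fit (a flat
severe curve must still score 0). Duplicate injections are averaged at the
readout-statistic level, not the trace level.

## Problem sizes used in the test suite

Unit tests run on single curves/traces; the recovery suites use 200 seeded
replicates for EC50 and K_D error distributions and 100 seeded 21-variant
panels for rank-recovery (Spearman between recovered and truth-derived CES
rankings), sizes at which the suite completes in a few minutes on one core
while the medians are stable to well under the tolerances tested.

## Known limitations

* The CES treats components as exchangeable; a variant defective in one
  assay but normal elsewhere can score like one mildly impaired everywhere.
* The hemolysis rule thresholds (90% / 75% / 50% / 5% / 10%) are the
  package's own quantitative rendering of a qualitative three-way call.
* The yield component inherits single-run uncertainty; the yield-omitted
  CES exists precisely to expose its influence.
* Synthetic panels cannot detect assay-specific systematic errors (matrix
  effects, surface decay between cycles) that real instruments exhibit.
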