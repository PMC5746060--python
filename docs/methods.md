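# Methods

This note documents the kinetic models implemented in `slowbind`, the
choices made where the underlying experimental reports leave details open,
and what the synthetic-data generator does and does not emulate.

## Units

Fixed throughout: time in minutes, inhibitor and enzyme in nM, substrate in
μM, signal in arbitrary fluorescence units (AU). The single internal
conversion (nM ↔ μM) is the constant `NM_PER_UM`; no unit inference is ever
performed on input tables.

## Kinetic scheme and parameterization

A scheme is parameterized by the true inhibitory constant `Ki` and the
dissociation rate `koff`, with `kon = koff/Ki` derived. This choice is
deliberate: published tables for the ketoamide series report a kon column
that is internally inconsistent with `Ki = koff/kon` by roughly a factor of
ten (a suspected units error), whereas the Ki and koff columns agree with
the progress-curve analysis. `(Ki, koff)` are therefore authoritative and
kon is never taken from the table.

Substrate binding is treated as rapid equilibrium relative to inhibitor
binding (the ES fraction is `S/(Km+S)` instantaneously). This is justified
by the very low inhibitor association/dissociation rates that produce the
slow-binding phenotype in the first place; it removes the unknown substrate
on/off rates from the model entirely.

The modality enters in two places:

* the steady-state denominator (competitive `Km(1+I/Ki)+S`, pure
  noncompetitive `(Km+S)(1+I/Ki)`, uncompetitive `Km+S(1+I/Ki)`, mixed
  `Km(1+I/Ki)+S(1+I/(αKi))`);
* the apparent association rate `kon_eff` governing kobs. For mixed
  inhibition we use `kon_eff = kon·(Km + S/α)/(Km + S)`, which is the
  unique form consistent with `Kiapp(S) = koff/kon_eff` equal to the
  steady-state half-inhibition concentration, and which reduces to the
  competitive (α→∞), noncompetitive (α=1) and — with ES-only binding —
  uncompetitive limits.

Two-step binding (E + I ⇌ EI ⇌ EI\*) reuses `(kon, koff)` as the fast
encounter step, so `Ki1 ≡ koff/kon`, and adds the isomerization rates
`(k5, k6)`; the predicted onset rate is `kobs = k6 + k5·I/(Ki1_eff + I)`
with the same substrate correction applied to `Ki1`.

## Simulators

`closed_form_curve` evaluates the standard biphasic law with
`vi = v(S, I=0)` (a slow binder does not inhibit at time zero),
`vs = v(S, I)` and `kobs` from the scheme. It is valid while substrate
conversion is small; a conversion above 10% raises a warning and sets a
`depletion_warning` flag on the curve. `product_progress` switches to the
exact linear limit below `kobs = 1e-12 min⁻¹` to avoid 0/0.

`ode_curve` integrates the full scheme (LSODA, rtol 1e-9, atol 1e-12 by
default) with explicit substrate and free-inhibitor depletion and optional
EI\* state, and verifies the substrate mass balance `S + P = S0` to 1e-6
relative at every output point. It is the oracle for the closed form (they
agree to <1% under low conversion on the canonical design) and the engine
for preincubation and jump-dilution simulations, where enzyme is at
hundreds of nM and free-inhibitor depletion is no longer negligible.

Preincubation is integrated at S = 0; the resulting bound-enzyme fraction
lowers the initial rate of the subsequent curve (closed form) or sets the
ODE initial condition. For uncompetitive schemes no E·I complex exists at
S = 0, so preincubation has no effect — a real property of that modality.

## Noise and seeding

Noise is Gaussian, `signal·(1+ε_rel)+ε_abs`, i.i.d. per point; this matches
the dominant multiplicative character of plate-reader fluorescence noise
but deliberately omits drift, photobleaching and inner-filter effects.
Per-curve generators are seeded by
`splitmix64(master_seed XOR fnv1a64(curve_id))` — a documented integer mix
so any implementation can reproduce a dataset bit-exactly from
`(scheme, design, noise, seed)`.

Because measured Km/kcat values for the fluorogenic transmembrane-peptide
substrates are not published, the synthetic world fixes `Km = 10 μM` and
`kcat = 0.1 min⁻¹` — a low-μM Km and a slow turnover typical of rhomboid
proteases acting on micelle-solubilized peptide substrates. Parameter-
recovery results are insensitive to both (noise is relative; kobs and Ki
recovery depend on them only through the fixed S/Km ratio of the designs).

## Progress-curve fitting

`fit_progress_curve` minimizes unweighted least squares by default
(mirroring common practice with graphing software); the `weighting=
"relative"` option divides residuals by the signal, the statistically
correct choice under multiplicative noise, and is what the benchmark
pipeline uses. Initialization is curvature-aware (vi from the first 15% of
points, vs from the last 25%, kobs ≈ 3/t_half of the transient) with kobs
bounded to [1e-5, 1e2] min⁻¹. A free additive baseline is fitted by default
and can be fixed.

kobs is only reported when the biphasic model beats the nested straight
line in an extra-sum-of-squares F-test (α = 0.05). This guard exists
because at low [I] the curvature time 1/kobs exceeds the observation
window and the fitted kobs would be noise; such curves are excluded from
the kobs profile with an explicit reason. Exactly linear data (residuals at
numerical precision) short-circuit the F-test.

## kobs–[I] analysis

The linear fit is OLS, or WLS with 1/SE² weights when requested — the
benchmark pipeline weights, because the per-curve kobs standard errors
differ by an order of magnitude across the dilution series and unweighted
regression lets the weakest fits dominate the intercept. `Kiapp = koff/kon`
is computed exactly from the fitted slope and intercept, with its SE by
the delta method using the full coefficient covariance. A negative
intercept beyond 2 SE, or a negligible slope, withholds Kiapp rather than
clamping it.

One- vs two-step selection is by AICc (k = parameters + 1), requiring the
hyperbolic model to win by ΔAICc ≥ 2; ties go to the simpler linear model.
When the simpler model already explains the data to numerical precision
(rss below `n·(1e-7·max|kobs|)²`), AICc differences are meaningless and
the simpler model is selected outright. The same floor logic applies to
modality selection below.

The vi-independence test is an OLS slope t-test of vi against [I]
(α = 0.05); exactly constant vi is reported independent without the
degenerate 0/0 t statistic.

## Modality selection

All four models are fitted globally (shared Vmax, Km, Ki, and α for mixed)
with `scipy.optimize.curve_fit`; α is parameterized as log10(α) bounded to
[−2, 2] to avoid boundary pathologies. The three 3-parameter models compete
by minimum AICc and the 4-parameter mixed model supersedes the winner only
with ΔAICc ≥ 2 — chosen because published characterizations of this inhibitor class
do not state their selection criterion, so a defensible one is fixed and
documented here. Nested F-tests (each simpler model vs mixed) are
reported as secondary evidence, and a mixed fit whose α confidence interval
covers 1 is annotated as consistent with noncompetitive. Replicate SDs can
weight the fit (1/sd²); the default is unweighted.

`ki_from_kiapp` inverts the substrate correction per modality (identity for
noncompetitive; `/(1+S/Km)` competitive; `/(1+Km/S)` uncompetitive;
`·(Km+S/α)/(Km+S)` mixed, returning the free-enzyme constant).
`ic50_from_scheme` provides the matching closed-form steady-state IC50 and
a brentq root-finder cross-check.

## Dose–response and gel quantification

IC50s use the four-parameter logistic on linear concentration; vehicle
(x = 0) rows sit exactly on the top plateau, so no pseudo-log substitution
is needed. The Hill slope is free by default. A transition smaller than
15% of the top plateau, or responses pinned to one plateau, yields a
first-class "above_range"/"below_range" result instead of an extrapolated
number — mirroring how out-of-range potencies are reported in practice
("IC50 > 1 mM").

Band-intensity conversion is `product/(product+substrate)`, normalized to
the vehicle lane; knockout background correction subtracts the matched
knockout product intensity and clamps at zero with a logged warning. ABP
competition is `100·(1 − band/DMSO)`, clamped to [0, 100].

## Jump dilution

The pre-equilibration (high enzyme + inhibitor, no substrate) is always
integrated by ODE because at 0.4 μM enzyme the bound inhibitor measurably
depletes the free pool. After an instantaneous 1/d dilution the bound
fraction is carried over and the recovery curve integrated at the diluted
concentrations. Classification thresholds (recovery ≥ 0.5 reversible,
≤ 0.1 irreversible, otherwise ambiguous, with the topped-up control
required to stay inhibited) are configurable defaults: the published
experiments report only qualitative "partial recovery", so no printed
cutoff exists to adopt.

## What a green test establishes

The generator emulates the published assay designs (concentrations, time
windows, dilution series) under an idealized noise model. Green recovery
tests establish that the estimators are unbiased and correctly calibrated
*for that world*: they do not validate against instrument drift,
pipetting error correlations, inner-filter effects, substrate or enzyme
instability over 2 h, or model misspecification beyond the alternatives
explicitly fitted. Monte-Carlo suite sizes in the default test run are
scaled down (20–100 seeds) to keep the suite fast; medians and selection
rates quoted in tests were checked to be stable at larger sizes.

## Known limitations

* The two-step simulator assumes the encounter step is fast relative to
  isomerization when interpreting `kobs`; strongly overlapping timescales
  produce multi-exponential onsets outside the fitted model family.
* Heteroscedastic noise models beyond signal-proportional are not
  implemented.
* Tight-binding corrections (inhibitor depletion by enzyme at comparable
  concentrations *during the assay*) are handled only by the ODE
  simulator, not by the fitting equations, which assume [I] ≫ [E].
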