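# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real measurements.

## The unfolding scheme

The forward model is a sequential, doubly irreversible variant of the
Lumry–Eyring scheme:

```
N --k1--> N* --k2--> D        k_i(T) = A_i exp(-Ea_i / (R T))
```

N is the native β-barrel in detergent micelles, N\* a kinetically trapped
intermediate, D the aggregated end state. Irreversibility of the *first*
step is the distinguishing assumption: in heat–cool–reheat protocols the
simulator never lets N\* revert to N, so a reheated sample shows only the
slow (aggregation) phase. The high-temperature pseudo-two-state N→D regime
is not a separate scheme; it is the k2 ≫ k1 limit of the same
parameterization, in which the intermediate never accumulates.

Species fractions from a pure-N start have exact closed forms
(f_N = e^(−k1 t); f_N\* = k1(e^(−k1 t) − e^(−k2 t))/(k2 − k1), confluent
limit k1·t·e^(−k1 t)). They are evaluated through the helper
h(a,b,t) = (e^(−at) − e^(−bt))/(b − a), computed as
e^(−min t)·t·exprel(−|b − a| t) so that both the removable singularity at
equal rates and widely separated rates (ratios of 10³ and beyond) are stable.
Everything is verified against an independent stiff ODE integration
(`solve_ivp`, LSODA, rtol 1e−11) to 1e−8 absolute.

## Observables

Signals are linear mixtures of species populations:

* **Ellipticity** ME(t) = me_n·f_N + me_n\*·f_N\* + me_d·f_D. Defaults
  me_n = −9000, me_d = −1000 deg cm² dmol⁻¹ (typical β-barrel CD contrast at
  215 nm). The intermediate retains ≈55% of the native-vs-final contrast
  (me_n\* = −5400): with a fully native-like intermediate the first kinetic
  phase would be spectroscopically invisible, while the two-transition traces
  this model emulates show both phases clearly. The CD-silent case
  (me_n\* = me_n) remains available and is exercised in the tests: it
  reduces the observable decay to a single exponential at k2 after a burn-in.
* **Anisotropy** r(t) = r_n·f_N + r_u·f_N\* + r_d·f_D, with r_n = 0.14,
  r_u = 0.07 and a variant-dependent aggregate value (0.16 wild type, 0.08
  Cys-less), the printed levels for folded, unfolded and aggregated barrel.
  Mixing is linear in species fractions, not intensity-weighted — species
  quantum yields are unknown and anisotropy is used only corroboratively.
  This is an acknowledged approximation.
* **Light scattering** (PMT voltage): suspended aggregate pool
  dA_s/dt = k2·f_N\* − k_settle·A_s, A_s(0) = 0, PMT = s_gain·A_s. This is
  the minimal first-order model producing the observed rise (aggregate
  production) then fall (settling out of the beam). With k_settle = 0 the
  pool equals f_D exactly. The analytic solution is used except in
  near-degenerate rate corners, where the stiff integrator takes over.

Noise is additive Gaussian per channel, with σ expressed as a fraction of
that channel's noiseless dynamic range. Every trace draws from an
independent stream spawned (`SeedSequence`) from a single root seed, so the
entire dataset is bit-reproducible.

## Default study conditions

The study generator emulates a factorial design: two variants (wild type
with nine cysteines; the Cys-less mutant C0) × detergent concentrations
{5, 13, 30, 65, 80, 100} mM LDAO × isothermal temperatures 65–95 °C in 5 °C
steps (84 kinetic traces), plus one 1 °C/min ramp per variant/detergent pair
(12 scans). Defaults: 5 µM protein, 15 min traces at 1 Hz, 2% channel noise.

Rate parameters are anchored at 80 °C: k1(80) per (variant, detergent) takes
the corresponding measured fast rate (e.g. 2.242 min⁻¹ for wild type at
5 mM, falling to 0.316 min⁻¹ at 100 mM); Ea1 is 16.54 kcal/mol for wild
type and 22.64 kcal/mol for the Cys-less mutant — the +6.1 kcal/mol gap is
the cysteine effect the variant comparison recovers. For the low-detergent
(double-phase) regime, k2(80) uses the measured slow rates where available
and 0.12 min⁻¹ otherwise, with Ea2 = 15 kcal/mol (consistent with the weak
temperature trend of the slow rates; not independently measured). The
high-detergent single-exponential regime is produced by k2 ≫ k1
(anchor 50 min⁻¹), not by a separate model. Traces start at t = 0 with no
censoring by default; an optional dead-time argument reproduces the ~30 s
unobserved interval of a real stopped-measurement setup (the analysis side
defaults to trimming 30 s, never extrapolating the unobserved burst).

## Fitting

**Exponential decays.** Time is stored in seconds and converted to minutes
exactly once, at fit time; rates are reported in min⁻¹. The optimizer
(`least_squares`, trust-region reflective) works in log-rate space, which
enforces positivity and makes the multi-start grid scale-free. Rates are
bounded in [1e−6, 1e4] min⁻¹; hitting a bound flags a warning rather than
failing. Starts: the single-rate guess is ln 2 over the observed half-change
time; the double fit starts at (4×, 0.25×), (10×, 0.1×) and (2×, 0.5×) that
guess. Tolerances 1e−12 — far below every assertion in the test suite.
Standard errors come from the Gauss–Newton covariance; log-rate errors are
mapped to rate errors by multiplication with the rate. A double fit whose
rates collapse (ratio < 1.05) degrades to the single fit with a
`rate_collapse` warning.

**Model selection.** The double model is accepted only if it beats the
single model by ≥ 2 AICc units *and* the rates are ≥ 3× apart *and* each
phase carries ≥ 5% of the total amplitude *and* the amplitudes share a sign
(a monotone decay cannot have opposing phases; a mixed-sign "second phase"
is noise chasing). An explicit override reproduces any externally prescribed
single/double assignment. Calibration under the study conditions: across 50
seeded monophasic traces at 2% noise the selector never returns "double";
across 50 biphasic traces at rate ratio 6.6 it returns "double" 47 times.

**Two-state melts.** Greenfield-style van't Hoff sigmoid with linear
baselines and ΔCp = 0 — the minimal model behind a reported Tm. Fitting raw
ellipticity with free baselines is the default; a fixed-baseline mode
freezes them at robust line fits to the outer 20% of points (that mode is
approximate when the baselines hold transition tail). Initialization:
Tm from the steepest point of a 5-point moving-average smoothed signal
(smoothing is used for initialization only; residuals are always on raw
data), ΔH_vH multi-start over {20, 50, 100} kcal/mol. Lowest RSS wins; ties
break to the smaller |ΔH_vH|. A midpoint within 2% of a scan edge raises a
boundary warning, and baselines crossing within ±5 °C of Tm are flagged.

**Arrhenius.** Unweighted regression of ln k on 1/T (kelvin); rate standard
errors are carried into reports but never used as weights, matching the
conventional procedure. R is fixed at 1.987 cal K⁻¹ mol⁻¹ (the value
conventional in this literature, not CODATA) so recomputations match
published arithmetic; slope = −E_act/R holds to machine precision by
construction. Linearity is decided by comparing linear and quadratic models
in 1/T on AICc with a 2-unit margin — a formalization of the visual judgement
usually applied to Arrhenius plots; with fewer than four points the
diagnostic is undefined and, in the pipeline, an activation energy is only
derived where the diagnostic passes or an override is set. Data already
linear to numerical precision short-circuit the comparison (comparing models
on rounding noise is meaningless).

## Temperature ramps

Along a ramp at β °C/min the surviving native fraction is
f_N(T) = exp(−(1/β)∫ k1(T′) dT′), integrated by Simpson quadrature on a
0.1 °C grid; the apparent midpoint is the temperature where f_N = 1/2, found
by interpolation. It satisfies ∫k1 dT = β ln 2 and increases strictly with
both ramp rate and activation energy (grid-verified). An option integrates
all three species along the ramp instead of folding N\* into D.

**Known limitation:** with the isothermal rate anchors extrapolated down the
ramp, simulated apparent midpoints fall in the 36–64 °C range — well below
the ≈65–71 °C midpoints measured for the real system. Real melts imply a far
steeper effective temperature dependence below 65 °C than a single Arrhenius
law anchored to 65–95 °C rates, which is consistent with curved Arrhenius
behaviour and with a kinetic-plus-thermodynamic stabilization picture. The
simulator is therefore a test bed for the *analysis machinery* (recovery,
ordering, ramp-rate dependence), not a quantitative predictor of ramp
midpoints. Relatedly, the symmetric van't Hoff sigmoid fitted to these
asymmetric kinetic melts lands a few degrees above the f_N = 1/2 point; the
pipeline tests check ordering and bounded offset, not identity.

What passing tests show: the fitters recover their own generating models
exactly (noiseless) and without material bias (noisy, Monte-Carlo); the
pipeline recovers ground-truth fast rates with median error < 5% at 2%
noise across the full 84-trace design. What they do not show: correctness
under instrument drift, non-Gaussian noise, baseline curvature, partial
refolding, or concentration-dependent aggregation — none of which the
generator emulates.

## Data handling

Traces travel as UTF-8 CSV with `# key=value` metadata headers
(variant, ldao_mM, protein_uM, temp_C, ramp_C_per_min, dead_time_s,
signal_kind) followed by `time_s,signal[,...]` or `temp_C,signal` columns.
Vendor binary formats are out of scope; users export delimited text. No
smoothing or denoising is ever applied to data entering a fit. Normalized
fractions outside [−0.05, 1.05] are flagged, never clamped. Anisotropy is
validated against the physical range [−0.2, 0.4]. The detergent:protein
ratio is computed arithmetically as (mM × 1000)/µM; published ratio labels
that disagree with that arithmetic are a metadata question left to the user.
Every fit result and report serializes to JSON with units in the field names
(`ku1_per_min`, `tm_C`, `eact_kcal_mol`).

Test problem sizes (5–15 min traces at 1 Hz, 0.5 °C melt grids, 50–100
Monte-Carlo repeats) were chosen as the smallest sizes at which the
statistical assertions are stable.
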