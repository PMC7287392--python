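# Methods

This note documents the models, estimators and numerical choices behind
ectoscope, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Experimental design and measurement model

The design crosses four two-level factors: day length (short/long),
thyroid status (hypothyroid/normothyroid), acclimation temperature
(18/28 °C) and acute test temperature (18/28 °C). The first three are
between-fish; test temperature is within-fish — every fish is measured at
both acute temperatures, so fish identity is a blocking (random) factor.
Synthetic traits follow an additive model on the measurement scale:

    y_ij = baseline + Σ effects(cell_ij) + u_i + e_ij,
    u_i ~ N(0, within_fish_sd²),  e_ij ~ N(0, noise_sd²)

with the fish intercept u_i shared across a fish's two measurements. This
is exactly the structure the downstream factorial analysis assumes; it is
deliberately the *simplest* data-generating process consistent with that
analysis. Defaults: 16 fish per between-fish cell (the study sizes span
13–21), all randomness drawn from one seed through named substreams.

## Respirometry

Dissolved O₂ (μmol L⁻¹) declines linearly in a sealed chamber while the
fish respires; the rate is the OLS slope over the recording window and

    MO2 = (−slope) · V / m      [μmol O₂ g⁻¹ min⁻¹]

Defaults mirror the assay geometry: 27 ml chamber and 30 min recording at
rest, 130 ml chamber and ~10 min at the exercise-induced maximum. Choices:

- The slope is fitted to the **full window** by default; `trim_initial_min`
  and an explicit `window` are available because no trimming rule is part
  of the protocol. On noiseless linear traces any sub-window returns the
  same slope (tested).
- No background-respiration correction by default; a blank-slope argument
  exists for users with empty-chamber recordings.
- Non-declining O₂ is an **error**, not a zero rate: a zero or negative
  consumption estimate would silently enter downstream scopes.
- r² < 0.9 attaches a QC flag but keeps the value; dropping data silently
  would change inference.
- Inputs are μmol O₂ L⁻¹; converters from % air saturation (Garcia &
  Gordon 1992 solubility coefficients, freshwater default) and mg L⁻¹ are
  explicit utilities, never an implicit guess.

## Swimming (Ucrit)

Stepped-velocity protocol: 0.06 m s⁻¹ for 20 min, then +0.02 m s⁻¹ every
5 min to exhaustion. Brett's interpolation credits the partial final step:
Ucrit = U_last + dU·(t_f/dt); division by standard length gives BL s⁻¹.
Fish failing during the initial habituation step get the pro-rated speed
`initial_speed · t/initial_duration` with an `initial_step_failure` flag
for exclusion review — the protocol is silent on this edge, so the value
is kept but marked. Ucrit is strictly increasing in both U_last and t_f
and bounded by [U_last, U_last + dU) (property-tested).

## Mitochondrial bioenergetics

An oxygraph trace with event markers: substrates (malate + pyruvate)
start State 2, a 0.5 mM ADP bolus starts State 3, ADP exhaustion relaxes
the trace to State 4, FCCP uncouples. Rates are −slope/protein in nmol O₂
min⁻¹ mg⁻¹; RCR = State3/State4; an FCCP rate below State 3 raises a
membrane-integrity flag.

The State 3→4 transition ("stabilisation" of the rate) is located by
**continuous two-segment least squares**: for every candidate breakpoint
at sample resolution, fit `y ~ 1 + t + (t − t_k)₊` and keep the RSS
minimiser subject to |slope₂| < |slope₁|. The sweep is assembled from
suffix cumulative sums (O(n) per trace) and is an exhaustive search — a
naive per-candidate regression is kept in the test suite as an
independent oracle and agrees exactly. A slope-threshold heuristic was
rejected because "stabilisation" is not quantified anywhere and a
breakpoint fit is reproducible and oracle-checkable. If no candidate
shows a slope-magnitude decrease (ADP never exhausted), a no-State-4
error with QC flag is raised. A minimum of 10 samples per segment is
enforced; no minimum State 4 *duration* is imposed (exposed as the same
parameter) since the descriptive 30–50 min stabilisation window is not a
rule.

The P:O ratio is ADP phosphorylated per oxygen **atom**:

    P:O = (adp_mM · V_ml · 1000) / (2 · ΔO2 · V_ml)

where ΔO2 is the *fitted* concentration drop between the ADP addition and
the detected State 4 onset — fitted boundary values, not raw samples, so
the estimate is noise-robust and identical in the noiseless limit.
ADP→ATP is taken as 1:1. P:O is invariant to chamber volume at fixed
concentrations (tested). The chamber volume has no default: the
instrument's working volume is configuration, not physiology.

The trace simulator inverts this stoichiometry: given a target P:O it
sets the State 3 segment length so the O₂ consumed equals
ADP_nmol/(2·P:O), snapping the onset to the sampling grid (default 0.05
min; the snapping error on P:O is < 0.1% at default geometry) and
recording both target and realised values as ground truth. Simulated
chamber O₂ starts at 400 nmol ml⁻¹ (oxygen-enriched medium) so that a
full run at P:O ≥ 1 never exhausts the chamber.

## Energetics

Metabolic scope = MO2max − MO2rest (non-positive values flagged, never
clipped). ATP production scope multiplies each fish's scope by its *own*
P:O at the *same* acute test temperature — no cross-fish averaging, and a
missing pairing is an explicit error rather than an imputation. Because
MO2 counts O₂ molecules and P:O counts oxygen atoms, the default
conversion multiplies by 2; the unconverted product is available
(`atom_factor=1`). All group comparisons are invariant to this constant,
which is why both conventions can coexist safely. The pipeline can
produce opposite group orderings for oxygen scope and ATP scope — the
central scientific point — and a constructed regression test pins this.

## Permutation inference

With two-level sum-to-zero factors and complete within-fish pairs, the
mixed model decomposes exactly into per-fish means m_i (between stratum)
and half-differences c_i (within stratum). Both strata are regressed on
the between-fish design; in the c-regression the intercept carries the
test-temperature main effect and each between column its interaction with
test temperature. The model has 14 terms (4 mains, 6 two-way, 3 + 1
three-way); the four-way interaction is excluded, which concretely means
the between three-way column is *omitted* from the within-stratum model
and pooled into its error (df = n_fish − 7 there, n_fish − 8 in the
between stratum).

F statistics use marginal (drop-term) sums of squares with sum-to-zero
coding — order-invariant, equal to sequential SS under balance, and
verified against an independent Type III reference fit under imbalance.
Empty cells raise an aliasing error naming the cells rather than silently
dropping terms.

P-values come from Freedman–Lane residual permutation within the correct
stratum: residuals of the reduced model are permuted **across fish** for
between terms and **sign-flipped per fish** for test-temperature terms,
then added back to the reduced-model fit and the F recomputed.
p = (#{F* ≥ F} + 1)/(B + 1), B = 4999 by default; exhaustive enumeration
(exact p, no +1) replaces Monte-Carlo automatically when the number of
arrangements (n! or 2ⁿ) is at most B. Each term draws from an independent
substream of the seed, and data are sorted internally, so results are
deterministic and row-order invariant. Calibration is enforced by the
test suite (null rejection rates and p-value uniformity over 500
simulated null studies) rather than by fidelity to any particular
existing implementation. Both one- and two-sided views are recoverable
since per-term contrasts are single-df.

Post hoc marginal-means contrasts average cell means over unconditioned
factors; their permutation p reassigns the contrasted factor at the level
it was randomised (whole-fish labels within strata of the other between
factors, or per-fish swaps for test temperature).

## Effect sizes

Cohen's d uses the pooled SD with n−1 weights; the sign is oriented by
argument order, and the thyroid helper always computes normothyroid −
hypothyroid so a positive d is a positive thyroid-hormone effect. The
95% CI is a **BCa bootstrap** (independent within-group resampling,
2000 resamples, seeded). BCa was chosen over the simpler percentile
interval after a direct calibration experiment: at n = 16 per group and
true d = 1, percentile intervals covered ~91% — a known small-sample
deficiency — while BCa covered ~94%, consistent with the nominal level;
the percentile method remains available via `ci_method="percentile"`.
The warming-mismatch contrast compares the warm cell (28 °C acclimation
and test) under short versus long days, pooling thyroid groups, for
Ucrit, P:O and ATP scope.

## Climate index

Per cell: seasonality × projected warming, min–max scaled over valid
cells to [0, 1]. Min–max scaling is the only transform that guarantees
both stated endpoints; it makes the index invariant under positive affine
transforms of the raw metric (so uniformly rescaling the warming grid
changes nothing) and preserves the raw ranking exactly. Two seasonality
definitions coexist because both appear in practice: mean monthly
maximum minus mean monthly minimum over the year (`annual_range`,
default) and the absolute July–January mean-temperature difference
(`july_january`); the definition used is recorded in the output
provenance. Negative warming cells are kept as-is. NaN is nodata and the
25 bands share a unioned mask. Raster I/O is NumPy `.npz` plus CSV; no
GeoTIFF reader is included and tests use synthetic latitudinal-gradient
rasters only.

## Default synthetic scenario

The pipeline's default ground truth encodes the qualitative structure the
analysis is designed to resolve: acute warming raises all whole-animal
rates; cold acclimation raises oxygen scope while *lowering* P:O (so ATP
scope ranks acclimation groups opposite to oxygen scope); short days
enhance cold acclimation of swimming, with a thyroid-dependent three-way
interaction; State 3 peaks when acclimation temperature mismatches
photoperiod. Magnitudes are round numbers chosen to give realistic
signal-to-noise at n = 16 per cell (e.g. resting MO₂ 0.10 ± 0.014,
scope 0.25, P:O 1.30 ± 0.14, Ucrit 0.11 m s⁻¹ ± 0.013 for a 25 mm,
0.5 g fish); no variance components were reported for the real study, so
these are stated assumptions, not estimates.

What the generator does **not** emulate: intermittent-flow cycles,
temperature drift between test temperatures, electrode drift or
background respiration, behavioural noise in swim trials, organ-specific
mitochondrial differences, or any mechanistic (Q10) temperature model —
temperature effects are pure design effects. Passing round-trip tests
therefore demonstrate estimator correctness under the stated measurement
model, not robustness to every field artefact.

## Problem sizes

Test-suite simulations use 500 null studies (B = 999) for calibration,
200 studies for power, 500 bootstrap experiments for coverage, and 100
seeded oxygraph traces for the P:O round trip; the acceptance script uses
the same or moderately reduced replicate counts. These sizes keep Monte
Carlo error well below the decision margins of each check.

## Known limitations

- The split-plot decomposition requires complete within-fish pairs; fish
  missing one test temperature abort the fit (by design, with a named
  error) instead of entering an unbalanced mixed model.
- Freedman–Lane p-values are asymptotically, not finitely, exact; the
  suite verifies calibration at the study's actual n.
- The breakpoint search assumes a single State 3→4 transition; biphasic
  ADP exhaustion would be mis-segmented (the QC flags would show rising
  or inconsistent segments).
- The climate index is an ordinal risk surface, not a mechanistic
  prediction; air-temperature seasonality only indicates the pattern of
  water-temperature fluctuation.
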