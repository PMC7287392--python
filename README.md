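# ectoscope

From raw oxygen traces to ATP production scope — a tested pipeline for
whole-animal and mitochondrial bioenergetics of ectotherms under crossed
photoperiod, thyroid and temperature treatments, with permutation-based
factorial inference and a global climate-mismatch index.

## The problem

Climate warming shifts temperatures but not day length, so ectotherms
increasingly meet warm water under short-day (winter) light regimes.
Whether that mismatch matters energetically cannot be read off
whole-animal oxygen consumption alone: the ATP yield per oxygen consumed
(the P:O ratio) itself changes with acclimation. ectoscope implements the
full analysis chain for a 2×2×2×2 repeated-measures experiment — day
length (short/long) × thyroid status (hypo/normothyroid) × acclimation
temperature (18/28 °C) × acute test temperature (18/28 °C, measured twice
per fish):

- **Respirometry** — closed-chamber O₂ depletion slopes →
  mass-specific MO₂: `MO2 = (−slope)·V/m` (μmol O₂ g⁻¹ min⁻¹).
- **Swimming** — stepped-velocity trials → critical sustained swimming
  speed by Brett interpolation: `Ucrit = U_last + dU·(t_f/dt)`, in m s⁻¹
  and body lengths s⁻¹.
- **Mitochondria** — event-annotated oxygraph traces → State 2/3/4 and
  FCCP-uncoupled rates (nmol O₂ min⁻¹ mg protein⁻¹), RCR, and the P:O
  ratio `ADP_nmol / (2·O2_nmol)` with the State 3→4 transition located by
  exhaustive two-segment breakpoint regression.
- **Energetics** — metabolic scope `MO2max − MO2rest` and ATP production
  scope `scope × P:O × 2` per fish and test temperature.
- **Inference** — split-plot factorial permutation ANOVA (Freedman–Lane
  residual permutation; whole-fish permutations for between-fish terms,
  per-fish sign flips for test-temperature terms), post hoc marginal-means
  contrasts, and Cohen's d with BCa bootstrap 95% CIs.
- **Climate** — a seasonality × projected-warming product, min–max scaled
  to a [0, 1] global mismatch-impact index.

A synthetic-data module generates every input class with known ground
truth (design tables, respirometry and oxygraph traces, swim trials,
climate rasters), so the whole chain is testable end to end without any
animal data.

## Worked example

```python
from ectoscope import (
    simulate_mito_trace, analyze_mito_trace,
    simulate_swim_trial, compute_ucrit,
)

# an oxygraph run with known mitochondrial efficiency
trace = simulate_mito_trace(target_po=1.5, noise_sd=1.0, seed=1)
rates = analyze_mito_trace(trace)
print(f"State 3 {rates.state3:.1f}, State 4 {rates.state4:.1f} nmol O2/min/mg")
print(f"RCR {rates.rcr:.2f}, P:O {rates.po_ratio:.3f}")

# a swim trial for a fish whose true Ucrit is 0.11 m/s
rec = simulate_swim_trial(0.11, body_length_m=0.025)
u = compute_ucrit(rec)
print(f"Ucrit {u.ucrit_ms:.3f} m/s = {u.ucrit_bl_s:.1f} BL/s")
```

prints

```
State 3 50.0, State 4 10.1 nmol O2/min/mg
RCR 4.93, P:O 1.500
Ucrit 0.110 m/s = 4.4 BL/s
```

i.e. the analysis recovers the simulated State 3/State 4 rates (50 and 10
nmol O₂ min⁻¹ mg⁻¹, up to sensor noise), their ratio (RCR ≈ 5 —
well-coupled mitochondria), the target P:O ratio of 1.5
ATP per oxygen atom, and the true swimming speed (4.4 body lengths per
second at 25 mm standard length).

A full synthetic study — 128 fish, all assays, permutation ANOVA on eight
response variables, warming-mismatch effect sizes and the climate index —
runs from one command and writes a reproducible results bundle:

```bash
ectoscope run --out my_run --seed 42
```

Under the default scenario the bundle's `stats.json` shows the pipeline's
key behaviour: cold-acclimated fish have the larger oxygen-consumption
scope but the lower P:O ratio, so ATP production scope ranks the
acclimation groups in the *opposite* order — oxygen consumption alone
does not predict ATP production.

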