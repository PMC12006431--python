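# Methods

## Scope and model structure

`thermoclamp` analyzes whole-cell patch-clamp recordings of a voltage- and
temperature-gated cation channel and ships a generative model calibrated to
the published condition-level statistics of epididymal sperm CatSper
recordings. The generative current density (pA/pF) is the composition

```
I(V, T, t) = Po(V; V1/2(T), k(T)) · (V − Vrev) · G(T) · h(t)  +  I_leak(V)
```

with `Po` the two-state Boltzmann open probability, `(V − Vrev)·G` a
per-voltage-side linear driving/conductance term, `G(T)` a temperature-
dependent amplitude, `h(t)` mono-exponential inactivation, and an ohmic,
temperature-insensitive leak anchored at −80 mV. Inward current is negative;
potentials are mV, densities pA/pF, temperatures °C (Kelvin appears only in
the Arrhenius transform, additive offset 273.15).

### Gating vs temperature

Each condition stores gating anchors at two temperatures (22 °C and 38 °C,
where G-V curves were measured). Between them `V1/2(T)` (and `k(T)`) follow
a logistic transition centred on the thermal threshold (33.5 °C, width
2 °C), affinely rescaled to pass through both anchors exactly. The raw
logistic would miss the hot anchor by ~9% of the span at width 2 °C;
anchor-exactness was preferred because the anchors are the measured
quantities, at the cost of the curve's centre sitting at 0.55 rather than
0.50 of the span. Only the two anchors are observable; the transition shape
between them is a modelling convention.

### Conductance amplitude vs temperature — two modes

Whether the heat response originates in the `V1/2` shift, the conductance
increase, or both cannot be separated from two-temperature G-V data, so
presets carry one of two amplitude modes:

* **anchored** (monovalent presets): gating shifts with temperature and
  `G(T)` is log-interpolated through the printed current-density ladder
  (e.g. −143.54 / −162.20 / −194.44 / −271.81 pA/pF at −80 mV for
  24/28/32/38 °C at pH 7.4), separately per stimulus protocol and voltage
  side. The noise-free model therefore reproduces every printed density
  anchor exactly, including step-vs-ramp discrepancies the source data
  itself shows. A strict two-Q10 law cannot fit that ladder (its successive
  ratios disagree), which is why interpolation is used here.
* **q10** (divalent presets): the voltage dependence is frozen at the cold
  anchors and the amplitude follows the exact piecewise law
  `G(T) ∝ q10_slow^((min(T,Th)−Tref)/10) · q10_steep^((max(T,Th)−Th)/10)`
  with `q10_slow = 2.7`, `q10_steep = 5.01`, `Th = 33.5 °C`, `Tref = 22 °C`.
  This is the condition used for thermal analysis, and the printed divalent
  anchors (−4.3 pA/pF at 24 °C, −22.8 at 38 °C) are mutually consistent
  with this law to 0.06% — the 38 °C anchor is reproduced from the cold
  calibration alone.

A side effect of anchor calibration: where an anchor lies far below the G-V
midpoint (tiny `Po`), the implied conductance is large and simulated
currents at strongly activating voltages can exceed realistic magnitudes.
This does not affect any normalized analysis (G-V, Arrhenius), which is
amplitude-invariant.

### Inactivation, tails, leak

Inactivation is `h(t) = h_inf + (1 − h_inf)·exp(−t/τ)` with the clock
starting at step onset (τ = 25 ms, `h_inf` 0.3–0.4 for the acidic-pH,
spermine and capacitated-divalent presets; none elsewhere). Ramps are
generated at the peak phase, since the anchored ramp densities were measured
at the peak. At the step→tail transition the conductance jumps to the tail
driving force and deactivates mono-exponentially (τ = 2 ms) to zero, making
the tail amplitude exactly proportional to `Po(step level)` — the assumption
tail-current G-V analysis rests on. Deactivation kinetics are not reported
in the source data; 2 ms keeps the tail peak well resolved at the 0.2 ms
sample interval.

The leak is linear through `Vrev` with −6.1 pA/pF at −80 mV for monovalent
conditions (the channel-null residual); divalent anchors are
baseline-subtracted in the source, so divalent presets carry zero leak.
Density anchors for the monovalent presets are treated as totals
(gated + leak).

## Synthetic cohorts

Cells draw capacitance from a normal distribution truncated to
[2.0, 3.5] pF (means 2.45–2.97 pF per condition; SDs 0.10–0.11 pF chosen
from the reported per-condition ranges — the capacitated legend's ±0.09 is
a standard error, which as a population SD would contradict the reported
2.65–3.10 pF range) and a lognormal amplitude scale with unit mean
(CV 0.2) so cohort-mean densities target the anchors. Recording noise is
Gaussian on the raw current, SD 5 pA (≈2 pA/pF), giving cohort SEMs of the
magnitude the source legends report at comparable n. All draws descend from
one integer seed; regeneration is byte-identical. The generator omits seal
and capacitance artifacts, access-resistance errors, activation kinetics
within a step, and temperature gradients within a sweep (bath ramps are
~0.1 °C/s; sweeps ≤1 s).

Because the generator realizes the same two-state model the analysis
assumes, passing recovery tests demonstrates the pipeline's correctness and
statistical calibration — not that real recordings obey a two-state model,
nor robustness to artifacts the generator omits.

## Analysis pipeline

* **Baselines.** Ramp-density pipelines subtract the pre-stimulus holding
  segment by default (holding sits at the reversal potential, so this is a
  no-op on clean data but removes offsets in real recordings); this keeps
  the channel-null residual density observable. The Arrhenius pipeline
  subtracts the HS companion sweep sample-wise, isolating the gated current
  whose log-slope carries the Q10s.
* **Amplitudes.** Peak = signed extremum of the expected polarity within the
  step, excluding the first 2 ms (capacitive edge in real data); steady
  state = mean of the last 10% of the step; tail = signed extremum in the
  first 10 ms after the transition minus the tail's own steady level. With
  noise, extremum-based tails are biased upward by roughly the expected
  extreme of ~50 noise samples; this is negligible for large tails but can
  shift fitted midpoints of small-amplitude conditions by a few mV — a
  known limitation shared with extremum measures on real data.
* **G-V fitting.** The mean tail curve across cells is normalized by its
  largest magnitude and fitted with `g_max/(1+exp((V1/2−V)/k))`,
  `g_max ∈ [0.8, 1.2]` free (fixed `g_max = 1` is biased for shallow curves
  far from saturation at +80 mV), initialized by logit linearization.
  Conditions whose printed slope factors are missing use 20 mV (acidic pH)
  and 15 mV (divalent); the published 42.6 mV would demand relative maxima
  outside the `g_max` bounds at +80 mV for those midpoints.
* **Two-phase fit.** Exhaustive breakpoint scan, ≥4 points per segment, two
  independent OLS lines (no continuity constraint — the threshold is defined
  as the intersection of two free lines), ties broken toward the median
  temperature. Intersections outside the sampled range are flagged and
  clipped; parallel lines raise. Default thermal schedules sample 18
  temperatures (1 °C apart, 24→41 °C), comfortably satisfying the ≥8-point,
  ≥10 °C span requirement.
* **Slope→Q10.** `Q10 = 10^(−m·10/((T_K−5)(T_K+5)))` with `T_K` the segment
  midpoint: the exact finite-ratio over a centred 10 °C window on the fitted
  line. An uncentred window (`T_K·(T_K+10)`) would bias Q10 by ~3%; the
  centred form agrees with the two-point formula within 0.5% on exact data
  across 22–41 °C.
* **Cohorts.** Per-cell fits are averaged (mean ± SEM over cells); a pooled
  mode and a bootstrap over cells are available. Reported SEM is always the
  sample-SD-based standard error with n = number of cells.

## Reference runs and tolerances

`thermoclamp.report.reproduce(seed)` regenerates all calibrated cohorts
(7-cell divalent thermal, 9-cell G-V cohorts per condition, 9-cell density
ladder, 13-cell null, 51-cell capacitance sample) and compares recovered
values to the preset calibration targets at twice the published SEM where
one exists (threshold: 1 °C), otherwise 5% relative with a 2 mV floor for
midpoints. Cohort seeds derive as `base·1009 + offset (mod 2^31)` with
fixed per-cohort offsets; base 0 gives the library's reference runs. These
problem sizes match the source cohorts and keep a full reproduction run
under a few seconds.

## Known limitations

Two-state gating only (no multi-state kinetics, no Ca²⁺-dependent
inactivation, no GHK permeation, no voltage-dependent polyamine block —
spermine effects are encoded phenomenologically through gating/density
parameters). The `V1/2(T)` transition shape between the two measured
temperatures is a convention. Spermine and capacitated density anchors are
phenomenological (not printed in the source); they do not influence any
normalized analysis. Vendor binary formats are an extension point, not
implemented; datasets are plain text.
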