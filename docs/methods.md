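# Methods

`eaeox` analyzes longitudinal tissue-oximetry recordings from mice with
chronically implanted fiber-optic PO2 probes in cerebellar or cortical
gray matter, followed through induction of experimental autoimmune
encephalomyelitis (EAE) alongside CFA-injected controls. This note
documents the statistical model, the defaults and why they were chosen,
what the synthetic-cohort generator does and does not emulate, and the
known limitations of the procedure itself.

## The measurement model

Each mouse-day yields one session: nominally 60 PO2 samples recorded at
0.1 Hz over 10 minutes (mmHg). Days are indexed relative to induction
(day 0); days −3…−1 are pre-induction baseline. Because absolute PO2
varies several-fold between animals (probe placement, local
vasculature), all inference runs on ΔPO2:

    ΔPO2_i(d) = x_i(d) − b_i,   b_i = grand mean of all baseline samples of mouse i

The baseline is the pooled mean over every pre-induction sample (180 at
the nominal schedule). At equal session lengths this equals the mean of
session means; pooling stays well-defined when a session is truncated.
Sessions with other than 60 samples are accepted with a warning; two
samples is the minimum for any variance-based statistic.

## Day-level hypoxia/hyperoxia calling

For EAE mouse *i* on day *d*, the 60 ΔPO2 samples are compared with the
concatenated ΔPO2 samples of every control mouse measured on the
matched day (nearest session within ±1 day per control, each control
normalized by its own baseline) with a two-sample t-test — Welch's
unequal-variance form by default, pooled Student as an option. The
threshold is Bonferroni-corrected: α′ = α/m with α = 0.05 and, by
default, m = the mouse's own number of post-induction measurement days
(a global all-mouse-days family is available). Calls:

* **hypoxic** — p < α′ and mean ΔPO2 below the control pool mean;
* **hyperoxic** — p < α′ and above (this sign convention permits a
  hyperoxic call at negative ΔPO2 when controls declined further);
* **normoxic** — otherwise.

Per-mouse summaries (counts of hypoxic/hyperoxic days, mean ± SD of the
called-day ΔPO2, day of largest |ΔPO2|, peak behavior score and its
first day) and cohort totals mirror the published per-mouse tables,
which also ship in the package as fixtures. The magnitude asymmetry of
hypoxic vs hyperoxic excursions is tested with a pooled two-sample
t-test on |ΔPO2|.

### Known inferential limitation: baseline estimation error

The t-test treats b_i as known, but it is estimated from ~180 samples
(standard error ≈ σ_w/√180 ≈ 0.19 mmHg at σ_w = 2.5). That error is
shared by every day of the same mouse and shifts all of its ΔPO2 values
coherently, so the realized per-comparison false-positive rate under a
true null exceeds α′ by roughly a factor
2Φ̄(t_crit/√(1 + 1/3))/2Φ̄(t_crit) ≈ 3 (the 1/3 is
(1/180)/(1/60 + 1/300) and is invariant to the within-session sd):
measured ≈ 1.1–1.5% against α′ ≈ 0.46% on null simulations. The same
mechanism affects any analysis that reuses one estimated baseline
across repeated days, including the original procedure this package
implements; a mixed-effects or paired formulation would remove it but
is deliberately out of scope. Power for realistic shifts (|δ| ≈ 8.8
mmHg against se ≈ 0.35 mmHg) is essentially unaffected.

The same correlation structure matters for the behavior-bin tests on
absolute PO2 (below): repeated session means of one animal share its
baseline (between-animal sd ≈ 5–7 mmHg), so pooling them as independent
replicates inflates size badly. The package's null-size test therefore
uses a one-session-per-animal design, where the property genuinely
holds.

## Time-course and behavior statistics

* **Windowed probabilities.** Calls are binned into half-open 4-day
  windows [a, a+4); each window reports count(label)/n. Windows tile
  the study span, so window n's sum to the total number of calls.
* **|ΔPO2| by deficit bin.** Behavior uses a 15-point paralysis scale
  (tail ≤ 2, each limb ≤ 3, 15 = death), scored the same day as the
  recording; a call pairs with the same-day score, else the nearest
  within ±2 days, else it is set aside. Bins are low [0, 4), medium
  [4, 8), high [8, 12] — equivalent to "0–3.9 / 4–7.9 / 8–12" at
  half-point granularity. Scores above 12 (possible just before the
  humane endpoint at ≥13) fall in the top bin with a warning.
* **ANOVA + Games-Howell.** One-way ANOVA F plus Games-Howell pairwise
  comparisons for unequal variances: q_ij = |m_i − m_j| /
  √((s_i²/n_i + s_j²/n_j)/2) referred to the studentized-range
  distribution with k groups and Welch–Satterthwaite df (SciPy's
  quadrature-based studentized-range CDF). At k = 2 this reduces
  exactly to Welch's t (q = t√2); under equal variances and equal n it
  approaches Tukey HSD. Both limits are exercised in tests, along with
  an independent cross-check against pingouin.
* **Regression.** OLS of mouse-day |ΔPO2| on deficit score, restricted
  to animals whose peak score exceeds 0, with F = (n−2)R²/(1−R²) on
  (1, n−2) df against the flat-line null.
* **Absolute-PO2 bin tests.** Session means (not ΔPO2) per deficit bin
  vs pooled control session means, Welch t-tests with Bonferroni family
  = number of occupied bins.

## PHD oxygen-kinetics sensitivity

PO2 converts to dissolved O2 as c = α·PO2 with α = 1.39 μM/mmHg
(standard brain tissue at 37 °C; configurable). Prolyl hydroxylase
(PHD1–3), the oxygen sensor that tags HIF-1α for degradation, follows
v/Vmax = c/(Km + c) with published Km between 85 and 240 μM — far above
tissue concentrations of ~30–45 μM, so the enzyme operates on the steep
limb. The rate drop for a decline c1 → c2 is 100·(1 − (c2/(Km+c2)) /
(c1/(Km+c1))), evaluated at both Km endpoints; the drop is monotone in
Km (→ 100·(1 − c2/c1) as Km → ∞), so the endpoints bound the range.
For the region-typical decline 41.6 → 29.4 μM this gives 21.8–26.1%.
The pipeline recomputes the same quantity from each run's own cohort
(mean baseline and mean hypoxic-day ΔPO2).

## Synthetic cohorts

No raw traces were deposited, so the generator produces cohorts with
the structure the analysis assumes:

* Per-animal baseline ~ Normal(μ_b, σ_b) truncated positive —
  cerebellum 29.9 ± 6.8, cortex 23.6 ± 4.8 mmHg; samples ~
  Normal(baseline + shift, σ_w) floored at 0 mmHg.
* σ_w = 2.5 mmHg by default, chosen so the session-mean SEM is
  ≈ 0.3 mmHg, consistent with the small day-level error bars of this
  kind of recording; exposed in the config.
* Each EAE post-induction day independently draws a label from
  region-specific windowed probability curves (cerebellar hypoxia
  peaking at 0.67 in days 4–8, hyperoxia 0.46 in days 8–12; cortical
  hypoxia 0.86 in days 8–12, hyperoxia 0.29 in days 16–20; off-peak
  levels set so roughly half of cerebellar and three-quarters of
  cortical days are hypoxic). Hypoxic shifts ~ Normal(−8.8, 6.0)
  (cerebellum) or Normal(−8.0, 4.6) (cortex), hyperoxic +3.2 ± 2.8 /
  +0.8 ± 2.1, rejection-sampled to the label's sign so the ground-truth
  invariant (hypoxic ⇒ shift < 0) holds. Per-day draws let one mouse
  mix hypoxic and hyperoxic days, as the real cohorts do.
* Measurement schedule: baseline −3, −2, −1; post-induction 3, 5, 7,
  10, 12, 14, 16, 18 (every 2–3 days through the peak), then 23, 28, 33
  (every 5 days) — 11 scheduled post days.
* Behavior: piecewise-linear onset → peak → 85%-of-peak plateau with
  0.5-point noise, clamped to the [0, 15] half-point grid; peak drawn
  per mouse (≈ 6 ± 3.4; a draw below 0.5 gives an asymptomatic,
  all-zero animal). Controls score 0 throughout. A score ≥ 13 triggers
  humane-endpoint censoring: later sessions, scores and truth rows are
  removed.
* RNG: one root seed; each mouse consumes its own `SeedSequence`
  substream, so growing the cohort never perturbs existing animals.

What the generator does **not** emulate: within-session autocorrelation
(samples are i.i.d. by default; an AR(1) knob exists but is off — the
oscillations present in real traces would make the 60-sample t-test
effectively anticonservative beyond what is described above), day-level
physiological drift in controls, probe drift or failure, and any
coupling between behavior and PO2 beyond their shared schedule. Passing
recovery tests therefore demonstrates that the pipeline recovers the
statistical structure it assumes, not that the assumptions hold for
real recordings.

Because injected shift magnitudes are drawn per day (occasionally
< 1 mmHg, the detection limit at these sample sizes), hypoxic-day
recovery sensitivity is ≈ 0.97 rather than the ≈ 0.999 a fixed
|δ| = 8.8 power calculation would suggest. Called-day summaries are
selection-biased toward large shifts: simulated cohorts report mean
hypoxic ΔPO2 ≈ −10 mmHg for an injected mean of −8.8 (truncation plus
detection bias), which is inherent to summarizing only significant
days.

## Numerical and degenerate-input conventions

Zero variance in both t-test groups: t = 0, p = 1 at equal means,
|t| = ∞, p = 0 otherwise. All-constant ANOVA groups: F is NaN and
flagged, pairwise p = 1 (or 0 at unequal means). A constant response in
the regression returns slope 0, R² = 0, F = 0, p = 1; a constant
predictor is an error. Ties in day matching and score pairing resolve
to the earlier day. Sample-level truncation at 0 mmHg introduces
negligible bias at the default means (> 9 sd from the floor).
Percentages are reported to one decimal; comparisons against printed
integers use ±0.5.

## Problem sizes used in stochastic checks

Monte-Carlo properties run on default-size cohorts replicated across
seeds: 12 null studies (~1 050 mouse-days) for the false-positive rate,
12–20 studies (~550–850 injected hypoxic days) for sensitivity, 200
animals for generator calibration, and 50–100 random instances for the
oracle-agreement checks. At these sizes the Monte-Carlo standard errors
(≤ 0.01 on rates) are small relative to the margins being tested.
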