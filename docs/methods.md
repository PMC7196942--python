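# Methods

## Scoring model

A vessel's stenosis score (SS) is the maximum grade over its detected
stenotic segments (the narrowest segment governs). Grade boundaries are
half-open: 0 → none, (0, 50) → mild, [50, 70) → moderate, [70, 100) →
severe, exactly 100 → occlusion. The clinical category labels do not
define "no stenosis" numerically; we treat percent 0 (or an absent plaque)
as grade none.

The total stenosis score (TSS) sums SS over six vessels (bilateral CCA,
ICA, VA), range 0–24; RI-TSS applies identical rules to angiographic
grades. Global blood flow (GBF) sums measured flow over four vessels
(bilateral ICA and VA), because volumetric flow is measured on those
vessels only. The two vessel sets are configurable: the source material
defines TSS over six vessels but lists flow measurements for four, and the
published cubic intercept (1380.6 mL/min) exceeds the four-vessel
no-stenosis sum (1181.2 mL/min), so the exact vessel set behind the
published GBF is ambiguous. Missing vessels score as grade none with a
logged warning (strict mode raises); a missing flow on a non-occluded
GBF vessel is always an error — the pipeline never imputes flow silently.

## Calculated stenosis score

For grade g of a vessel type, `calculated_ss = (BF_none − BF_g) /
(BF_none − BF_mild)`, i.e. the grade's mean flow reduction normalised by
the mild-grade reference; mild is 1 by construction and occlusion is fixed
at 4 (its flow is unmeasurable and taken as 0). Reported rounding is
half-up to 1 decimal (clinical-table convention; Python's banker's
rounding would differ), and the approximate SS is the unrounded quotient
rounded to the nearest integer. The Cochrane change-from-baseline
imputation `SD = sqrt(SD1² + SD2² − 2·corr·SD1·SD2)` is provided with an
explicit correlation argument defaulting to 0.5, the common Cochrane
default; the source does not state the value it used, so no numeric claim
is tied to it.

## Curve models

`fit_cubic`/`fit_linear` are ordinary least squares on a Vandermonde
design (statsmodels), reporting R² = 1 − SSE/SST (defined as 0 for a
constant outcome) and the overall-F p-value. `fit_segmented` fits three
independent polynomials over segments x < t1, t1 ≤ x ≤ t2, x > t2 for
every candidate integer pair (default grid 3 ≤ t1 < t2 ≤ 12), cubic where
a segment has ≥ 5 points and ≥ 4 distinct x, otherwise the highest order
the segment supports; candidates leaving a segment under 2 points are
skipped. Selection maximises pooled R² = 1 − Σ segment SSE / SST(all y);
ties go to the smaller first, then smaller second, threshold. No
continuity constraint is imposed at the breakpoints — nothing in the
source suggests constrained splines, and the independent-segment choice is
stated here explicitly.

Two facts about this estimator worth knowing:

* On a *continuous* piecewise curve sampled at integer scores, a knot
  shifted by one step fits exactly as well (the kink value lies on both
  adjacent pieces); only the tie-break yields the smaller pair.
* Under noise the three cubics are flexible enough to absorb a one-step
  knot shift almost completely, so the recovered breakpoints carry roughly
  ±1 score of uncertainty at realistic cohort sizes. Training-data pooled
  R² always improves with segmentation; it is a descriptive fit index
  here, not a model-selection criterion with guarantees.

## Prognostic evaluation

Endpoints are classified as binary flags at an assessment horizon (30, 90
or 180 days; analyses default to 180, the last assessment): recurrent
stroke (primary), composite cardiovascular events (recurrent stroke,
cardiac death, non-fatal MI), all-cause death, cardiovascular death,
non-fatal MI. A death terminates a record; an event-free patient lost to
follow-up before the horizon is excluded from that horizon's denominator
(their exclusion can never change the event count), while a death before
the horizon without the endpoint event counts as a negative — death is an
observed outcome, not censoring.

AUC is the Mann–Whitney pair-counting estimator (ties ½, computed via
midranks), with the Hanley–McNeil SE and a normal 95% CI clipped to
[0, 1]. The best prediction point maximises Youden's J over observed score
values, smallest qualifying threshold on ties; GBF is negated internally
(low flow = high risk) and its threshold reported back on the flow scale.
Correlated AUCs are compared with DeLong's covariance z-test; identical
rankings short-circuit to p = 1. AUC ≥ 0.7 is flagged "accurate" per the
usual convention.

## Synthetic cohort generator

No patient-level data accompany the scale, so the generator emulates the
study conditions and every distributional claim the tests make is a claim
about this generator, not about real patients:

* **Grades.** Per-vessel categorical draws; defaults give ~87% stenotic
  ICA/VA vessels (the published prevalence) with a first-stroke-like split
  (ICA: none .13, mild .37, moderate .25, severe .15, occlusion .10; CCA
  mostly clean). The true per-grade split is unpublished; this is a
  modelling choice.
* **Flows.** Per-grade means from the flow chart (no-stenosis mean minus
  the grade's mean reduction; reduction SDs as spreads). A patient's
  vessel deviations are projected to sum to one patient-level total-flow
  residual e ~ N(0, 30 mL/min): cerebral autoregulation redistributes
  flow between supply vessels, so total flow varies far less than an
  independent four-vessel sum — and a cohort-level TSS–GBF R² in the 0.8s,
  as published, is only possible under such tight totals. Vessel means
  stay anchored to the chart (verified by test); marginal vessel SDs sit
  somewhat below the chart SDs as a consequence of the projection.
* **Compensation curve.** E[GBF | TSS] follows a monotone inverse-S:
  slope −80 mL/min/point below score 5, −8 across the 5–10 plateau, −53
  beyond 10 (anchored at the 1181.2 baseline and ≈0 at the all-occluded
  score 24), with downward level drops of 40 and 50 mL/min at the knots
  modelling the threshold nature of collateral recruitment and
  exhaustion. The drops also make the knots identifiable — a fully
  continuous curve is not (see curve models above). The mean structure is
  rescaled per patient; the total-flow residual rides on top unscaled, so
  GBF noise is homoscedastic across scores.
* **Events.** Per-endpoint logistic models in TSS. The slope is
  root-found so the model-implied, tie-aware AUC over the realised TSS
  distribution equals the design AUC (default 0.75); a binormal
  approximation b = √2·Φ⁻¹(AUC)/σ seeds the bracket but is biased high in
  realisation because TSS is discrete. The intercept is root-found to
  match the target 180-day incidences (recurrent stroke 7.7%, all-cause
  death 5.2% with 16/39 cardiac, non-fatal MI 3.4%) to 1e-6. Events are
  allocated by TSS stratum with stochastic rounding of each stratum's
  expected count, so realised incidence and discrimination concentrate on
  their design values at n = 750 instead of drifting on binomial noise;
  marginal per-patient risks are unchanged. Event days are uniform over
  1–180; loss to follow-up hits 2.4% of patients at a uniform day; events
  after death or after loss are removed, which biases realised incidences
  down by a few tenths of a percentage point.

What the generator does **not** emulate: measurement error in grading,
velocity-based grade assignment, competing-risks structure, covariate
effects (age, plaque morphology), within-patient correlation between
disease severity and loss to follow-up, or any intracranial/collateral
flow measurement. Passing tests therefore demonstrate the pipeline's
correctness and calibration under these assumptions, not clinical
performance.

## Problem sizes and determinism

All randomness flows from one integer seed through per-module substreams
(`numpy` SeedSequence spawning), so every table is bit-reproducible.
The test suite runs the default cohort at n = 750 (the study's enrolment)
and law-of-large-numbers checks at n = 20 000; the permutation oracle for
the DeLong test enumerates all 64 sign-flip patterns of a 6-patient set
and cross-checks a 10⁴-draw resampled version. Curve fits use the default
integer breakpoint grid (45 candidate pairs).

## Known limitations

* Breakpoint recovery has ±1-score uncertainty at n = 750 noise levels
  (above); across seeds the default generator recovers (5, 10) in roughly
  half of runs, exactly at the packaged default seed.
* The published second cubic equation is internally inconsistent (two
  linear terms) and the first is increasing over the score range; neither
  is used beyond its intercept. The generator's inverse-S is its own
  construction, anchored to the published no-stenosis flows.
* Half-up rounding reproduces printed percentages except the published
  non-fatal-MI rate (26/750 prints as 3.4; the arithmetic gives 3.47).
* ROC analyses treat endpoints as binary-by-horizon; no time-to-event
  modelling, by design.
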