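# Methods

## Inference model

All four systems are multi-input single-output Mamdani controllers.
For a rule base R₁…R_m over inputs u₁…u_n and output y:

1. **Fuzzification.** Each crisp input is mapped to a degree per
   linguistic term through piecewise-linear membership functions
   (triangles and trapezoids, optionally with an open shoulder at a
   universe edge).  Values outside a variable's universe of discourse
   are clamped to the nearest edge and a warning is logged — clinical
   outliers (e.g. glycaemia 350 mg/dL) must degrade gracefully, never
   crash the decision support.
2. **Firing strength.** αᵢ = min over the antecedent clause degrees for
   AND, max for OR, multiplied by the rule weight.  All shipped rules
   are AND with weight 1; OR and weights are engine features kept for
   generality.  A clause list may omit a variable entirely (wildcard),
   which is how the ProtACE rule that depends only on the dose
   difference is encoded.
3. **Implication and aggregation.** Each consequent set is clipped at
   αᵢ (min-implication) and the clipped sets are combined pointwise by
   max on a uniform grid over the output universe.
4. **Defuzzification.** Centre of gravity of the aggregate set,
   computed with trapezoidal quadrature on the grid.  Trapezoidal
   weighting is exact for piecewise-linear curves whose breakpoints lie
   on grid nodes, and avoids the half-sample bias a plain weighted sum
   picks up when the aggregate is positive at a universe edge.

**Grid resolution** defaults to 2001 points (configurable, minimum
101).  On the widest universe (proteinuria, 0–4000 mg/24 h) the step is
2 mg/24 h; the observed COG discretization error against closed-form
centroids is far below 0.5 output units, i.e. orders of magnitude
smaller than any band width.

**No-rule-fired policy.** The shipped rule tables intentionally cover
only the clinically meaningful term combinations, so inputs can fall
into a gap (e.g. diabetic-range glycaemia with an in-window sirolimus
level has no ProtFIS rule).  The default policy raises `NoRuleFired`
carrying the full fuzzified input state; a nearest-band fallback (use
the consequent of the closest-to-firing rule) exists but is off by
default, because a silently fabricated output would be unsafe in a
decision-support setting.  `coverage_report` enumerates the uncovered
input regions on a grid so the gaps are auditable.

Determinism: the engine contains no randomness; `infer` is a pure
function and identical inputs give bit-identical results.

## Membership-function reconstruction and calibration

The clinical sources fix band *ranges*, not vertices.  The shipped
vertices follow three conventions:

* **Contiguous bands** (glycaemia, proteinuria): adjacent sets cross at
  degree 0.5 exactly on the clinical boundary.  Transition half-widths:
  10 mg/dL for glycaemia; 20% of the narrower adjacent band for
  proteinuria (30/70/100/200 mg/24 h at the 150/500/1000/3000 cutoffs).
* **Overlapping therapeutic windows** (sirolimus 0–5 / 4–7 / 6–12 /
  11–14 / 13–20 ng/mL; cyclosporine 0–2 / 1.5–5 / 4–11 / 8–15 / 12–20
  mg/kg): each term's plateau is its non-overlapped core and the linear
  transition spans the printed overlap.
* **Dose-step levels** (ACE-inhibitor dose difference, levels 0–4): the
  engine consumes the magnitude |Δ| of the signed dose change; levels
  are triangles peaked at the integers.

Within those conventions a handful of vertices remain genuinely free,
and the four published single-patient cases are the only quantitative
anchors available.  They were used once, as a calibration set, and the
resulting vertices frozen into `src/renalfis/configs/*.json`:

* **Sirolimus sufficient→good crossover at 8.5 ng/mL** (transition
  spanning 6–11 ng/mL rather than only the printed 6–7 overlap).  The
  ProtFIS anchor (glycaemia 90, sirolimus 7.82 → ≈290 mg/24 h, light
  proteinuria) requires the "sufficient" rule to outweigh the "good"
  rule at 7.82 ng/mL; with any narrow symmetric overlap only the
  good-good rule fires and the output would sit in the physiological
  band near 76 mg/24 h, contradicting the anchor's band outright.
* **Asymmetric dose-difference levels (k−0.5, k, k+1).**  The two
  case-2 anchors jointly require |Δ| = 2.50 to activate level 2 and not
  level 3 (both fire "sufficient"/"stage 3" consequents at level 2,
  while level 3 would drag the proteinuria case into the moderate
  band).  With symmetric unit triangles the 2.5-step input ties levels
  2 and 3 at 0.5 each and the tie is provably unresolvable by output
  shaping alone (the moderate set's mass cannot be made small enough
  for the aggregate centroid to stay below 500 mg/24 h).  The
  asymmetric support reads a fractional dose step as belonging to the
  level already completed — the protective interpretation.
* **GFR per-boundary half-widths 3/12/4/6 mL/min at 15/30/60/90.**
  Both GFR anchors sit in stage 3 (43.20 and 43.10 mL/min), pinning the
  stage-3 set's lower-tail asymmetry; the calibrated widths reproduce
  them at 44.00 and 42.86 mL/min while keeping every 0.5-crossing on
  its stage cutoff.

With these frozen configs the four anchors reproduce at
289.55 / 44.00 / 335.42 / 42.86 against the published
290 / 43.20 / 316 / 43.10 — all within the ±10% calibration tolerance
and, more importantly, all in the published risk band (light
proteinuria / stage 3 / light proteinuria / stage 3).  The residual
numeric gaps reflect the unpublished original vertices; band identity,
not the third digit, is the clinically meaningful contract.

## Risk bands and MDRD

Band classification is a total step function.  Exact proteinuria
boundary values (150/500/1000/3000 mg/24 h) belong to the higher-risk
band, reflecting the protective bias of the whole design.  GFR stage
intervals are lower-inclusive ([90,∞) / [60,90) / [30,60) / [15,30) /
[0,15)), matching the half-open clinical convention; GFR exactly 15,
which the printed staging leaves unassigned, is stage 4 by this rule.

The GFR estimate from serum creatinine uses the 4-variable
IDMS-traceable re-expressed MDRD equation,
175 · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · 0.742(female) · 1.212(Black),
in mL/min/1.73 m²; the 175 coefficient is configurable (186 selects
the legacy form).

## Evaluation

A prediction is *correct* when its crisp output falls in the same risk
band as the measured outcome.  Cohort accuracy is 100·correct/total
rounded half-up to an integer; records that hit a rule-base gap are
counted in the denominator as errors and reported separately as a
no-rule-fired frequency.  For the binary metric family the five-band
task is binarized as "any abnormality" (band ordinal ≥ 1 is positive);
sensitivity = recall = TP/(TP+FN), specificity = TN/(TN+FP),
precision = TP/(TP+FP), F = harmonic mean of precision and recall,
G = √(sensitivity·specificity).  Undefined ratios are reported as
not-applicable, never as silent zeros.  The binarization choice is a
genuine design gap in the source material; one-vs-rest tallies are
recoverable from the 5×5 agreement matrix that `ConfusionCounts`
always carries.

## Synthetic cohorts

No patient registry is distributed, so the pipeline is exercised on
synthetic cohorts matching the published summary statistics of the four
follow-up samples (n = 63/103/70/107; proteinuria 401.78 ± 424.19 and
532 ± 516 mg/24 h; GFR 65.98 ± 15.86 and 53.54 ± 16.22 mL/min; ages
30–60; 2–6 years post transplant; diabetes-risk fractions 12/63, 38/103,
13/70, 16/107).  Distribution families are a modelling choice, not a
published fact: proteinuria is log-normal (the printed SD exceeds the
mean, implying strong right skew), GFR a normal truncated to the
physiological 0–130 mL/min; glycaemia is a two-component normal mixture
(88 ± 10 normal-range, 150 ± 30 elevated) with the elevated weight
equal to the diabetes-risk fraction; drug levels are uniform over their
therapeutic ranges; serum creatinine is back-solved from the drawn GFR
through MDRD so the two fields are mutually consistent.  All draws flow
through one integer seed.

What the simulator does *not* emulate: any real dependence of the
outcomes on the inputs (outcomes are sampled independently of the rule
bases by default), longitudinal correlation within patients, drug
pharmacokinetics, or co-medication.  Passing pipeline tests on
synthetic cohorts therefore demonstrates correctness and robustness of
the machinery — not clinical accuracy, which the published figures
(90%+ band agreement on real registries) address and which cannot be
re-derived without the registry.  An optional FIS-consistent mode draws
outcomes as multiplicative log-normal noise (CV 0.10) around the FIS
prediction and serves as a positive control: with it, band agreement on
fired records exceeds 80% by construction.

The published normalized outcome means (e.g. 0.51 for GFR 65.98/130)
use divisors that are not mutually consistent across the proteinuria
cohorts, so `normalize_outcome` always takes the divisor as an explicit
argument and never infers one.

## Known limitations

* The original membership-function vertices are unpublished; the
  shipped configs are a calibrated reconstruction, and quantities other
  than the four anchor cases may deviate numerically from the original
  implementation while staying band-faithful.
* The published per-cohort accuracies (91–93%) are not reproducible
  here (no registry); only their arithmetic (e.g. 94/102 → 92%) and the
  internal consistency of the published metric table are checked.  One
  published table entry (a column's F-measure) is inconsistent with its
  own printed precision/recall by one rounding unit and is flagged in
  the test suite.
* Rule-base gaps are inherent to the encoded tables; deployment would
  require either table completion with clinical sign-off or the
  explicit fallback policy.
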