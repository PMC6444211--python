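# Methods

## The grading protocol

The package implements the 2010 revision of the European Society of
Hypertension International Protocol (ESH-IP2) for validating automatic blood
pressure monitors, together with the heart-rate extension used when a monitor
also reports pulse.

Each of 33 participants contributes nine consecutive same-arm measurements in
a fixed alternating schedule: an entry pair (`BPA` on the reference device,
`BPB` on the test device, both discarded from grading) followed by
`BP1`…`BP7`, odd slots on the reference device and even slots on the test
device. Each measurement is a (SBP, DBP, HR) triple.

**Pairing.** Each graded test reading (`BP2`, `BP4`, `BP6`) is compared with
its two flanking reference readings (`BP1`/`BP3`, `BP3`/`BP5`, `BP5`/`BP7`).
The graded difference is the signed test-minus-reference value against the
*nearer* flank (smaller absolute difference; an exact tie keeps the earlier
slot). This yields exactly 3 differences per participant per quantity, 99 per
cohort. Fixed-flank rules (`before`, `after`) are available for sensitivity
analysis.

**Band classification.** Absolute differences are counted cumulatively within
three nested bands — ≤5, ≤10, ≤15 mm Hg for pressure; ≤3, ≤5, ≤8 beats/min for
heart rate. Membership is inclusive.

**Verdicts.**

* *Part 1* (per measurement, 99 pairs): pass iff at least two of the three
  bands reach the stricter count row (73/87/96) **and** all three reach the
  looser row (65/81/93).
* *Part 2* (per participant, 33 subjects): pass iff ≥24 participants have at
  least 2 of their 3 differences inside the innermost band, and ≤3
  participants have none.
* *Part 3*: pass iff parts 1 and 2 both pass.

### Design choices in the grading

* **Threshold semantics.** Validation reports sometimes print the two
  part-1 rows attached to SBP and DBP respectively; read literally, that makes
  the rows single-quantity requirements that must hold in *all* bands, and an
  SBP outcome such as (75, 93, 94) would fail (94 < 96) even though such
  devices are reported as passing. The default here is the protocol's
  two-of-three / all-of-three semantics applied to every quantity, which
  reproduces the published verdicts; `mode="paper-literal"` additionally
  grades the literal single-row reading and flags any discrepancy in the
  report.
* **Heart-rate extension.** The protocol defines count thresholds for blood
  pressure only. The HR extension keeps the BP count rows and substitutes the
  3/5/8 beats/min bands; every HR report is flagged as an extension.
* **Non-standard cohort sizes.** For n ≠ 33, minimum counts scale by n/33
  rounded *up* and maxima rounded *down* (a smaller cohort never passes more
  easily), and the run is flagged non-standard. This exists for simulation
  studies, not for real validations.
* **Tie-break.** Equidistant flanks resolve to the earlier slot:
  deterministic, order-based, independent of sign.

## Agreement statistics

Signed differences are summarized by mean and SD (n−1 denominator throughout)
and by Bland–Altman bias ± 1.96 SD limits of agreement (multiplier
configurable), plotted against per-pair means. Because published "mean
difference" figures are ambiguous between signed and absolute conventions,
both are computed and labelled explicitly in every report.

The demographics table compares men and women per characteristic with a
normality-gated test: Shapiro–Wilk on each group at α = 0.05, then the
independent-samples Student t test (pooled variance by default, matching
legacy SPSS reporting; Welch available) if neither group rejects, otherwise
the Wilcoxon–Mann–Whitney rank-sum test. A constant group makes Shapiro–Wilk
inapplicable; the comparison then falls back to the rank-sum test and flags
it.

## Synthetic-data generator

No raw session data accompany published validations, so the generator
produces cohorts with the statistical structure the analysis assumes. Per
participant and quantity:

1. latent true level ~ Normal(mean, between-SD);
2. a within-subject random walk across the nine slots (step SD `drift_sd`),
   emulating reading-to-reading physiological variability;
3. reference slots observe latent + Normal(0, observer-noise SD);
4. test slots observe `a + b·latent` + Normal(0, device-noise SD).

Coherence is enforced after noise (DBP below SBP with a pulse-pressure floor,
HR clipped to its 40–180 beats/min plausibility window, SBP to the 0–300 mm Hg
device range), and readings are rounded to integers by default, as
oscillometric displays report them.

**Defaults** (chosen once, held fixed): demographics truncated-normal with the
means/SDs/ranges typical of a general-population validation cohort
(age 47.94 ± 17.21 years on 25–87, weight 72.45 ± 10.47 kg, height
167.06 ± 5.51 cm, arm circumference 285.76 ± 21.80 mm; 13 men / 20 women);
latent SBP ~ N(125, 15) mm Hg, DBP ~ N(75, 10) mm Hg, HR ~ N(72, 10)
beats/min; drift SD 2 / 1.5 / 1.5 per slot; observer noise SD 2 / 2 / 1;
additive device bias +3 / +3 mm Hg and +1.5 beats/min with multiplicative term
1; device noise SD 3.5 / 3.5 / 2.5. Under this model the signed
test-minus-reference difference has SD ≈ √(3.5² + 2² + 2²) ≈ 4.5 mm Hg and a
mean absolute difference ≈ 4.3 mm Hg, matching the agreement level reported
for validated consumer monitors (≈4.2, SD ≈4.5 mm Hg).

**Seeding.** One integer seed drives a hierarchical `SeedSequence` scheme: the
cohort seed spawns one child stream per participant, and draws within a
participant occur in a fixed slot order. The same seed reproduces the same
cohort exactly; replicate studies (`pass_probability`) spawn one child per
replicate.

**Parameter recovery.** `estimate_device_params` differences each test
reading against the *mean* of its two flanking reference readings. Under the
symmetric random-walk drift this estimator of the additive bias is unbiased,
whereas nearest-flank (minimum |difference|) selection shrinks the apparent
bias toward zero — the selection that makes grading lenient also biases naive
bias estimates, which is why the two pairings are kept distinct. Reported
standard errors treat differences as independent and therefore slightly
understate uncertainty (consecutive differences share a flank).

**What the generator does not emulate.** Real sessions exhibit cuff-induced
congestion trends, sex-specific anthropometry (a single distribution per
characteristic is used for both sexes), digit preference beyond integer
rounding, arrhythmia-driven outliers, and device failures/repeats. Passing the
simulation-based tests therefore demonstrates correctness of the pipeline's
statistics under its stated model, not device performance on real arms.

## Numerical and reporting choices

* Readings are stored as floats; the CSV contract accepts integers and
  fractions and applies no internal rounding. CSV serialization uses the
  shortest exact float representation, so write→read round-trips are
  value-identical.
* Grading refuses an ineligible cohort (fewer than 33 participants, <10 of
  either sex, under-25 participants, exclusion flags) unless forced; forced
  runs are flagged in the report. Cuff-fit (arm circumference 220–420 mm) is a
  warning, not an error, since it is a sizing step rather than an eligibility
  criterion.
* Reports are JSON-first (pydantic models; a JSON Schema ships in
  `eship2/schema/`), with text/markdown renderers and optional Bland–Altman
  PNGs; every verdict carries its full achieved-vs-required detail.
* Monte-Carlo pass probabilities report 95% Wilson intervals; interval bounds
  are clamped to bracket the point estimate against floating-point jitter.

## Problem sizes used in the test suite

Oracle-equivalence checks run on 10,000 random count vectors and 10,000
random sessions; Bland–Altman coverage on 10,000 simulated differences;
bias recovery on 100 replicate cohorts of 33; pass-probability curves on 200
replicates per bias level. These sizes give Monte-Carlo standard errors well
below the tolerances asserted while keeping the default suite around ten
seconds.

## Known limitations

* The entry-BP range-recruitment quotas of the full protocol are not
  implemented (out of scope); eligibility covers size, sex mix, age, and
  exclusion flags only.
* The reference device is treated abstractly as ground-truth readings; the
  two-observer auscultation arrangement of the original protocol is not
  modelled.
* The HR requirement rows are an extension by analogy, not part of the
  protocol itself.
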