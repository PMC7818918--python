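# Methods

## Scope and data model

`dropcover` analyzes dispensing-level pharmacy claims for topical glaucoma
therapy.  Its inputs are four delimited text tables: prescription claims
(patient, dispense date, generic name, dosage in mL, a months-like period
field), diagnoses (ICD-10), procedures (glaucoma surgery/laser flag) and
optional health-checkup covariates.  Dates are calendar dates without
times; every derived interval is half-open `[start, end)` in whole days,
which makes day counting unambiguous.  Generic names are the join key into
a drug dictionary shipped as an editable CSV (classes, fixed-combination
flag, unit bottle volume, dosing frequency); claims with unresolvable
names are a hard load error, since silently dropping products would bias
every downstream exposure quantity.  Unknown ICD-10 codes are retained but
ignored by the cohort filter, because claims extracts routinely carry
unrelated diagnoses.

Class pairs are always written in the canonical order PG < BB < CAI < AA
(so the dorzolamide/timolol pair is labeled `BB/CAI`).

## Exposure normalization

Claimed dosage and period fields for eye drops are unreliable, so exposure
is reconstructed from bottle arithmetic:

* bottles = dosage / unit bottle volume, rounded to the nearest integer
  and floored at 1 (2.5 mL bottles for once-daily formulations, 5 mL for
  twice-or-more-daily; a dosage more than 10 % off a bottle multiple is
  rounded with a warning);
* one bottle supplies 30 days for one eye — a month is 30 days everywhere
  in the package;
* a prescription of ≥ 7 bottles is read as treatment of both eyes.  The
  arithmetic consequence is not standardized anywhere we know of; the
  default halves the days supplied (supply consumed twice as fast), with a
  ceiling so a single bottle can never round to zero days.
  `both_eyes_policy="none"` disables the halving.
* the claim's period field is ignored for day counting; it is retained for
  audit only.

Refills dispensed before the previous supply is exhausted *stockpile*: the
new interval starts when the old supply ends, shifting rather than
truncating supply, so covered days are never double-counted and never
discarded.  A day-by-day bottle-stock simulation is the test oracle for
this arithmetic (several hundred random streams, plus a 1000-stream
acceptance check).

## Cohort extraction (new-user design)

A patient enters a cohort when all of the following hold within the study
window (default 2011-04-01 .. 2016-03-31):

1. a glaucoma diagnosis (ICD-10 H401 or H409) at any time — the source
   literature anchors the codes but not their timing, so no temporal
   restriction is imposed;
2. a monotherapy run-in: walking back from the index date, all claims are
   single-class monotherapy for ≥ 365 days.  Within-class product switches
   (e.g. latanoprost → tafluprost) are tolerated — the requirement is
   monotherapy, not a single product;
3. an index event: either the first fixed-combination dispensing (fixed
   cohort) or the first dispensing of a second distinct-class monotherapy
   product on a day the first drug's coverage interval still covers
   (unfixed cohort).  The overlap rule makes "added to" concrete.  If both
   events occur on the same day, fixed takes precedence (deterministic
   tie-break);
4. no glaucoma surgery or laser record strictly before index.

Patients with no claims activity in the 12 months after index are
*flagged* withdrawn, not dropped: dropping them would silently change the
denominator, and in the source design they indicate database withdrawal
rather than ineligibility.  Every exclusion increments a ledger keyed by
rule; `excluded + assigned = candidates` is asserted on every run.

## Adherence (PDC)

PDC (%) = total two-drug-therapy supply days inside `[index, index+365)` /
365 × 100, capped at 100.  Only two-drug therapy counts, regardless of
switching within it: for the fixed cohort a covered day is any day inside
any fixed-combination product's supply; for the unfixed cohort it is a day
on which two distinct-class monotherapy products are simultaneously
supplied.  The intersection rule is the default because the endpoint is
adherence to the two-drug regimen; `unfixed_day_rule="either"` exposes the
union reading.  Days from the first concurrent third drug class onward do
not count (therapy withdrawn).  The a-priori adherence cutpoint is 80 %,
with bins 80+, 60–79, 40–59, 20–39, < 20 (left-closed: 80.0 is adherent,
79.99 is not).

The 30-day grace period does **not** add covered days by default: PDC
counts prescription days, and crediting unsupplied days would inflate the
numerator beyond dispensed supply.  Because the source convention is
ambiguous on this point, `pdc_count_grace=True` implements the alternative
(each coverage gap and the trailing tail is credited up to 30 days).

## Persistence

A persistence episode runs from the index date until the first of:

* **refill gap** — supply exhausted and the next qualifying supply starts
  more than 30 days later (exactly 30 days continues the episode; the
  30-day grace mirrors the ~4-week use-by period of an opened bottle).
  The event time is the last covered day (last prescription date + its
  prescription days), not the end of the grace window;
* **third-drug addition** — a third class becomes concurrently supplied;
  event at the addition day.  A same-day tie with a gap resolves to the
  third-drug reason (deterministic);
* **any switch or change** away from the index products — only in
  `subset` mode, used for single-product (e.g. latanoprost/timolol) or
  single-class-pair analyses.  The default `class` mode continues the
  episode across switches between two-drug regimens.

Whether the original gap clock was anchored at supply end or at the
dispense date is not stated anywhere; both are implemented
(`gap_anchor="supply_end"` default, `"dispense"` re-anchors at each
dispense date plus that claim's own days supplied, ignoring stockpile —
for the unfixed cohort this variant falls back to joint-coverage
anchoring, a documented roughness).  Patients still on therapy at 12
months are censored at 365 days.

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines`; pointwise 95 % CIs use the complementary log-log
(exponential Greenwood) transform, which is stable near survival 0 and 1.
Hall–Wellner simultaneous bands are out of scope.  Tests pin the estimator
to hand-computed product-limit values (1e-12) and the log-rank statistic
to a risk-set enumeration oracle.

## Switching patterns

Each patient's post-index trajectory is classified by the first qualifying
transition: `continued_same_class`, `switched_two_drug:<pair>`,
`addon_third:<class>`, or `discontinued_all` (all eye-drop supply ceases
beyond the grace period with no later claims).  "Concurrent" is coverage
overlap, the same rule the cohort builder uses for the unfixed index
event.  Categories are exhaustive and mutually exclusive by construction;
a property test checks this on random synthetic cohorts.

## Statistical battery

Mean PDC comparisons use Welch's t-test by default (the cohort SDs differ
by construction; `ttest_equal_var=True` gives the pooled variant).
Adherent proportions use Pearson's χ² on the 2×2 table without continuity
correction.  Multiplicity over the nine planned comparisons is controlled
by Bonferroni: threshold 0.05/9 ≈ 0.00556.  The nonadherence (PDC < 80 %)
risk-factor screen fits one univariate logistic model per covariate
(complete-case per variable; categorical covariates as dummies against the
most frequent level, likelihood-ratio p per variable), passes candidates
with P < 0.1 to a stepwise forward/backward logistic selection
(entry 0.05 / stay 0.05 — the common default of the originating stats
environment, configurable), and reports odds ratios with Wald 95 % CIs.
Perfect separation or non-convergence excludes a variable with a warning.
Degenerate 2×2 tables (empty margin) return p = 1: there is no discordance
to test.

## Synthetic data generator

The generator emulates the structure the analysis assumes — it defines the
study conditions for all recovery tests and is not tuned per test:

* cohort sizes default to 309 fixed / 329 unfixed; index-regimen class
  mixes follow the published distribution (fixed: PG/BB 78 %, BB/CAI 22 %;
  unfixed: PG+BB 39.5 %, PG+AA 26.4 %, PG+CAI 14.3 %, remainder split
  between BB+CAI and BB+AA), with product choices weighted toward
  latanoprost-based regimens;
* each patient draws a latent nonadherent type from a logistic model in
  HbA1c: logit P(nonadherent) = α_cohort + log(1.606)·(HbA1c − 5.6).  The
  intercept is calibrated by Gauss–Hermite quadrature so the marginal
  nonadherence rate matches the published bin profile (30.4 % fixed,
  51.4 % unfixed).  Adherent patients refill to the end of the window with
  zero-inflated-geometric delays (on-time probability 0.7, mean delay 4
  days); nonadherent patients draw a PDC bin from the published
  conditional profile and stop after the corresponding number of 30-day
  bottles (on-time 0.3, mean delay 10 days).  Whole-bottle quantization
  keeps planted PDC safely inside its bin, so the latent type is
  essentially never misclassified at the 80 % cutpoint and the planted
  odds ratio is recoverable without attenuation;
* the monotherapy run-in (365 + 10..180 days) uses a component class of
  the index regimen; for the unfixed cohort both components are dispensed
  at the same visits thereafter, so the joint two-class coverage equals
  the added drug's schedule.  Synchronized dispensing is a simplification
  of real refill behavior (components can desynchronize), one of several
  features of real data the generator does not emulate — along with
  seasonality, enrollment gaps, pricing and realistic Japanese claim
  coding — so passing recovery tests demonstrates pipeline correctness,
  not real-world effect sizes;
* covariates are independent normals/Bernoullis at the published
  means/SDs with per-variable missingness; only the HbA1c–adherence link
  is planted.  Missingness is noninformative;
* `contamination` plants decoy patients violating each inclusion rule
  (short run-in, prior surgery, monotherapy only, no glaucoma diagnosis)
  to exercise the cohort filter; defaults to none;
* `dropout_hazard` (extra per-cycle stopping for adherent patients) and
  `addon_third_class_prob` (third-class add-on trajectories) default to
  0.0 so the planted adherence profile is exact; tests that need add-on
  trajectories turn the knob on explicitly;
* ground truth (true covered days, PDC, adherent flag, discontinuation
  day and reason) is computed by day-bitmap arithmetic on the planted
  supply intervals — deliberately a different algorithm from the
  pipeline's interval sweep, so truth-vs-pipeline equality is a real
  cross-check.  Identical (config, seed) produces byte-identical output.

Published five-bin percentage profiles sum to 99.9/100.0 because of
printed rounding; profiles within 0.5 % of 1 are renormalized exactly.

## Numerical choices and problem sizes

Intervals are integer ordinal days; all interval algebra (union, clip,
k-of-n sweep) is exact.  Bottle rounding uses round-half-up on a positive
quantity.  The Kaplan–Meier hand fixtures are checked to 1e-12; χ² against
the closed form to 1e-9.  Recovery tests use the sizes a desk-scale run
affords: the HbA1c odds-ratio recovery runs one synthetic cohort of
n = 10,000 (±15 % tolerance covers the Monte-Carlo spread at that n); the
family-wise-error check uses 500 null replicates of the nine-test battery
at n = 200 per cohort — large enough that every subset 2×2 table meets the
Pearson χ² expected-count validity condition, so the check measures the
battery rather than small-sample distortion; stepwise-selection stability
uses 30 seeded replicates at n = 5,000.

## Known limitations

* Eye-level laterality is inferred only through the ≥ 7-bottle rule; no
  per-eye tracking.
* The geography covariate is an opaque three-level categorical, not the
  full prefecture/region/city-size hierarchy.
* Enrollment and eligibility gaps are not modeled; absence of claims is
  read as absence of therapy.
* The `dispense` gap anchor for unfixed-cohort episodes falls back to
  joint-coverage anchoring.
* Real-data effect sizes (mean PDCs, persistence rates) from the source
  population are not reproducible from synthetic data and are not claimed;
  the pipeline's checkable surface is its arithmetic, its rules, and
  parameter recovery under planted conditions.
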