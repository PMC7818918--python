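# dropcover

Adherence and persistence analysis of **fixed- versus unfixed-combination
glaucoma eye drops** from longitudinal pharmacy-claims data.

## The problem

Glaucoma therapy usually starts with one intraocular-pressure-lowering eye
drop — a prostaglandin analog (PG), β-blocker (BB), carbonic anhydrase
inhibitor (CAI) or α2-agonist (AA).  When monotherapy is insufficient a
second class is added, either as a *fixed combination* (two classes
co-formulated in one bottle, e.g. latanoprost/timolol) or an *unfixed
combination* (two separate bottles).  Whether patients stay on these
second-line regimens is a central question for claims-database
pharmacoepidemiology, and answering it from dispensing records requires a
stack of bespoke conventions: bottle-volume exposure normalization,
stockpile handling, grace periods, and new-user cohort extraction.

`dropcover` implements that stack as a tested, reusable pipeline for
epidemiologists working with dispensing-level claims extracts:

* **claims model** — typed claims/diagnosis/procedure records and an
  extensible ophthalmic drug dictionary (generic name → classes, fixed
  flag, bottle volume, dosing frequency);
* **cohort builder** — new-user design: ICD-10 H401/H409 diagnosis filter,
  ≥ 365-day single-class monotherapy run-in, index date at the first
  fixed-combination claim or first concurrent second-class claim, surgery
  and short-run-in exclusions, with a full exclusion ledger;
* **exposure engine** — dosage (mL) → bottles → days supplied
  (1 bottle = 30 days; ≥ 7 bottles = both eyes treated, days halved) and
  carry-forward coverage intervals that never double-count stockpiled
  supply;
* **adherence metrics** — proportion of days covered,
  `PDC (%) = covered days in [index, index+365) / 365 × 100`, with the
  a-priori 80 % adherence cutpoint and the 80+/60–79/40–59/20–39/<20 bins;
* **persistence analysis** — episodes with a 30-day refill grace period,
  third-drug-addition withdrawal, Kaplan–Meier product-limit curves with
  complementary log-log pointwise CIs, and two-group log-rank tests
  (`persistence rate (%) = 100 % − cumulative discontinuation rate`);
* **switching patterns** — trajectory taxonomy (continued same class /
  switched two-drug regimen / third-class add-on / discontinued all);
* **risk-factor analysis** — Welch t-tests, Pearson χ² on 2×2 tables,
  Bonferroni control (m = 9, threshold 0.05/9 = 0.00556), univariate
  logistic screen at P < 0.1 and stepwise multivariate logistic regression
  with odds ratios and Wald 95 % CIs;
* **synthetic claims generator** — a deterministic simulator of the study
  population (309 fixed / 329 unfixed patients, published regimen mixes
  and PDC-bin profiles, an HbA1c→nonadherence odds ratio of 1.606, decoy
  patients violating each inclusion rule) with a planted ground-truth
  table for parameter-recovery testing.

## Worked example

```python
from dropcover import RunConfig, SyntheticConfig, run_all

result = run_all(RunConfig(simulate=SyntheticConfig(seed=7), seed=7))
print(result.adherence_summary[["n", "pdc_mean", "adherent_pct"]].round(1))
```

```
           n  pdc_mean  adherent_pct
group
all      638      69.8          57.4
fixed    309      76.0          66.0
unfixed  329      64.0          49.2
```

The cohort builder recovered exactly the 309/329 patients the generator
planted (`result.ledger`), mean PDC is ~12 points higher under the fixed
combination, and 66 % vs 49 % of patients reach the 80 % adherence
cutpoint.  Persistence separates the same way —

```
fixed    persistence 180 d 75.4 %, 365 d 64.7 %
unfixed  persistence 180 d 61.4 %, 365 d 47.7 %
log-rank chi2 19.78, p 8.7e-06
```

— and the risk-factor screen retains exactly the two planted effects:
treatment (fixed vs unfixed, multivariate OR 0.48, 95 % CI 0.33–0.72) and
HbA1c (OR 1.91 per 1 %, CI 1.32–2.77, planted OR 1.606; single-run Wald
noise at n = 638).  All other covariates are generated as independent
noise and screen out.

The same run is available from the shell, writing publication-shaped
delimited tables, Kaplan–Meier tables and plot, the exclusion ledger and a
YAML run log with the seed and every policy flag:

```bash
dropcover run-all --seed 7 --outdir out/
dropcover simulate --seed 3 --outdir data/     # tables only
dropcover cohort --claims data/claims.csv --dx data/diagnoses.csv \
    --px data/procedures.csv --out assign.csv --ledger ledger.csv
```

Policy points the literature leaves open are explicit flags with
documented defaults: `both_eyes_policy` (halve | none), `unfixed_day_rule`
(both | either), `pdc_count_grace`, `gap_anchor` (supply_end | dispense),
persistence `--mode` (class | subset), t-test variant and stepwise
thresholds.

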