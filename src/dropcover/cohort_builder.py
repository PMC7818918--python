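"""New-user cohort extraction for second-line glaucoma therapy.

Reproduces the study's patient-extraction flowchart on any claims extract:

1. glaucoma diagnosis filter (ICD-10 H401 / H409);
2. >= 365 days of single-class monotherapy run-in immediately before index;
3. index date = first fixed-combination dispensing (fixed cohort) or first
   date a second distinct-class monotherapy product is dispensed while the
   first is still covered (unfixed cohort); a same-day tie resolves to the
   fixed cohort;
4. no glaucoma surgery / laser record before index;
5. patients with no claims activity in the 12 months after index are kept
   but flagged withdrawn rather than silently dropped.

Every removal is counted in an exclusion ledger so the flowchart structure
is auditable; assigned + excluded always equals the candidate count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from itertools import groupby
from typing import Iterable, Sequence

from .claims_model import (
    GLAUCOMA_ICD10,
    STUDY_WINDOW,
    DiagnosisRecord,
    DrugDictionary,
    PharmacyClaim,
    ProcedureRecord,
    canonical_classes,
)
from .exposure_engine import Interval, intervals_cover, patient_coverage

log = logging.getLogger(__name__)

POST_INDEX_DAYS = 365
RUN_IN_DAYS = 365

EXCLUSION_KEYS = (
    "no_glaucoma_diagnosis",
    "no_second_line_therapy",
    "pre_index_monotherapy_lt_12mo",
    "prior_glaucoma_surgery",
)


@dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    cohort: str  # "fixed" | "unfixed"
    index_date: date
    index_regimen: str
    pre_index_monotherapy_days: int
    index_products: tuple[str, ...] = ()
    withdrawn: bool = False

    def __post_init__(self) -> None:
        if self.cohort not in ("fixed", "unfixed"):
            raise ValueError(f"bad cohort {self.cohort!r}")
        if self.index_regimen.startswith("fixed:") != (self.cohort == "fixed"):
            raise ValueError("index_regimen kind must match cohort")
        if self.pre_index_monotherapy_days < RUN_IN_DAYS:
            raise ValueError("pre-index monotherapy run-in shorter than 12 months")


def _find_index_event(
    claims: Sequence[PharmacyClaim],
    coverage: dict[str, list[Interval]],
    dictionary: DrugDictionary,
):
    """First qualifying second-line event, scanning claims chronologically.

    Returns (index_ordinal, cohort, class_pair, index_products) or None.
    Fixed-combination claims take precedence within a day.
    """
    mono_cov: dict[str, list[Interval]] = {}
    for name, ivs in coverage.items():
        entry = dictionary.resolve(name)
        if not entry.is_fixed_combination:
            cls = next(iter(entry.drug_classes))
            mono_cov.setdefault(cls, []).extend(ivs)

    for day, day_claims in groupby(claims, key=lambda c: c.dispense_date.toordinal()):
        day_claims = list(day_claims)
        for c in day_claims:
            entry = dictionary.resolve(c.generic_name)
            if entry.is_fixed_combination:
                pair = canonical_classes(entry.drug_classes)
                return day, "fixed", pair, (c.generic_name,)
        for c in day_claims:
            entry = dictionary.resolve(c.generic_name)
            cls = next(iter(entry.drug_classes))
            for other_cls, ivs in mono_cov.items():
                if other_cls == cls:
                    continue
                merged = sorted(ivs)
                if intervals_cover(merged, day):
                    partner = _active_product(claims, dictionary, other_cls, day)
                    pair = canonical_classes((cls, other_cls))
                    products = tuple(p for p in (partner, c.generic_name) if p)
                    return day, "unfixed", pair, products
    return None


def _active_product(
    claims: Sequence[PharmacyClaim], dictionary: DrugDictionary, drug_class: str, day: int
) -> str | None:
    """Most recently dispensed monotherapy product of ``drug_class`` on ``day``."""
    best = None
    for c in claims:
        if c.dispense_date.toordinal() > day:
            break
        entry = dictionary.resolve(c.generic_name)
        if not entry.is_fixed_combination and drug_class in entry.drug_classes:
            best = c.generic_name
    return best


def _run_in_days(
    claims: Sequence[PharmacyClaim], dictionary: DrugDictionary, index_ord: int
) -> int:
    """Length in days of the single-class monotherapy run ending at index.

    Walks backwards from the index through claims, accepting only
    monotherapy claims of one drug class (within-class product switches are
    tolerated); returns index minus the earliest date of that run, or 0 if
    the patient has a pre-index combination claim or a second class inside
    the run.
    """
    pre = [c for c in claims if c.dispense_date.toordinal() < index_ord]
    if not pre:
        return 0
    run_class: str | None = None
    run_start = index_ord
    for c in reversed(pre):
        entry = dictionary.resolve(c.generic_name)
        if entry.is_fixed_combination:
            break
        cls = next(iter(entry.drug_classes))
        if run_class is None:
            run_class = cls
        if cls != run_class:
            break
        run_start = c.dispense_date.toordinal()
    # any disqualifying claim inside the trailing 365-day span voids the run-in
    span_lo = index_ord - RUN_IN_DAYS
    for c in pre:
        o = c.dispense_date.toordinal()
        if o < span_lo:
            continue
        entry = dictionary.resolve(c.generic_name)
        if entry.is_fixed_combination or next(iter(entry.drug_classes)) != run_class:
            return 0
    return index_ord - run_start


def build_cohorts(
    claims: Sequence[PharmacyClaim],
    diagnoses: Iterable[DiagnosisRecord],
    procedures: Iterable[ProcedureRecord],
    dictionary: DrugDictionary | None = None,
    window: tuple[date, date] = STUDY_WINDOW,
    *,
    both_eyes_policy: str = "halve",
) -> tuple[list[CohortAssignment], dict[str, int]]:
    """Assign patients to the fixed / unfixed cohorts with an exclusion ledger."""
    if not claims:
        raise ValueError("empty claims table")
    dictionary = dictionary or DrugDictionary.default()
    w0, w1 = window[0].toordinal(), window[1].toordinal() + 1

    by_patient: dict[str, list[PharmacyClaim]] = {}
    for c in claims:
        if w0 <= c.dispense_date.toordinal() < w1:
            by_patient.setdefault(c.patient_id, []).append(c)

    diagnosed = {
        d.patient_id for d in diagnoses if d.icd10_code in GLAUCOMA_ICD10
    }
    first_surgery: dict[str, int] = {}
    for p in procedures:
        if p.is_glaucoma_surgery_or_laser:
            o = p.date.toordinal()
            if p.patient_id not in first_surgery or o < first_surgery[p.patient_id]:
                first_surgery[p.patient_id] = o

    ledger: dict[str, int] = {k: 0 for k in EXCLUSION_KEYS}
    ledger.update(candidates=0, assigned_fixed=0, assigned_unfixed=0, withdrawn_flagged=0)
    assignments: list[CohortAssignment] = []

    for pid in sorted(by_patient):
        pclaims = sorted(by_patient[pid], key=lambda c: c.dispense_date)
        ledger["candidates"] += 1
        if pid not in diagnosed:
            ledger["no_glaucoma_diagnosis"] += 1
            continue
        coverage = patient_coverage(pclaims, dictionary, both_eyes_policy=both_eyes_policy)
        event = _find_index_event(pclaims, coverage, dictionary)
        if event is None:
            ledger["no_second_line_therapy"] += 1
            continue
        index_ord, cohort, pair, products = event
        run_days = _run_in_days(pclaims, dictionary, index_ord)
        if run_days < RUN_IN_DAYS:
            ledger["pre_index_monotherapy_lt_12mo"] += 1
            continue
        if pid in first_surgery and first_surgery[pid] < index_ord:
            ledger["prior_glaucoma_surgery"] += 1
            continue
        withdrawn = not any(
            index_ord < c.dispense_date.toordinal() <= index_ord + POST_INDEX_DAYS
            for c in pclaims
        )
        label = (
            f"fixed:{pair[0]}/{pair[1]}" if cohort == "fixed" else f"unfixed:{pair[0]}+{pair[1]}"
        )
        assignments.append(
            CohortAssignment(
                patient_id=pid,
                cohort=cohort,
                index_date=date.fromordinal(index_ord),
                index_regimen=label,
                pre_index_monotherapy_days=run_days,
                index_products=products,
                withdrawn=withdrawn,
            )
        )
        ledger[f"assigned_{cohort}"] += 1
        if withdrawn:
            ledger["withdrawn_flagged"] += 1

    assert (
        sum(ledger[k] for k in EXCLUSION_KEYS)
        + ledger["assigned_fixed"]
        + ledger["assigned_unfixed"]
        == ledger["candidates"]
    )
    return assignments, ledger
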