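"""Proportion of days covered (PDC) over the 12-month post-index window.

PDC (%) = total two-drug-therapy supply days inside the 365-day assessment
window / 365 x 100, capped at 100.  Only the two-drug regimen counts,
regardless of class switching within it: for the fixed cohort a covered day
is any day inside a fixed-combination product's supply; for the unfixed
cohort it is a day on which two distinct-class monotherapy products are
both supplied (intersection; switchable to union with
``unfixed_day_rule="either"``).  Days from the first concurrent third drug
class onward do not count (therapy withdrawn).  The 30-day refill grace
period affects persistence only and adds no covered days by default
(``pdc_count_grace=True`` exposes the alternative reading).

The a-priori adherence cutpoint is PDC >= 80%, with summary bins
80+, 60-79, 40-59, 20-39, < 20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims_model import DrugDictionary
from .cohort_builder import CohortAssignment, POST_INDEX_DAYS
from .exposure_engine import (
    Interval,
    class_coverage,
    clip_intervals,
    merge_intervals,
    sweep_at_least,
    total_days,
)

log = logging.getLogger(__name__)

ADHERENCE_CUTPOINT = 80.0
BINS = ("80+", "60-79", "40-59", "20-39", "<20")
GRACE_DAYS = 30


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    cohort: str
    pdc_percent: float
    adherent: bool
    bin: str

    def __post_init__(self) -> None:
        if bin_adherence(self.pdc_percent) != self.bin:
            raise ValueError("bin inconsistent with pdc_percent")
        if self.adherent != (self.bin == "80+"):
            raise ValueError("adherent flag inconsistent with bin")


def bin_adherence(pdc_percent: float) -> str:
    """Map a PDC percentage to its summary bin (80+ means >= 80, etc.)."""
    if not 0 <= pdc_percent <= 100:
        raise ValueError(f"PDC {pdc_percent} outside [0, 100]")
    if pdc_percent >= 80:
        return "80+"
    if pdc_percent >= 60:
        return "60-79"
    if pdc_percent >= 40:
        return "40-59"
    if pdc_percent >= 20:
        return "20-39"
    return "<20"


def regimen_coverage(
    coverage: dict[str, list[Interval]],
    cohort: str,
    dictionary: DrugDictionary,
    *,
    unfixed_day_rule: str = "both",
) -> list[Interval]:
    """Days on which the two-drug therapy is supplied, as merged intervals."""
    if cohort == "fixed":
        ivs: list[Interval] = []
        for name, drug_ivs in coverage.items():
            if dictionary.resolve(name).is_fixed_combination:
                ivs.extend(drug_ivs)
        return merge_intervals(ivs)
    if unfixed_day_rule not in ("both", "either"):
        raise ValueError(f"unknown unfixed_day_rule {unfixed_day_rule!r}")
    mono_by_class: dict[str, list[Interval]] = {}
    for name, drug_ivs in coverage.items():
        entry = dictionary.resolve(name)
        if not entry.is_fixed_combination:
            cls = next(iter(entry.drug_classes))
            mono_by_class.setdefault(cls, []).extend(drug_ivs)
    k = 2 if unfixed_day_rule == "both" else 1
    return sweep_at_least(mono_by_class.values(), k)


def third_class_day(
    coverage: dict[str, list[Interval]], dictionary: DrugDictionary
) -> int | None:
    """First ordinal day on which >= 3 distinct drug classes are supplied."""
    by_class = class_coverage(coverage, dictionary)
    triple = sweep_at_least(by_class.values(), 3)
    return triple[0][0] if triple else None


def _extend_with_grace(intervals: list[Interval], hi: int, grace: int) -> list[Interval]:
    out: list[Interval] = []
    for i, (s, e) in enumerate(intervals):
        nxt = intervals[i + 1][0] if i + 1 < len(intervals) else hi
        out.append((s, min(e + grace, nxt, hi)))
    return merge_intervals(out)


def compute_pdc(
    coverage: dict[str, list[Interval]],
    assignment: CohortAssignment,
    dictionary: DrugDictionary | None = None,
    *,
    unfixed_day_rule: str = "both",
    pdc_count_grace: bool = False,
    grace_days: int = GRACE_DAYS,
) -> AdherenceResult:
    """Per-patient PDC over [index, index + 365)."""
    if assignment is None:
        raise ValueError("assignment required")
    dictionary = dictionary or DrugDictionary.default()
    lo = assignment.index_date.toordinal()
    hi = lo + POST_INDEX_DAYS
    t3 = third_class_day(coverage, dictionary)
    if t3 is not None:
        hi = min(hi, max(lo, t3))
    ivs = clip_intervals(
        regimen_coverage(coverage, assignment.cohort, dictionary, unfixed_day_rule=unfixed_day_rule),
        lo,
        hi,
    )
    if pdc_count_grace:
        ivs = _extend_with_grace(ivs, hi, grace_days)
    pdc = min(100.0, total_days(ivs) / POST_INDEX_DAYS * 100.0)
    b = bin_adherence(pdc)
    return AdherenceResult(
        patient_id=assignment.patient_id,
        cohort=assignment.cohort,
        pdc_percent=pdc,
        adherent=b == "80+",
        bin=b,
    )


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """A count as a percentage of a total, rounded for display (e.g. 58.8)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def summarize_adherence(results: Iterable[AdherenceResult]) -> pd.DataFrame:
    """Cohort-level adherence summary shaped like the study's Table 2.

    One row per cohort plus an ``all`` row: n, mean and SD of PDC, adherent
    count/percentage, and count/percentage per PDC bin.
    """
    results = list(results)
    groups: dict[str, list[AdherenceResult]] = {}
    for r in results:
        groups.setdefault(r.cohort, []).append(r)
    if not groups:
        raise ValueError("no adherence results to summarize")
    if len(groups) > 1:
        groups = {"all": results, **dict(sorted(groups.items()))}

    rows = []
    for name, rs in groups.items():
        if not rs:
            log.warning("cohort %s empty; omitted from adherence summary", name)
            continue
        pdc = np.array([r.pdc_percent for r in rs], dtype=float)
        n = len(rs)
        row = {
            "group": name,
            "n": n,
            "pdc_mean": float(pdc.mean()),
            "pdc_sd": float(pdc.std(ddof=1)) if n > 1 else 0.0,
            "adherent_n": sum(r.adherent for r in rs),
            "adherent_pct": percent(sum(r.adherent for r in rs), n),
        }
        for b in BINS:
            nb = sum(r.bin == b for r in rs)
            row[f"bin_{b}_n"] = nb
            row[f"bin_{b}_pct"] = percent(nb, n)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def adherence_frame(results: Sequence[AdherenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "cohort": [r.cohort for r in results],
            "pdc_percent": [r.pdc_percent for r in results],
            "adherent": [r.adherent for r in results],
            "bin": [r.bin for r in results],
        }
    ).set_index("patient_id")
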