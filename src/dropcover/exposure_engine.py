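"""Exposure normalization: claim quantities -> bottles -> coverage intervals.

Claims report a dosage in mL and a months-like period field that is not
reliable for day counting.  Exposure is therefore normalized through bottle
arithmetic: the dosage is divided by the approved unit bottle volume
(2.5 mL once-daily, 5 mL otherwise) to get a bottle count, one bottle is
equated to 30 days of supply for one eye, and a prescription of >= 7
bottles is read as treatment of both eyes (supply consumed twice as fast,
days halved with ceiling; switch off with ``both_eyes_policy="none"``).

Coverage intervals are half-open ``[start, end)`` integer day ranges
(``date.toordinal()`` units).  Early refills stockpile: a refill arriving
before the previous supply ends starts when that supply ends, so covered
days are never double-counted.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from .claims_model import DrugDictionary, DrugEntry, PharmacyClaim

log = logging.getLogger(__name__)

Interval = tuple[int, int]

DAYS_PER_BOTTLE = 30
BOTH_EYES_BOTTLE_THRESHOLD = 7


# ---------------------------------------------------------------------------
# Interval primitives (ordinal-day arithmetic shared by the whole pipeline)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals; contiguous pieces are coalesced."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def clip_intervals(intervals: Iterable[Interval], lo: int, hi: int) -> list[Interval]:
    return [(max(s, lo), min(e, hi)) for s, e in intervals if max(s, lo) < min(e, hi)]


def total_days(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intervals_cover(intervals: Sequence[Interval], day: int) -> bool:
    """True if ``day`` lies inside one of the (merged, sorted) intervals."""
    i = bisect_right(intervals, (day, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= day < intervals[i][1]


def sweep_at_least(interval_sets: Iterable[Sequence[Interval]], k: int) -> list[Interval]:
    """Days on which at least ``k`` of the given interval sets are active.

    Each member set is merged first, so it contributes at most one unit of
    depth per day (a set typically represents one drug class).
    """
    events: list[tuple[int, int]] = []
    for ivs in interval_sets:
        for s, e in merge_intervals(ivs):
            events.append((s, +1))
            events.append((e, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    start: int | None = None
    for day, delta in events:
        prev = depth
        depth += delta
        if prev < k <= depth:
            start = day
        elif prev >= k > depth and start is not None:
            out.append((start, day))
            start = None
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedDispensing:
    patient_id: str
    dispense_date: date
    generic_name: str
    bottles: int
    both_eyes: bool
    days_supplied: int


@dataclass(frozen=True)
class CoverageInterval:
    patient_id: str
    drug_key: str
    start: date
    end: date  # half-open


def normalize(
    claim: PharmacyClaim, entry: DrugEntry, *, both_eyes_policy: str = "halve"
) -> NormalizedDispensing:
    """Convert one claim into bottles and days supplied.

    Bottles are the dosage divided by the unit bottle volume, rounded to the
    nearest integer and floored at 1; a dosage more than 10% off a bottle
    multiple is rounded with a warning.  One bottle supplies 30 days; >= 7
    bottles flags both-eyes treatment and, under the default ``halve``
    policy, divides the days supplied by two (with ceiling).
    """
    if both_eyes_policy not in ("halve", "none"):
        raise ValueError(f"unknown both_eyes_policy {both_eyes_policy!r}")
    unit = entry.unit_bottle_volume
    bottles = max(1, int(claim.dosage_quantity / unit + 0.5))
    if abs(claim.dosage_quantity - bottles * unit) > 0.1 * unit:
        log.warning(
            "claim %s/%s: dosage %.3g mL is not a near-multiple of the %.2g mL bottle; "
            "rounding to %d bottle(s)",
            claim.patient_id, claim.generic_name, claim.dosage_quantity, unit, bottles,
        )
    both_eyes = bottles >= BOTH_EYES_BOTTLE_THRESHOLD
    days = bottles * DAYS_PER_BOTTLE
    if both_eyes and both_eyes_policy == "halve":
        days = -(-days // 2)
    return NormalizedDispensing(
        patient_id=claim.patient_id,
        dispense_date=claim.dispense_date,
        generic_name=claim.generic_name,
        bottles=bottles,
        both_eyes=both_eyes,
        days_supplied=days,
    )


def coverage_from_dispensings(dispensings: Iterable[tuple[int, int]]) -> list[Interval]:
    """Carry-forward coverage from (dispense_ordinal, days_supplied) pairs.

    A refill arriving before the running supply ends starts when it ends
    (stockpile shift, never truncation); the result is a merged disjoint
    interval list.
    """
    cursor: int | None = None
    out: list[Interval] = []
    for t, d in sorted(dispensings):
        start = t if cursor is None else max(t, cursor)
        out.append((start, start + d))
        cursor = start + d
    return merge_intervals(out)


def build_coverage(dispensings: Sequence[NormalizedDispensing]) -> list[CoverageInterval]:
    """Coverage intervals for one patient + drug key, as calendar dates."""
    if not dispensings:
        return []
    patient_ids = {d.patient_id for d in dispensings}
    drug_keys = {d.generic_name for d in dispensings}
    if len(patient_ids) > 1 or len(drug_keys) > 1:
        raise ValueError("build_coverage expects dispensings for one patient and one drug")
    ivs = coverage_from_dispensings(
        (d.dispense_date.toordinal(), d.days_supplied) for d in dispensings
    )
    pid, key = patient_ids.pop(), drug_keys.pop()
    return [
        CoverageInterval(pid, key, date.fromordinal(s), date.fromordinal(e)) for s, e in ivs
    ]


def patient_coverage(
    claims: Sequence[PharmacyClaim],
    dictionary: DrugDictionary,
    *,
    both_eyes_policy: str = "halve",
) -> dict[str, list[Interval]]:
    """Per-drug merged coverage intervals (ordinal days) for one patient."""
    by_drug: dict[str, list[tuple[int, int]]] = {}
    for claim in claims:
        nd = normalize(claim, dictionary.resolve(claim.generic_name), both_eyes_policy=both_eyes_policy)
        by_drug.setdefault(claim.generic_name, []).append(
            (claim.dispense_date.toordinal(), nd.days_supplied)
        )
    return {name: coverage_from_dispensings(disps) for name, disps in by_drug.items()}


def class_coverage(
    coverage: dict[str, list[Interval]], dictionary: DrugDictionary
) -> dict[str, list[Interval]]:
    """Merged coverage per drug class; fixed products feed both their classes."""
    by_class: dict[str, list[Interval]] = {}
    for name, ivs in coverage.items():
        for cls in dictionary.resolve(name).drug_classes:
            by_class.setdefault(cls, []).extend(ivs)
    return {cls: merge_intervals(ivs) for cls, ivs in by_class.items()}
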