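"""Classify 12-month post-index treatment trajectories.

Each patient falls into exactly one category, decided by the first
qualifying transition after the index date:

* ``continued_same_class`` - every post-index two-drug regimen maps to the
  index class pair;
* ``switched_two_drug:<pair>`` - a different two-class regimen appears
  (e.g. PG+BB to PG+CAI);
* ``addon_third:<class>`` - a third drug class becomes concurrently
  supplied (e.g. PG+BB to PG+BB+AA);
* ``discontinued_all`` - all eye-drop supply ceases (refill gap beyond the
  grace period) with no replacement.

"Concurrent" means overlapping coverage intervals, mirroring the overlap
rule the cohort builder uses for the unfixed index event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .claims_model import DrugDictionary, PharmacyClaim, canonical_classes, regimen_pair
from .cohort_builder import CohortAssignment, POST_INDEX_DAYS
from .exposure_engine import Interval, class_coverage, intervals_cover, merge_intervals
from .adherence_metrics import GRACE_DAYS, percent, third_class_day


@dataclass(frozen=True)
class SwitchPattern:
    patient_id: str
    index_regimen: str
    outcome_category: str


def classify_trajectory(
    claims: Sequence[PharmacyClaim],
    coverage: dict[str, list[Interval]],
    assignment: CohortAssignment,
    dictionary: DrugDictionary | None = None,
    *,
    grace_days: int = GRACE_DAYS,
    horizon: int = POST_INDEX_DAYS,
) -> SwitchPattern:
    """Assign one patient to a trajectory category (first transition wins)."""
    dictionary = dictionary or DrugDictionary.default()
    idx = assignment.index_date.toordinal()
    index_pair = set(regimen_pair(assignment.index_regimen))
    by_class = class_coverage(coverage, dictionary)

    candidates: list[tuple[int, int, str]] = []  # (day, precedence, category)

    # third-class add-on while the two-drug therapy is active
    t3 = third_class_day(coverage, dictionary)
    if t3 is not None and idx <= t3 < idx + horizon:
        added = [
            cls
            for cls in canonical_classes(by_class)
            if cls not in index_pair and intervals_cover(by_class[cls], t3)
        ]
        label = added[0] if added else "?"
        candidates.append((t3 - idx, 0, f"addon_third:{label}"))

    # switch to a different two-class regimen
    claims = sorted(claims, key=lambda c: (c.dispense_date, c.generic_name))
    for c in claims:
        day = c.dispense_date.toordinal()
        if day <= idx or day >= idx + horizon:
            continue
        entry = dictionary.resolve(c.generic_name)
        if entry.is_fixed_combination:
            pair = set(entry.drug_classes)
            if pair != index_pair:
                label = "/".join(canonical_classes(pair))
                candidates.append((day - idx, 1, f"switched_two_drug:{label}"))
                break
        else:
            cls = next(iter(entry.drug_classes))
            if cls in index_pair:
                continue
            active = {
                other
                for other, ivs in by_class.items()
                if other != cls and intervals_cover(ivs, day)
            }
            if index_pair <= active:
                continue  # full index pair still on board: an add-on, handled above
            retained = active & index_pair
            if retained:
                label = "+".join(canonical_classes(retained | {cls})[:2])
                candidates.append((day - idx, 1, f"switched_two_drug:{label}"))
                break

    # all eye-drop supply ceases without replacement
    union = merge_intervals(iv for ivs in coverage.values() for iv in ivs)
    tail = [e for s, e in union if s < idx + horizon]
    if tail:
        last_covered = max(tail)
        later_claims = [
            c for c in claims if last_covered < c.dispense_date.toordinal() < idx + horizon
        ]
        if last_covered < idx + horizon - grace_days and not later_claims:
            candidates.append((last_covered - idx, 2, "discontinued_all"))

    if not candidates:
        category = "continued_same_class"
    else:
        candidates.sort()
        category = candidates[0][2]
    return SwitchPattern(assignment.patient_id, assignment.index_regimen, category)


def pattern_table(patterns: Iterable[SwitchPattern]) -> pd.DataFrame:
    """Counts and percentages per index regimen x outcome category."""
    patterns = list(patterns)
    if not patterns:
        return pd.DataFrame(columns=["index_regimen", "outcome_category", "n", "pct"])
    rows = []
    frame = pd.DataFrame(
        {
            "index_regimen": [p.index_regimen for p in patterns],
            "outcome_category": [p.outcome_category for p in patterns],
        }
    )
    for regimen, grp in frame.groupby("index_regimen", sort=True):
        total = len(grp)
        for category, sub in grp.groupby("outcome_category", sort=True):
            rows.append(
                {
                    "index_regimen": regimen,
                    "outcome_category": category,
                    "n": len(sub),
                    "pct": percent(len(sub), total),
                }
            )
    return pd.DataFrame(rows)
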