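"""Therapy persistence: episodes, Kaplan-Meier curves, log-rank tests.

Persistence is the time in days from the index date to discontinuation of
the two-drug index therapy, with a 30-day grace period for refills (the
Japanese use-by recommendation for an opened bottle is about 4 weeks).
Discontinuation rules:

* a refill gap of *more than* 30 days after supply exhaustion ends the
  episode at the last covered day (supply end, i.e. last prescription date
  + prescription days) - a gap of exactly 30 days does not;
* addition of a third concurrent drug class ends it at the addition date
  (therapy withdrawn); a same-day tie with a gap resolves to the third-drug
  reason;
* in ``subset`` mode (used for single-product or single-class-pair
  analyses) any switch or change away from the index products ends it.

Patients still on therapy at 12 months are censored at 365 days.  The
Kaplan-Meier product-limit estimator (with complementary log-log pointwise
95% CIs, stable near 0 and 1) summarizes each cohort, and
persistence rate (%) = 100% - cumulative discontinuation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .claims_model import DrugDictionary, PharmacyClaim
from .cohort_builder import CohortAssignment, POST_INDEX_DAYS
from .exposure_engine import Interval, clip_intervals, merge_intervals, sweep_at_least
from .adherence_metrics import GRACE_DAYS, regimen_coverage, third_class_day

#: event-reason precedence for same-day ties (lower wins)
_REASON_RANK = {"third_drug_added": 0, "regimen_changed": 1, "gap": 2}


@dataclass(frozen=True)
class PersistenceResult:
    patient_id: str
    cohort: str
    duration_days: int
    event: bool  # True = discontinued, False = censored at 365
    reason: str = "none"  # gap | third_drug_added | regimen_changed | none

    def __post_init__(self) -> None:
        if not self.event and self.duration_days != POST_INDEX_DAYS:
            raise ValueError("censored episodes are censored at 365 days")
        if self.event and not 0 <= self.duration_days <= POST_INDEX_DAYS:
            raise ValueError("event day outside the 12-month horizon")
        if self.event == (self.reason == "none"):
            raise ValueError("reason must be none iff censored")


def _subset_coverage(
    coverage: dict[str, list[Interval]],
    assignment: CohortAssignment,
    dictionary: DrugDictionary,
) -> list[Interval]:
    """Supply intervals of the index products only (product-subset mode)."""
    keys = [k for k in assignment.index_products if k in coverage]
    if assignment.cohort == "fixed":
        return merge_intervals([iv for k in keys for iv in coverage[k]])
    return sweep_at_least([coverage[k] for k in keys], 2)


def build_episode(
    coverage: dict[str, list[Interval]],
    claims: Sequence[PharmacyClaim],
    assignment: CohortAssignment,
    dictionary: DrugDictionary | None = None,
    *,
    mode: str = "class",
    grace_days: int = GRACE_DAYS,
    gap_anchor: str = "supply_end",
    horizon: int = POST_INDEX_DAYS,
) -> PersistenceResult:
    """Scan one patient's post-index supply stream into a persistence episode.

    ``mode="class"`` continues the episode across switches between two-drug
    regimens; ``mode="subset"`` ends it on any prescription outside the
    index products.  ``gap_anchor`` selects whether the grace clock starts
    at supply end (default; stockpiled supply counts) or at the last
    dispense date plus that claim's own days supplied (``"dispense"``).
    """
    if mode not in ("class", "subset"):
        raise ValueError(f"unknown mode {mode!r}")
    if gap_anchor not in ("supply_end", "dispense"):
        raise ValueError(f"unknown gap_anchor {gap_anchor!r}")
    dictionary = dictionary or DrugDictionary.default()
    idx = assignment.index_date.toordinal()

    if mode == "class":
        q = regimen_coverage(coverage, assignment.cohort, dictionary)
    else:
        q = _subset_coverage(coverage, assignment, dictionary)
    q = [iv for iv in clip_intervals(q, idx, idx + 10 * horizon)]

    candidates: list[tuple[int, str]] = []

    # refill-gap rule on the qualifying supply stream
    if not q:
        candidates.append((0, "gap"))
    else:
        if q[0][0] - idx > grace_days:
            candidates.append((0, "gap"))
        else:
            cur_end = q[0][1]
            stopped = False
            for s, e in q[1:]:
                if cur_end - idx >= horizon:
                    stopped = True
                    break
                if s - cur_end > grace_days:
                    candidates.append((cur_end - idx, "gap"))
                    stopped = True
                    break
                cur_end = e
            if not stopped and cur_end - idx < horizon:
                candidates.append((cur_end - idx, "gap"))

    if gap_anchor == "dispense":
        # re-anchor the gap clock at each dispense date + its own supply,
        # ignoring stockpile carried over from earlier refills
        disp = _dispense_stream(claims, assignment, dictionary, mode, idx)
        candidates = [c for c in candidates if c[1] != "gap"]
        prev_end = None
        gap_day = None
        for t, d in disp:
            if prev_end is not None and t - prev_end > grace_days:
                gap_day = prev_end - idx
                break
            prev_end = t + d
        if gap_day is None and prev_end is not None and prev_end - idx < horizon:
            gap_day = prev_end - idx
        if not disp:
            gap_day = 0
        if gap_day is not None:
            candidates.append((max(0, gap_day), "gap"))

    t3 = third_class_day(coverage, dictionary)
    if t3 is not None and idx <= t3 < idx + horizon:
        candidates.append((t3 - idx, "third_drug_added"))

    if mode == "subset":
        allowed = set(assignment.index_products)
        for c in claims:
            o = c.dispense_date.toordinal()
            if o <= idx:
                continue
            if o >= idx + horizon:
                break
            if c.generic_name not in allowed:
                candidates.append((o - idx, "regimen_changed"))
                break

    candidates = [c for c in candidates if c[0] < horizon]
    if not candidates:
        return PersistenceResult(assignment.patient_id, assignment.cohort, horizon, False)
    day, reason = min(candidates, key=lambda c: (c[0], _REASON_RANK[c[1]]))
    return PersistenceResult(assignment.patient_id, assignment.cohort, day, True, reason)


def _dispense_stream(claims, assignment, dictionary, mode, idx):
    from .exposure_engine import normalize

    out = []
    allowed = set(assignment.index_products)
    for c in sorted(claims, key=lambda c: c.dispense_date):
        o = c.dispense_date.toordinal()
        if o < idx:
            continue
        entry = dictionary.resolve(c.generic_name)
        if mode == "subset":
            ok = c.generic_name in allowed
        elif assignment.cohort == "fixed":
            ok = entry.is_fixed_combination
        else:
            ok = not entry.is_fixed_combination
        if ok:
            out.append((o, normalize(c, entry).days_supplied))
    return out


@dataclass
class KMEstimate:
    """Product-limit persistence estimate for one group."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    persistence_rate_180: float
    persistence_rate_365: float
    fitter: KaplanMeierFitter = field(repr=False)

    def survival_at(self, t: float) -> float:
        return float(self.fitter.survival_function_at_times(t).iloc[0])

    def rate_at(self, t: float) -> float:
        """Persistence rate (%) = 100 - cumulative discontinuation rate."""
        return 100.0 * self.survival_at(t)


def km_fit(results: Sequence[PersistenceResult], *, alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier product-limit fit with pointwise complementary log-log CIs."""
    if not results:
        raise ValueError("no persistence results")
    durations = [r.duration_days for r in results]
    events = [r.event for r in results]
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=events, label="persistence")
    ci = kmf.confidence_interval_survival_function_
    est = KMEstimate(
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["persistence"].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        at_risk=kmf.event_table["at_risk"].to_numpy(dtype=float),
        persistence_rate_180=float("nan"),
        persistence_rate_365=float("nan"),
        fitter=kmf,
    )
    est.persistence_rate_180 = est.rate_at(180)
    est.persistence_rate_365 = est.rate_at(365)
    return est


def logrank(
    group_a: Sequence[PersistenceResult], group_b: Sequence[PersistenceResult]
) -> tuple[float, float]:
    """Two-group log-rank test on the 365-day horizon: (chi-square, p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(
        [r.duration_days for r in group_a],
        [r.duration_days for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)
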