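"""Persistence episodes, Kaplan-Meier estimates and log-rank comparisons."""

import numpy as np
import pytest

from conftest import claim, day, km_hand, logrank_hand
from dropcover.cohort_builder import CohortAssignment
from dropcover.exposure_engine import patient_coverage
from dropcover.persistence_analysis import (
    PersistenceResult,
    build_episode,
    km_fit,
    logrank,
)


def fixed_assignment(pid="P"):
    return CohortAssignment(pid, "fixed", day(0), "fixed:PG/BB", 400, ("latanoprost/timolol",))


def unfixed_assignment(pid="P"):
    return CohortAssignment(pid, "unfixed", day(0), "unfixed:PG+BB", 400,
                            ("latanoprost", "timolol"))


def episode(claims, assignment, dictionary, **kw):
    claims = sorted(claims, key=lambda c: c.dispense_date)
    cov = patient_coverage(claims, dictionary)
    return build_episode(cov, claims, assignment, dictionary, **kw)


def test_continuous_refills_censored_at_365(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 365, 30)]
    r = episode(claims, fixed_assignment(), dictionary)
    assert (r.duration_days, r.event, r.reason) == (365, False, "none")


def test_gap_over_30_days_discontinues_at_supply_end(dictionary):
    # supply [0,120), next refill day 160: 40-day gap
    claims = [claim("P", t, "latanoprost/timolol") for t in (0, 30, 60, 90)]
    claims.append(claim("P", 160, "latanoprost/timolol"))
    r = episode(claims, fixed_assignment(), dictionary)
    assert (r.duration_days, r.event, r.reason) == (120, True, "gap")


def test_gap_of_exactly_30_days_continues(dictionary):
    claims = [claim("P", t, "latanoprost/timolol", 4) for t in (0, 150, 300)]
    r = episode(claims, fixed_assignment(), dictionary)
    assert not r.event  # two gaps of exactly 30 days; supply reaches past 365
    late = [claim("P", 0, "latanoprost/timolol", 4), claim("P", 151, "latanoprost/timolol", 4)]
    r31 = episode(late, fixed_assignment(), dictionary)
    assert (r31.duration_days, r31.event) == (120, True)  # 31-day gap discontinues


def test_supply_ending_early_without_refill_is_an_event(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in (0, 30, 60)]
    r = episode(claims, fixed_assignment(), dictionary)
    assert (r.duration_days, r.event) == (90, True)


def test_third_class_addition_ends_episode(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 365, 30)]
    claims.append(claim("P", 200, "brimonidine"))
    r = episode(claims, fixed_assignment(), dictionary)
    assert (r.duration_days, r.event, r.reason) == (200, True, "third_drug_added")


def test_unfixed_component_lapse_discontinues(dictionary):
    # PG keeps going, BB stops at day 120: joint coverage ends there
    claims = [claim("P", t, "latanoprost") for t in range(0, 365, 30)]
    claims += [claim("P", t, "timolol") for t in (0, 30, 60, 90)]
    r = episode(claims, unfixed_assignment(), dictionary)
    assert (r.duration_days, r.event, r.reason) == (120, True, "gap")


def test_class_mode_survives_regimen_switch_subset_mode_does_not(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 180, 30)]
    claims += [claim("P", t, "dorzolamide/timolol") for t in range(180, 365, 30)]
    r_class = episode(claims, fixed_assignment(), dictionary, mode="class")
    assert not r_class.event
    r_subset = episode(claims, fixed_assignment(), dictionary, mode="subset")
    assert r_subset.event and r_subset.reason == "regimen_changed"
    assert r_subset.duration_days == 180


def test_grace_monotonicity_on_random_streams(dictionary):
    """A longer grace period never shortens an episode."""
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(1, 12))
        claims = [claim("P", int(t), "latanoprost/timolol", int(b))
                  for t, b in zip(np.sort(rng.integers(0, 400, n)), rng.integers(1, 3, n))]
        durations = [
            episode(claims, fixed_assignment(), dictionary, grace_days=g).duration_days
            for g in (0, 10, 30, 60)
        ]
        assert durations == sorted(durations)


def test_gap_anchor_dispense_ignores_stockpile(dictionary):
    # two bottles at day 0 (60 days), refill at day 45: with supply_end
    # anchoring the stockpiled refill runs [60, 90); with dispense anchoring
    # the clock restarts at day 45 + 30 = 75 and the episode ends there.
    claims = [claim("P", 0, "latanoprost/timolol", 2), claim("P", 45, "latanoprost/timolol", 1)]
    r_supply = episode(claims, fixed_assignment(), dictionary)
    r_disp = episode(claims, fixed_assignment(), dictionary, gap_anchor="dispense")
    assert r_supply.duration_days == 90
    assert r_disp.duration_days == 75


def test_km_matches_hand_product_limit():
    results = [
        PersistenceResult("a", "fixed", 100, True, "gap"),
        PersistenceResult("b", "fixed", 200, True, "gap"),
        PersistenceResult("c", "fixed", 365, False),
        PersistenceResult("d", "fixed", 365, False),
    ]
    est = km_fit(results)
    assert est.survival_at(100) == pytest.approx(0.75, abs=1e-12)
    assert est.survival_at(200) == pytest.approx(0.5, abs=1e-12)
    assert est.rate_at(365) == pytest.approx(50.0, abs=1e-10)
    times, surv = km_hand([100, 200, 365, 365], [1, 1, 0, 0])
    for t, s in zip(times, surv):
        assert est.survival_at(t) == pytest.approx(s, abs=1e-12)


def test_km_all_censored_and_single_event():
    all_censored = [PersistenceResult(str(i), "fixed", 365, False) for i in range(5)]
    est = km_fit(all_censored)
    assert est.survival_at(365) == 1.0
    single = [PersistenceResult("x", "fixed", 1, True, "gap")]
    assert km_fit(single).survival_at(1) == 0.0


def test_km_nonincreasing_and_starts_at_one():
    rng = np.random.default_rng(7)
    durations = rng.integers(1, 366, 60)
    events = rng.random(60) < 0.6
    results = [
        PersistenceResult(str(i), "fixed", int(d) if e else 365, bool(e), "gap" if e else "none")
        for i, (d, e) in enumerate(zip(durations, events))
    ]
    est = km_fit(results)
    assert est.survival[0] == 1.0
    assert np.all(np.diff(est.survival) <= 1e-12)
    assert np.all(est.ci_lower <= est.survival + 1e-12)
    assert np.all(est.survival <= est.ci_upper + 1e-12)


def test_logrank_identical_groups_is_null():
    group = [
        PersistenceResult("a", "fixed", 50, True, "gap"),
        PersistenceResult("b", "fixed", 150, True, "gap"),
        PersistenceResult("c", "fixed", 365, False),
        PersistenceResult("d", "fixed", 365, False),
    ]
    stat, p = logrank(group, group)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_risk_set_enumeration():
    dur_a, ev_a = [1, 3, 5], [1, 1, 0]
    dur_b, ev_b = [2, 4, 6], [1, 1, 0]
    a = [PersistenceResult(f"a{i}", "fixed", 365 if not e else d, bool(e), "gap" if e else "none")
         for i, (d, e) in enumerate(zip(dur_a, ev_a))]
    b = [PersistenceResult(f"b{i}", "unfixed", 365 if not e else d, bool(e), "gap" if e else "none")
         for i, (d, e) in enumerate(zip(dur_b, ev_b))]
    stat, _ = logrank(a, b)
    hand = logrank_hand([1, 3, 365], ev_a, [2, 4, 365], ev_b)
    assert stat == pytest.approx(hand, rel=1e-9)


def test_logrank_detects_planted_hazard_ratio():
    """Power >= 0.9 at hazard ratio 3 under the Bonferroni threshold."""
    rng = np.random.default_rng(11)
    reps, hits = 200, 0
    n = 300
    for _ in range(reps):
        t_a = rng.exponential(540, n)   # low-hazard group
        t_b = rng.exponential(180, n)   # hazard ratio 3
        a = [PersistenceResult(f"a{i}", "fixed", int(min(t, 365)) or 1, t < 365,
                               "gap" if t < 365 else "none")
             for i, t in enumerate(t_a)]
        a = [r if r.event else PersistenceResult(r.patient_id, r.cohort, 365, False) for r in a]
        b = [PersistenceResult(f"b{i}", "unfixed", int(min(t, 365)) or 1, t < 365,
                               "gap" if t < 365 else "none")
             for i, t in enumerate(t_b)]
        b = [r if r.event else PersistenceResult(r.patient_id, r.cohort, 365, False) for r in b]
        _, p = logrank(a, b)
        hits += p < 0.00556
    assert hits / reps >= 0.9


def test_result_invariants():
    with pytest.raises(ValueError):
        PersistenceResult("p", "fixed", 200, False)  # censored must be 365
    with pytest.raises(ValueError):
        PersistenceResult("p", "fixed", 400, True, "gap")
    with pytest.raises(ValueError):
        PersistenceResult("p", "fixed", 100, True, "none")
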