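"""PDC computation, binning and Table-2-shaped summaries."""

import numpy as np
import pytest

from conftest import claim, day, stock_covered_days
from dropcover.adherence_metrics import (
    AdherenceResult,
    bin_adherence,
    compute_pdc,
    percent,
    summarize_adherence,
)
from dropcover.cohort_builder import CohortAssignment
from dropcover.exposure_engine import patient_coverage


def fixed_assignment(pid="P"):
    return CohortAssignment(pid, "fixed", day(0), "fixed:PG/BB", 400, ("latanoprost/timolol",))


def unfixed_assignment(pid="P"):
    return CohortAssignment(pid, "unfixed", day(0), "unfixed:PG+BB", 400,
                            ("latanoprost", "timolol"))


def coverage_of(claims, dictionary):
    return patient_coverage(sorted(claims, key=lambda c: c.dispense_date), dictionary)


def test_full_year_fixed_coverage_gives_100(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 365, 30)]
    r = compute_pdc(coverage_of(claims, dictionary), fixed_assignment(), dictionary)
    assert r.pdc_percent == 100.0 and r.adherent and r.bin == "80+"


def test_single_90_day_fixed_interval(dictionary):
    claims = [claim("P", 0, "latanoprost/timolol", bottles=3)]
    r = compute_pdc(coverage_of(claims, dictionary), fixed_assignment(), dictionary)
    assert r.pdc_percent == pytest.approx(90 / 365 * 100)  # 24.7%
    assert r.bin == "20-39" and not r.adherent


def test_unfixed_joint_coverage_is_intersection(dictionary):
    # PG covered [0,180), BB covered [90,270): 90 joint days
    claims = [claim("P", 0, "latanoprost", bottles=6), claim("P", 90, "timolol", bottles=6)]
    cov = coverage_of(claims, dictionary)
    r = compute_pdc(cov, unfixed_assignment(), dictionary)
    assert r.pdc_percent == pytest.approx(90 / 365 * 100)
    r_either = compute_pdc(cov, unfixed_assignment(), dictionary, unfixed_day_rule="either")
    assert r_either.pdc_percent == pytest.approx(270 / 365 * 100)


def test_unfixed_pdc_not_above_component_pdc(dictionary):
    rng = np.random.default_rng(5)
    for _ in range(50):
        pg = [claim("P", int(t), "latanoprost") for t in rng.integers(0, 365, 6)]
        bb = [claim("P", int(t), "timolol") for t in rng.integers(0, 365, 6)]
        cov = coverage_of(pg + bb, dictionary)
        joint = compute_pdc(cov, unfixed_assignment(), dictionary).pdc_percent
        singles = []
        for sub in (pg, bb):
            c = coverage_of(sub, dictionary)
            ivs = next(iter(c.values()))
            singles.append(
                sum(min(e, day(365).toordinal()) - max(s, day(0).toordinal())
                    for s, e in ivs if e > day(0).toordinal()) / 365 * 100
            )
        assert joint <= min(singles) + 1e-9


def test_third_drug_addition_truncates_coverage(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 365, 30)]
    claims += [claim("P", t, "brimonidine") for t in range(180, 365, 30)]
    r = compute_pdc(coverage_of(claims, dictionary), fixed_assignment(), dictionary)
    assert r.pdc_percent == pytest.approx(180 / 365 * 100)


def test_class_switch_within_two_drug_therapy_still_counts(dictionary):
    claims = [claim("P", t, "latanoprost/timolol") for t in range(0, 180, 30)]
    claims += [claim("P", t, "dorzolamide/timolol") for t in range(180, 365, 30)]
    r = compute_pdc(coverage_of(claims, dictionary), fixed_assignment(), dictionary)
    assert r.pdc_percent == 100.0


def test_grace_days_not_counted_by_default(dictionary):
    claims = [claim("P", 0, "latanoprost/timolol"), claim("P", 55, "latanoprost/timolol")]
    cov = coverage_of(claims, dictionary)
    assert compute_pdc(cov, fixed_assignment(), dictionary).pdc_percent == pytest.approx(60 / 365 * 100)
    with_grace = compute_pdc(cov, fixed_assignment(), dictionary, pdc_count_grace=True)
    # the 25-day gap plus 30 trailing grace days are credited
    assert with_grace.pdc_percent == pytest.approx((60 + 25 + 30) / 365 * 100)


@pytest.mark.parametrize(
    "pdc, expected",
    [(100.0, "80+"), (80.0, "80+"), (79.99, "60-79"), (60.0, "60-79"), (59.999, "40-59"),
     (40.0, "40-59"), (20.0, "20-39"), (19.999, "<20"), (0.0, "<20")],
)
def test_bin_boundaries(pdc, expected):
    assert bin_adherence(pdc) == expected


def test_bin_out_of_range_errors():
    with pytest.raises(ValueError):
        bin_adherence(101.0)
    with pytest.raises(ValueError):
        bin_adherence(-0.1)


def test_result_invariants_enforced():
    with pytest.raises(ValueError):
        AdherenceResult("P", "fixed", 85.0, True, "60-79")
    with pytest.raises(ValueError):
        AdherenceResult("P", "fixed", 85.0, False, "80+")


def _result(pid, cohort, pdc):
    b = bin_adherence(pdc)
    return AdherenceResult(pid, cohort, pdc, b == "80+", b)


def test_summarize_adherence_counts_and_percentages():
    results = [_result(f"F{i}", "fixed", 90.0) for i in range(7)]
    results += [_result(f"F{i+7}", "fixed", 50.0) for i in range(3)]
    results += [_result(f"U{i}", "unfixed", 90.0) for i in range(2)]
    results += [_result(f"U{i+2}", "unfixed", 10.0) for i in range(2)]
    table = summarize_adherence(results)
    assert table.loc["fixed", "n"] == 10
    assert table.loc["fixed", "adherent_pct"] == 70.0
    assert table.loc["all", "adherent_pct"] == percent(9, 14)
    assert table.loc["unfixed", "bin_<20_pct"] == 50.0
    # bin percentages sum to 100 up to rounding
    for group in table.index:
        s = sum(table.loc[group, f"bin_{b}_pct"] for b in ("80+", "60-79", "40-59", "20-39", "<20"))
        assert abs(s - 100.0) < 0.3


def test_summarize_all_perfect_adherence():
    results = [_result(f"P{i}", "fixed", 100.0) for i in range(5)]
    table = summarize_adherence(results)
    assert table.loc["fixed", "pdc_mean"] == 100.0
    assert table.loc["fixed", "pdc_sd"] == 0.0
    assert table.loc["fixed", "adherent_pct"] == 100.0


def test_pdc_matches_stock_oracle_with_truncation(dictionary):
    """Randomized two-drug streams: sweep arithmetic == bitmap oracle."""
    rng = np.random.default_rng(17)
    idx = day(0).toordinal()
    for _ in range(200):
        n = rng.integers(1, 10)
        claims = [claim("P", int(t), "latanoprost/timolol", int(b))
                  for t, b in zip(rng.integers(0, 400, n), rng.integers(1, 4, n))]
        if rng.random() < 0.4:  # sometimes a third class appears
            claims += [claim("P", int(t), "brimonidine")
                       for t in rng.integers(0, 400, rng.integers(1, 4))]
        cov = coverage_of(claims, dictionary)
        r = compute_pdc(cov, fixed_assignment(), dictionary)
        # oracle: per-product stock simulation + class bitmaps + truncation
        fixed_days = stock_covered_days(
            [(c.dispense_date.toordinal(), 30 * int(c.period_field)) for c in claims
             if c.generic_name == "latanoprost/timolol"], idx, idx + 365)
        aa_days = stock_covered_days(
            [(c.dispense_date.toordinal(), 30) for c in claims if c.generic_name == "brimonidine"],
            idx - 500, idx + 365)
        triple = sorted(fixed_days & aa_days)
        if triple:
            fixed_days = {d for d in fixed_days if d < triple[0]}
        assert r.pdc_percent == pytest.approx(len(fixed_days) / 365 * 100)
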