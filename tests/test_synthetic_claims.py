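"""Synthetic generator: determinism, planted structure, truth consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import stock_covered_days
from dropcover.claims_model import DrugDictionary
from dropcover.cohort_builder import build_cohorts
from dropcover.pipeline import RunConfig, analyze_patients, load_inputs
from dropcover.synthetic_claims import (
    SyntheticConfig,
    calibrate_intercept,
    generate,
    plant_truth,
)


@pytest.fixture(scope="module")
def small_run():
    cfg = SyntheticConfig(seed=42, n_fixed=80, n_unfixed=80)
    tables = generate(cfg)
    claims, dx, px, cov, _ = load_inputs(RunConfig(simulate=cfg))
    assignments, ledger = build_cohorts(claims, dx, px)
    adherence, persistence, _ = analyze_patients(
        claims, assignments, DrugDictionary.default(), RunConfig()
    )
    return cfg, tables, assignments, ledger, adherence, persistence


def test_identical_config_and_seed_byte_identical(tmp_path):
    cfg = SyntheticConfig(seed=7, n_fixed=15, n_unfixed=15,
                          contamination={"short_monotherapy": 2})
    a_dir, b_dir = tmp_path / "a", tmp_path / "b"
    generate(cfg).write(a_dir)
    generate(cfg).write(b_dir)
    for name in ("claims", "diagnoses", "procedures", "covariates", "truth"):
        assert (a_dir / f"{name}.csv").read_bytes() == (b_dir / f"{name}.csv").read_bytes()


def test_different_seed_differs():
    a = generate(SyntheticConfig(seed=1, n_fixed=10, n_unfixed=10)).claims
    b = generate(SyntheticConfig(seed=2, n_fixed=10, n_unfixed=10)).claims
    assert not a.equals(b)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_fixed=-1)
    with pytest.raises(ValueError):
        SyntheticConfig(regimen_mix={"fixed": {"PG/BB": 0.5}, "unfixed": {"PG+BB": 1.0}})
    with pytest.raises(ValueError):
        SyntheticConfig(contamination={"bogus": 1})


def test_cohort_builder_recovers_configured_sizes_exactly(small_run):
    _, _, _, ledger, _, _ = small_run
    assert ledger["assigned_fixed"] == 80
    assert ledger["assigned_unfixed"] == 80


def test_decoys_are_excluded_by_the_matching_rule():
    cfg = SyntheticConfig(
        seed=9, n_fixed=20, n_unfixed=20,
        contamination={"short_monotherapy": 4, "surgery_history": 4,
                       "mono_only": 4, "no_diagnosis": 4},
    )
    claims, dx, px, _, _ = load_inputs(RunConfig(simulate=cfg))
    _, ledger = build_cohorts(claims, dx, px)
    assert ledger["assigned_fixed"] == 20 and ledger["assigned_unfixed"] == 20
    assert ledger["pre_index_monotherapy_lt_12mo"] == 4
    assert ledger["prior_glaucoma_surgery"] == 4
    assert ledger["no_second_line_therapy"] == 4
    assert ledger["no_glaucoma_diagnosis"] == 4


def test_regimen_mix_within_binomial_99_ci():
    cfg = SyntheticConfig(seed=13, n_fixed=309, n_unfixed=329)
    truth = plant_truth(cfg)
    for cohort, n in (("fixed", 309), ("unfixed", 329)):
        mix = cfg.regimen_mix[cohort]
        counts = truth[truth.cohort == cohort].index_regimen.value_counts()
        for pair, p in mix.items():
            k = counts.get(f"{cohort}:{pair}", 0)
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi, (pair, k, (lo, hi))


def test_saturation_config_gives_pdc_100_everywhere():
    cfg = SyntheticConfig(
        seed=3, n_fixed=25, n_unfixed=25,
        adherence_profile={"fixed": (1.0, 0, 0, 0, 0), "unfixed": (1.0, 0, 0, 0, 0)},
        refill_gap_model={"adherent": {"p_ontime": 1.0, "mean_delay": 1.0},
                          "nonadherent": {"p_ontime": 1.0, "mean_delay": 1.0}},
        both_eyes_prob=0.0,
    )
    claims, dx, px, _, _ = load_inputs(RunConfig(simulate=cfg))
    assignments, _ = build_cohorts(claims, dx, px)
    adherence, persistence, _ = analyze_patients(
        claims, assignments, DrugDictionary.default(), RunConfig()
    )
    assert len(adherence) == 50
    assert all(r.pdc_percent == 100.0 for r in adherence)
    assert all(not r.event for r in persistence)


def test_pipeline_pdc_equals_truth_for_clean_patients(small_run):
    cfg, tables, _, _, adherence, _ = small_run
    truth = tables.truth.set_index("patient_id")
    for r in adherence:
        assert r.pdc_percent == pytest.approx(truth.loc[r.patient_id, "true_pdc"], abs=1e-6)


def test_pipeline_events_equal_planted_events(small_run):
    cfg, tables, _, _, _, persistence = small_run
    truth = tables.truth.set_index("patient_id")
    for r in persistence:
        row = truth.loc[r.patient_id]
        assert r.duration_days == row.true_duration_days
        assert r.event == bool(row.true_event)


def test_truth_covered_days_match_stock_oracle():
    """Truth bitmaps agree with an independent per-product stock simulation."""
    cfg = SyntheticConfig(seed=31, n_fixed=25, n_unfixed=25)
    tables = generate(cfg)
    d = DrugDictionary.default()
    truth = tables.truth.set_index("patient_id")
    claims = tables.claims
    for pid, grp in claims.groupby("patient_id"):
        row = truth.loc[pid]
        idx = pd.Timestamp(row.index_date).date().toordinal()
        day_sets = {}
        for name, sub in grp.groupby("generic_name"):
            entry = d.resolve(name)
            disp = []
            for r in sub.itertuples(index=False):
                bottles = int(round(r.dosage_quantity / entry.unit_bottle_volume))
                days = bottles * 30 if bottles < 7 else -(-bottles * 30 // 2)
                disp.append((pd.Timestamp(r.dispense_date).date().toordinal(), days))
            day_sets[name] = stock_covered_days(disp, idx - 700, idx + 365)
        if row.cohort == "fixed":
            fixed_products = [n for n in day_sets if d.resolve(n).is_fixed_combination]
            covered = set().union(*(day_sets[n] for n in fixed_products))
        else:
            by_class = {}
            for name, days in day_sets.items():
                cls = next(iter(d.resolve(name).drug_classes))
                by_class.setdefault(cls, set()).update(days)
            pair = sorted(by_class, key=lambda c: -len(by_class[c]))[:2]
            covered = set.intersection(*by_class.values())
        covered = {t for t in covered if idx <= t < idx + 365}
        assert len(covered) == row.true_covered_days


def test_truth_gap_rule_plants_discontinuations():
    """Nonadherent patients with a large refill gap are planted as events."""
    truth = plant_truth(SyntheticConfig(seed=19, n_fixed=120, n_unfixed=120))
    non = truth[truth.nonadherent_type == 1]
    assert (non.true_event == 1).mean() > 0.9  # they stop refilling well before 365
    censored = truth[truth.true_event == 0]
    assert (censored.true_duration_days == 365).all()


def test_hba1c_effect_monotone_in_truth():
    """Higher HbA1c raises the planted nonadherence frequency."""
    truth = plant_truth(SyntheticConfig(seed=37, n_fixed=1500, n_unfixed=1500))
    low = truth[truth.hba1c_true < truth.hba1c_true.median()]
    high = truth[truth.hba1c_true >= truth.hba1c_true.median()]
    assert high.nonadherent_type.mean() > low.nonadherent_type.mean()


def test_calibrate_intercept_hits_marginal():
    rng = np.random.default_rng(0)
    beta, sd, q = np.log(1.606), 0.6, 0.304
    a = calibrate_intercept(q, beta, sd)
    h = rng.normal(0, sd, 200_000)
    marginal = float(np.mean(1 / (1 + np.exp(-(a + beta * h)))))
    assert marginal == pytest.approx(q, abs=0.005)
    assert calibrate_intercept(0.0, beta, sd) == -np.inf
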