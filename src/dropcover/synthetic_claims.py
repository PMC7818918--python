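"""Synthetic pharmacy-claims generator for the glaucoma second-line study.

Emulates the statistical structure the analysis assumes, so the whole
pipeline runs and is testable without any proprietary claims data:

* two second-line cohorts (defaults 309 fixed / 329 unfixed) with the
  published index-regimen class mixes;
* a >= 12-month single-class monotherapy run-in before the index date,
  drawn consistent with the index regimen;
* post-index refill streams whose gaps and stopping reproduce the
  published five-bin PDC distribution: each patient draws a latent
  adherent/nonadherent type from a logistic model in HbA1c (planted odds
  ratio per 1% HbA1c, default 1.606), nonadherent patients stop refilling
  after a bin-targeted number of 30-day bottles, adherent patients refill
  to the end of the window with short zero-inflated-geometric delays;
* baseline covariates at the published means/SDs with per-variable
  missingness; only HbA1c is linked to adherence - all other covariates
  are independent noise;
* optional decoy patients violating each inclusion rule, to exercise the
  cohort filter.

For the unfixed cohort both components are dispensed at the same visits
(the run-in component keeps refilling alongside the added drug), so the
joint two-class coverage equals the planted schedule of the added drug.

``generate`` is deterministic: identical (config, seed) gives
byte-identical output tables.  A ground-truth table records the latent
values (true covered days, adherent type, discontinuation day) computed by
day-bitmap arithmetic on the planted supply intervals - an oracle
independent of the pipeline's interval sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .claims_model import STUDY_WINDOW, DrugDictionary
from .adherence_metrics import BINS, GRACE_DAYS

POST_DAYS = 365
_BITMAP_PAD = 120  # days past the window kept in truth bitmaps

DEFAULT_REGIMEN_MIX = {
    "fixed": {"PG/BB": 0.78, "BB/CAI": 0.22},
    "unfixed": {
        "PG+BB": 0.395,
        "PG+AA": 0.264,
        "PG+CAI": 0.143,
        "BB+CAI": 0.100,
        "BB+AA": 0.098,
    },
}

#: probability over the five PDC bins (80+, 60-79, 40-59, 20-39, <20)
DEFAULT_ADHERENCE_PROFILE = {
    "fixed": (0.696, 0.052, 0.078, 0.061, 0.113),
    "unfixed": (0.486, 0.091, 0.058, 0.106, 0.258),
}

DEFAULT_REFILL_GAP_MODEL = {
    "adherent": {"p_ontime": 0.7, "mean_delay": 4.0},
    "nonadherent": {"p_ontime": 0.3, "mean_delay": 10.0},
}

DEFAULT_COVARIATES = {
    "fixed": {
        "male": 0.550, "age": (56.5, 10.2), "bmi": (22.9, 3.5), "hba1c": (5.6, 0.6),
        "bmi_missing": 0.320, "hba1c_missing": 0.337,
        "smoking_yes": 0.107, "smoking_missing": 0.317,
        "hypertension": 0.298, "diabetes": 0.275, "hyperlipidemia": 0.282, "cancer": 0.291,
    },
    "unfixed": {
        "male": 0.571, "age": (57.1, 10.2), "bmi": (22.7, 3.1), "hba1c": (5.6, 0.5),
        "bmi_missing": 0.334, "hba1c_missing": 0.343,
        "smoking_yes": 0.097, "smoking_missing": 0.316,
        "hypertension": 0.334, "diabetes": 0.295, "hyperlipidemia": 0.337, "cancer": 0.347,
    },
}

DEFAULT_REGION_MIX = {"east_metro": 0.60, "east_other": 0.08, "west": 0.32}

_FIXED_PRODUCTS = {
    "PG/BB": (("latanoprost/timolol", 0.51), ("travoprost/timolol", 0.25), ("tafluprost/timolol", 0.24)),
    "BB/CAI": (("dorzolamide/timolol", 0.5), ("brinzolamide/timolol", 0.5)),
}
_MONO_PRODUCTS = {
    "PG": (("latanoprost", 0.60), ("tafluprost", 0.20), ("travoprost", 0.15), ("bimatoprost", 0.05)),
    "BB": (("timolol", 0.70), ("carteolol", 0.30)),
    "CAI": (("dorzolamide", 0.5), ("brinzolamide", 0.5)),
    "AA": (("brimonidine", 1.0),),
}

#: number of 30-day bottles planted for a nonadherent patient, per PDC bin
_BIN_BOTTLES = {"60-79": (8, 9), "40-59": (5, 6, 7), "20-39": (3, 4), "<20": (1, 2)}

DECOY_KINDS = ("short_monotherapy", "surgery_history", "mono_only", "no_diagnosis")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic claims population."""

    seed: int = 0
    n_fixed: int = 309
    n_unfixed: int = 329
    regimen_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGIMEN_MIX.items()})
    adherence_profile: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ADHERENCE_PROFILE.items()})
    refill_gap_model: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REFILL_GAP_MODEL.items()})
    dropout_hazard: float = 0.0  # per-30-day extra stop probability, adherent type
    hba1c_effect_or: float = 1.606  # planted OR per 1% HbA1c on nonadherence
    covariate_means_sds: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()})
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    contamination: dict = field(default_factory=lambda: {k: 0 for k in DECOY_KINDS})
    addon_third_class_prob: float = 0.0
    both_eyes_prob: float = 0.03
    bottle_weights: tuple = ((1, 0.70), (2, 0.15), (3, 0.15))

    def __post_init__(self) -> None:
        if self.n_fixed < 0 or self.n_unfixed < 0:
            raise ValueError("cohort sizes must be >= 0")
        for cohort, mix in self.regimen_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"regimen_mix[{cohort}] does not sum to 1")
        for cohort, prof in list(self.adherence_profile.items()):
            if len(prof) != len(BINS):
                raise ValueError("adherence_profile needs one probability per PDC bin")
            total = sum(prof)
            if abs(total - 1.0) > 5e-3:
                raise ValueError(f"adherence_profile[{cohort}] does not sum to 1")
            if abs(total - 1.0) > 1e-9:
                # printed percentage tables round to 0.1%; renormalize exactly
                self.adherence_profile[cohort] = tuple(p / total for p in prof)
        if not 0 <= self.dropout_hazard <= 1:
            raise ValueError("dropout_hazard must be a probability")
        if self.hba1c_effect_or <= 0:
            raise ValueError("hba1c_effect_or must be positive")
        unknown = set(self.contamination) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown contamination kinds: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticTables:
    claims: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("claims", "diagnoses", "procedures", "covariates", "truth"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def calibrate_intercept(target_nonadherence: float, log_or: float, hba1c_sd: float) -> float:
    """Logistic intercept whose HbA1c-marginalized nonadherence rate hits the target.

    Solves E[expit(a + b (H - mu))] = q over H ~ N(mu, sd) by Gauss-Hermite
    quadrature; centered HbA1c means the intercept is on the cohort scale.
    """
    if target_nonadherence <= 1e-12:
        return -np.inf
    if target_nonadherence >= 1 - 1e-12:
        return np.inf
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / math.sqrt(2 * math.pi)

    def marginal(a: float) -> float:
        return float(np.sum(weights * expit(a + log_or * hba1c_sd * nodes)))

    return brentq(lambda a: marginal(a) - target_nonadherence, -40, 40, xtol=1e-12)


class _Builder:
    """Accumulates generated rows and per-product supply cursors."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.dictionary = DrugDictionary.default()
        self.claims: list[dict] = []
        self.diagnoses: list[dict] = []
        self.procedures: list[dict] = []
        self.covariates: list[dict] = []
        self.truth: list[dict] = []
        self._cursor: dict[tuple[str, str], int] = {}
        self._intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}

    # -- low-level planting -------------------------------------------------
    def dispense(self, pid: str, t: int, product: str, bottles: int) -> int:
        """Record a claim and its planted supply interval; returns supply end."""
        entry = self.dictionary.resolve(product)
        days = bottles * 30 if bottles < 7 else -(-bottles * 30 // 2)
        self.claims.append(
            {
                "patient_id": pid,
                "dispense_date": date.fromordinal(t).isoformat(),
                "generic_name": product,
                "dosage_quantity": round(bottles * entry.unit_bottle_volume, 2),
                "period_field": bottles,
            }
        )
        key = (pid, product)
        start = max(t, self._cursor.get(key, t))
        self._cursor[key] = start + days
        self._intervals.setdefault(key, []).append((start, start + days))
        return start + days

    def class_bitmaps(self, pid: str, idx: int) -> dict[str, np.ndarray]:
        """Day-bitmaps per drug class over [idx, idx + 365 + pad)."""
        n = POST_DAYS + _BITMAP_PAD
        maps: dict[str, np.ndarray] = {}
        for (p, product), ivs in self._intervals.items():
            if p != pid:
                continue
            entry = self.dictionary.resolve(product)
            for cls in entry.drug_classes:
                bm = maps.setdefault(cls, np.zeros(n, dtype=bool))
                for s, e in ivs:
                    lo, hi = max(s - idx, 0), min(e - idx, n)
                    if lo < hi:
                        bm[lo:hi] = True
        return maps

    def product_bitmap(self, pid: str, products, idx: int) -> np.ndarray:
        n = POST_DAYS + _BITMAP_PAD
        bm = np.zeros(n, dtype=bool)
        for product in products:
            for s, e in self._intervals.get((pid, product), []):
                lo, hi = max(s - idx, 0), min(e - idx, n)
                if lo < hi:
                    bm[lo:hi] = True
        return bm


def _weighted(rng: np.random.Generator, pairs) -> str:
    names = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _delay(rng: np.random.Generator, model: dict) -> int:
    if rng.random() < model["p_ontime"]:
        return 0
    return int(rng.geometric(1.0 / model["mean_delay"]))


def _truth_from_bitmap(regimen: np.ndarray, day3: int | None) -> tuple[int, int, bool, str]:
    """Covered days, discontinuation day and event flag from a day-bitmap.

    Scans the planted supply runs with the 30-day grace rule: the episode
    ends at the last covered day once the next supply starts more than 30
    days later (or never), or at the third-class addition day if earlier.
    """
    horizon = POST_DAYS
    window = regimen[:horizon].copy()
    if day3 is not None and day3 < horizon:
        window[day3:] = False
    covered = int(window.sum())

    # persistence scan over the untruncated bitmap (beyond-window pad included)
    diffs = np.flatnonzero(np.diff(np.concatenate(([False], regimen, [False])).astype(np.int8)))
    runs = list(zip(diffs[::2], diffs[1::2]))  # [start, end) day offsets
    event_day: int | None = None
    reason = "gap"
    if not runs or runs[0][0] > GRACE_DAYS:
        event_day = 0
    else:
        cur_end = runs[0][1]
        for s, e in runs[1:]:
            if cur_end >= horizon:
                break
            if s - cur_end > GRACE_DAYS:
                event_day = int(cur_end)
                break
            cur_end = e
        else:
            if cur_end < horizon:
                event_day = int(cur_end)
    if day3 is not None and day3 < horizon and (event_day is None or day3 <= event_day):
        event_day, reason = int(day3), "third_drug_added"
    if event_day is None or event_day >= horizon:
        return covered, horizon, False, "none"
    return covered, event_day, True, reason


def generate(config: SyntheticConfig | None = None) -> SyntheticTables:
    """Generate the four input tables plus the ground-truth table."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    b = _Builder(cfg, rng)

    w0 = STUDY_WINDOW[0].toordinal()
    w1 = STUDY_WINDOW[1].toordinal()
    beta = math.log(cfg.hba1c_effect_or)
    intercepts = {}
    for cohort in ("fixed", "unfixed"):
        q = 1.0 - cfg.adherence_profile[cohort][0]
        sd = cfg.covariate_means_sds[cohort]["hba1c"][1]
        intercepts[cohort] = calibrate_intercept(q, beta, sd)

    for cohort, n, prefix in (("fixed", cfg.n_fixed, "F"), ("unfixed", cfg.n_unfixed, "U")):
        for i in range(n):
            pid = f"{prefix}{i:05d}"
            _gen_clean_patient(b, pid, cohort, intercepts[cohort], beta, w0, w1)

    _gen_decoys(b, w0, w1)

    claims = pd.DataFrame(
        b.claims, columns=["patient_id", "dispense_date", "generic_name", "dosage_quantity", "period_field"]
    )
    diagnoses = pd.DataFrame(b.diagnoses, columns=["patient_id", "date", "icd10_code"])
    procedures = pd.DataFrame(
        b.procedures, columns=["patient_id", "date", "is_glaucoma_surgery_or_laser"]
    )
    covariates = pd.DataFrame(b.covariates)
    truth = pd.DataFrame(b.truth)
    return SyntheticTables(claims, diagnoses, procedures, covariates, truth)


def plant_truth(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Ground-truth table alone (regenerates deterministically from config)."""
    return generate(config).truth


def _gen_covariates(b: _Builder, pid: str, cohort: str) -> float:
    cfg, rng = b.cfg, b.rng
    cv = cfg.covariate_means_sds[cohort]
    age = float(np.clip(rng.normal(*cv["age"]), 20, 74))
    bmi = float(np.clip(rng.normal(*cv["bmi"]), 14, 45))
    hba1c = float(np.clip(rng.normal(*cv["hba1c"]), 3, 20))
    smoking = "yes" if rng.random() < cv["smoking_yes"] else "no"
    row = {
        "patient_id": pid,
        "sex": "male" if rng.random() < cv["male"] else "female",
        "age": round(age, 1),
        "body_mass_index": round(bmi, 1) if rng.random() >= cv["bmi_missing"] else np.nan,
        "smoking": smoking if rng.random() >= cv["smoking_missing"] else np.nan,
        "hba1c_percent": round(hba1c, 2) if rng.random() >= cv["hba1c_missing"] else np.nan,
        "hypertension": int(rng.random() < cv["hypertension"]),
        "diabetes": int(rng.random() < cv["diabetes"]),
        "hyperlipidemia": int(rng.random() < cv["hyperlipidemia"]),
        "cancer": int(rng.random() < cv["cancer"]),
        "region_category": _weighted(rng, list(b.cfg.region_mix.items())),
    }
    b.covariates.append(row)
    # the logistic adherence mechanism uses the drawn value even when the
    # reported one is missing (missingness is noninformative)
    return hba1c


def _regimen_products(b: _Builder, cohort: str) -> tuple[str, tuple[str, ...], tuple[str, ...]]:
    """(regimen label, index products, class pair) for one patient."""
    cfg, rng = b.cfg, b.rng
    mix = cfg.regimen_mix[cohort]
    pair_label = _weighted(rng, list(mix.items()))
    if cohort == "fixed":
        product = _weighted(rng, _FIXED_PRODUCTS[pair_label])
        return f"fixed:{pair_label}", (product,), tuple(pair_label.split("/"))
    classes = tuple(pair_label.split("+"))
    products = tuple(_weighted(rng, _MONO_PRODUCTS[cls]) for cls in classes)
    return f"unfixed:{pair_label}", products, classes


def _run_in(b: _Builder, pid: str, idx: int, mono_product: str, days: int) -> int:
    """Back-to-back monotherapy refills ending at the index; returns start."""
    start = idx - days
    t = start
    while t < idx:
        b.dispense(pid, t, mono_product, 1)
        t += 30
    return start


def _gen_clean_patient(
    b: _Builder, pid: str, cohort: str, alpha: float, beta: float, w0: int, w1: int
) -> None:
    cfg, rng = b.cfg, b.rng
    hba1c = _gen_covariates(b, pid, cohort)
    mu = cfg.covariate_means_sds[cohort]["hba1c"][0]
    p_non = float(expit(alpha + beta * (hba1c - mu))) if np.isfinite(alpha) else (
        0.0 if alpha < 0 else 1.0
    )
    nonadherent = rng.random() < p_non

    label, products, pair = _regimen_products(b, cohort)
    run_extra = int(rng.integers(10, 181))
    idx = int(rng.integers(w0 + 365 + 181, w1 - POST_DAYS))

    # monotherapy run-in with a component class of the index regimen
    run_cls = pair[0] if rng.random() < 0.7 else pair[1]
    if cohort == "unfixed":
        # the run-in drug must be one of the dispensed components
        run_product = products[pair.index(run_cls)]
    else:
        run_product = _weighted(rng, _MONO_PRODUCTS[run_cls])
    _run_in(b, pid, idx, run_product, 365 + run_extra)

    # glaucoma diagnosis some time during the run-in
    dx_code = "H401" if rng.random() < 0.7 else "H409"
    b.diagnoses.append(
        {"patient_id": pid, "date": date.fromordinal(idx - 365 - run_extra).isoformat(), "icd10_code": dx_code}
    )
    if rng.random() < 0.2:
        b.diagnoses.append(
            {"patient_id": pid, "date": date.fromordinal(idx - 100).isoformat(), "icd10_code": "E119"}
        )
    if rng.random() < 0.05:  # unrelated, unflagged procedure
        b.procedures.append(
            {"patient_id": pid, "date": date.fromordinal(idx - 200).isoformat(), "is_glaucoma_surgery_or_laser": 0}
        )

    # post-index refill stream of the index regimen; for the unfixed cohort
    # the run-in component keeps refilling alongside the added drug
    model = cfg.refill_gap_model["nonadherent" if nonadherent else "adherent"]
    post_products = products

    if nonadherent:
        profile = np.asarray(cfg.adherence_profile[cohort][1:], dtype=float)
        cond = profile / profile.sum()
        bin_label = BINS[1:][int(rng.choice(len(cond), p=cond))]
        n_bottles = int(rng.choice(_BIN_BOTTLES[bin_label]))
        t = idx
        for _ in range(n_bottles):
            for product in post_products:
                b.dispense(pid, t, product, 1)
            t += 30 + _delay(rng, model)
    else:
        t = idx
        while t < idx + POST_DAYS:
            if rng.random() < cfg.both_eyes_prob:
                bottles = 7
            else:
                bottles = int(_weighted(rng, [(str(k), p) for k, p in cfg.bottle_weights]))
            # the next visit is driven by whichever product runs out first
            end = min(b.dispense(pid, t, product, bottles) for product in post_products)
            if cfg.dropout_hazard and rng.random() < cfg.dropout_hazard:
                break
            t = end + _delay(rng, model)

    # optional third-class add-on (adherent trajectories only)
    addon = None
    if not nonadherent and rng.random() < cfg.addon_third_class_prob:
        addon_cls = next(c for c in ("AA", "CAI", "BB", "PG") if c not in pair)
        addon_product = _weighted(rng, _MONO_PRODUCTS[addon_cls])
        t = idx + int(rng.integers(60, 300))
        addon = t
        while t < idx + POST_DAYS:
            b.dispense(pid, t, addon_product, 1)
            t += 30

    # ground truth by day-bitmap arithmetic on the planted intervals
    class_maps = b.class_bitmaps(pid, idx)
    if cohort == "fixed":
        regimen_bm = b.product_bitmap(pid, [products[0]], idx)
    else:
        stack = [class_maps[c] for c in pair]
        regimen_bm = np.logical_and.reduce(stack)
    counts = np.sum(np.stack(list(class_maps.values())), axis=0)
    triple_days = np.flatnonzero(counts >= 3)
    day3 = int(triple_days[0]) if triple_days.size else None
    covered, event_day, event, reason = _truth_from_bitmap(regimen_bm, day3)
    b.truth.append(
        {
            "patient_id": pid,
            "role": "clean",
            "cohort": cohort,
            "index_date": date.fromordinal(idx).isoformat(),
            "index_regimen": label,
            "hba1c_true": round(hba1c, 4),
            "nonadherent_type": int(nonadherent),
            "true_covered_days": covered,
            "true_pdc": round(covered / POST_DAYS * 100.0, 6),
            "true_adherent": int(covered / POST_DAYS * 100.0 >= 80.0),
            "true_duration_days": event_day,
            "true_event": int(event),
            "true_reason": reason,
        }
    )


def _gen_decoys(b: _Builder, w0: int, w1: int) -> None:
    cfg, rng = b.cfg, b.rng
    counter = 0
    for kind in DECOY_KINDS:
        for _ in range(int(cfg.contamination.get(kind, 0))):
            pid = f"D{counter:05d}"
            counter += 1
            cohort = "fixed" if rng.random() < 0.5 else "unfixed"
            _gen_covariates(b, pid, cohort)
            label, products, pair = _regimen_products(b, cohort)
            idx = int(rng.integers(w0 + 365 + 181, w1 - POST_DAYS))
            run_cls = pair[0]
            run_product = (
                products[pair.index(run_cls)] if cohort == "unfixed"
                else _weighted(rng, _MONO_PRODUCTS[run_cls])
            )
            dx_code = "H401" if kind != "no_diagnosis" else "M545"
            run_days = 365 + int(rng.integers(10, 181))
            if kind == "short_monotherapy":
                run_days = int(rng.integers(60, 300))
            b.diagnoses.append(
                {"patient_id": pid, "date": date.fromordinal(idx - run_days).isoformat(), "icd10_code": dx_code}
            )
            _run_in(b, pid, idx, run_product, run_days)
            if kind == "surgery_history":
                b.procedures.append(
                    {
                        "patient_id": pid,
                        "date": date.fromordinal(idx - run_days + 30).isoformat(),
                        "is_glaucoma_surgery_or_laser": 1,
                    }
                )
            if kind != "mono_only":
                t = idx
                for _ in range(4):
                    for product in products:
                        b.dispense(pid, t, product, 1)
                    t += 30
            b.truth.append(
                {
                    "patient_id": pid,
                    "role": f"decoy:{kind}",
                    "cohort": cohort,
                    "index_date": date.fromordinal(idx).isoformat(),
                    "index_regimen": label,
                    "hba1c_true": np.nan,
                    "nonadherent_type": np.nan,
                    "true_covered_days": np.nan,
                    "true_pdc": np.nan,
                    "true_adherent": np.nan,
                    "true_duration_days": np.nan,
                    "true_event": np.nan,
                    "true_reason": "",
                }
            )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=int(seed))
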