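"""Domain model for ophthalmic pharmacy-claims analysis.

Claims, diagnosis, procedure and covariate records, plus the drug-class
dictionary that grounds every downstream classification.  Four classes of
intraocular-pressure-lowering eye drops are distinguished: prostaglandin
analogs (PG), beta-blockers (BB), carbonic anhydrase inhibitors (CAI) and
alpha2-agonists (AA).  A *fixed combination* co-formulates exactly two
classes in one bottle (e.g. latanoprost/timolol); an *unfixed combination*
is the same two classes dispensed as two separate products.

The shipped dictionary covers the generic products named in the study
regimen taxonomy and is user-extensible: it is a plain delimited file, and
``DrugDictionary.from_file`` accepts any file with the same columns.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from datetime import date
from functools import lru_cache
from importlib import resources

import pandas as pd

log = logging.getLogger(__name__)

#: Canonical ordering of drug classes used in every regimen label.
CLASS_ORDER: tuple[str, ...] = ("PG", "BB", "CAI", "AA")
DRUG_CLASSES = frozenset(CLASS_ORDER)

ONCE_DAILY = "once_daily"
MULTI_DAILY = "twice_or_more_daily"

#: ICD-10 codes selecting the glaucoma study population
#: (H401 open-angle / normal-tension glaucoma, H409 unspecified glaucoma).
GLAUCOMA_ICD10 = frozenset({"H401", "H409"})

#: Default study extraction window.
STUDY_WINDOW = (date(2011, 4, 1), date(2016, 3, 31))


def canonical_classes(classes: Iterable[str]) -> tuple[str, ...]:
    """Sort a set of drug classes into the canonical PG < BB < CAI < AA order."""
    unique = set(classes)
    unknown = unique - DRUG_CLASSES
    if unknown:
        raise ValueError(f"unknown drug classes: {sorted(unknown)}")
    return tuple(sorted(unique, key=CLASS_ORDER.index))


@dataclass(frozen=True)
class DrugEntry:
    """One generic product in the ophthalmic drug dictionary.

    ``unit_bottle_volume`` is the approved bottle size in mL: 2.5 mL for
    once-daily formulations and 5 mL for twice-or-more-daily formulations.
    """

    generic_name: str
    drug_classes: frozenset[str]
    is_fixed_combination: bool
    unit_bottle_volume: float
    dosing_frequency: str

    def __post_init__(self) -> None:
        canonical_classes(self.drug_classes)  # validates the vocabulary
        n = len(self.drug_classes)
        if self.is_fixed_combination and n != 2:
            raise ValueError(
                f"{self.generic_name}: fixed combinations carry exactly 2 classes, got {n}"
            )
        if not self.is_fixed_combination and n != 1:
            raise ValueError(
                f"{self.generic_name}: monotherapy products carry exactly 1 class, got {n}"
            )
        if self.dosing_frequency not in (ONCE_DAILY, MULTI_DAILY):
            raise ValueError(f"{self.generic_name}: bad dosing_frequency {self.dosing_frequency!r}")
        expected = 2.5 if self.dosing_frequency == ONCE_DAILY else 5.0
        if float(self.unit_bottle_volume) != expected:
            raise ValueError(
                f"{self.generic_name}: unit bottle volume must be {expected} mL for "
                f"{self.dosing_frequency} products, got {self.unit_bottle_volume}"
            )

    @property
    def class_label(self) -> str:
        """Canonical class label, e.g. ``PG`` or ``PG/BB`` for a fixed product."""
        classes = canonical_classes(self.drug_classes)
        return "/".join(classes) if self.is_fixed_combination else classes[0]


class DrugDictionary(Mapping[str, DrugEntry]):
    """Lookup from generic name to :class:`DrugEntry`.

    Generic names are the join key between claims and the dictionary; an
    unresolvable name in a claims file is a hard load error.
    """

    def __init__(self, entries: Iterable[DrugEntry]):
        self._entries: dict[str, DrugEntry] = {}
        for entry in entries:
            if entry.generic_name in self._entries:
                raise ValueError(f"duplicate dictionary entry: {entry.generic_name}")
            self._entries[entry.generic_name] = entry

    def __getitem__(self, name: str) -> DrugEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def resolve(self, name: str) -> DrugEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(
                f"generic name {name!r} not in drug dictionary; extend the dictionary file"
            ) from None

    def products(
        self, *, fixed: bool | None = None, drug_class: str | None = None
    ) -> list[DrugEntry]:
        out = []
        for entry in self._entries.values():
            if fixed is not None and entry.is_fixed_combination is not fixed:
                continue
            if drug_class is not None and drug_class not in entry.drug_classes:
                continue
            out.append(entry)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrugDictionary":
        entries = []
        for row in frame.itertuples(index=False):
            entries.append(
                DrugEntry(
                    generic_name=str(row.generic_name),
                    drug_classes=frozenset(str(row.drug_classes).split("/")),
                    is_fixed_combination=bool(int(row.is_fixed_combination)),
                    unit_bottle_volume=float(row.unit_bottle_volume),
                    dosing_frequency=str(row.dosing_frequency),
                )
            )
        return cls(entries)

    @classmethod
    def from_file(cls, path) -> "DrugDictionary":
        return cls.from_frame(read_table(path))

    @classmethod
    def default(cls) -> "DrugDictionary":
        return _default_dictionary()


@lru_cache(maxsize=1)
def _default_dictionary() -> DrugDictionary:
    with resources.files("dropcover.data").joinpath("drug_dictionary.csv").open() as fh:
        return DrugDictionary.from_frame(pd.read_csv(fh))


@dataclass(frozen=True)
class PharmacyClaim:
    """One dispensing event.

    ``dosage_quantity`` is the claim's dosage field in mL; ``period_field``
    is the months-like period count reported on the claim (kept for audit,
    but day counting is derived from bottle arithmetic downstream).
    """

    patient_id: str
    dispense_date: date
    generic_name: str
    dosage_quantity: float
    period_field: int = 1


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: date
    icd10_code: str

    @staticmethod
    def normalize_code(code: str) -> str:
        """Normalize an ICD-10 code to its 4-character uppercase form."""
        return str(code).strip().upper().replace(".", "")[:4]


@dataclass(frozen=True)
class ProcedureRecord:
    patient_id: str
    date: date
    is_glaucoma_surgery_or_laser: bool


@dataclass(frozen=True)
class PatientCovariates:
    """Baseline covariates; ``None`` encodes missingness, which propagates
    into complete-case analyses downstream."""

    patient_id: str
    sex: str | None = None
    age: float | None = None
    body_mass_index: float | None = None
    smoking: str | None = None
    hba1c_percent: float | None = None
    hypertension: bool | None = None
    diabetes: bool | None = None
    hyperlipidemia: bool | None = None
    cancer: bool | None = None
    region_category: str | None = None


# ---------------------------------------------------------------------------
# Loaders: delimited text (comma or tab, auto-detected), ISO-8601 dates.
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma vs tab separators."""
    return pd.read_csv(path, sep=None, engine="python")


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = series[parsed.isna()].unique()[:5]
        raise ValueError(f"{what}: unparseable ISO-8601 dates, e.g. {list(bad)}")
    return parsed.dt.date


def load_claims(path, dictionary: DrugDictionary | None = None) -> list[PharmacyClaim]:
    """Load a prescription-claims table.

    Rows with non-positive dosage are rejected with a logged warning; any
    generic name missing from the dictionary is a hard error listing the
    offending names.  Output is sorted by (patient_id, dispense_date).
    """
    dictionary = dictionary or DrugDictionary.default()
    frame = read_table(path)
    required = {"patient_id", "dispense_date", "generic_name", "dosage_quantity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"claims table missing columns: {sorted(missing)}")
    if "period_field" not in frame.columns:
        frame["period_field"] = 1

    unresolved = sorted(set(frame["generic_name"].astype(str)) - set(dictionary))
    if unresolved:
        raise ValueError(f"unresolvable generic names in claims table: {unresolved}")

    bad = frame["dosage_quantity"] <= 0
    if bad.any():
        log.warning("rejecting %d claim rows with non-positive dosage_quantity", int(bad.sum()))
        frame = frame[~bad]

    frame = frame.assign(dispense_date=_parse_dates(frame["dispense_date"], "claims"))
    frame = frame.sort_values(["patient_id", "dispense_date"], kind="stable")
    return [
        PharmacyClaim(
            patient_id=str(r.patient_id),
            dispense_date=r.dispense_date,
            generic_name=str(r.generic_name),
            dosage_quantity=float(r.dosage_quantity),
            period_field=int(r.period_field),
        )
        for r in frame.itertuples(index=False)
    ]


def load_diagnoses(path) -> list[DiagnosisRecord]:
    frame = read_table(path)
    frame = frame.assign(date=_parse_dates(frame["date"], "diagnoses"))
    return [
        DiagnosisRecord(str(r.patient_id), r.date, DiagnosisRecord.normalize_code(r.icd10_code))
        for r in frame.itertuples(index=False)
    ]


def load_procedures(path) -> list[ProcedureRecord]:
    frame = read_table(path)
    frame = frame.assign(date=_parse_dates(frame["date"], "procedures"))
    return [
        ProcedureRecord(
            str(r.patient_id), r.date, bool(int(r.is_glaucoma_surgery_or_laser))
        )
        for r in frame.itertuples(index=False)
    ]


def load_covariates(path) -> pd.DataFrame:
    """Load the health-checkup covariate table, indexed by patient_id.

    HbA1c values outside the plausible 3-20 NGSP % range are set to missing
    with a warning rather than rejected, since checkup extracts are noisy.
    """
    frame = read_table(path).set_index("patient_id")
    frame.index = frame.index.astype(str)
    if "hba1c_percent" in frame.columns:
        h = pd.to_numeric(frame["hba1c_percent"], errors="coerce")
        implausible = h.notna() & ((h < 3) | (h > 20))
        if implausible.any():
            log.warning("setting %d implausible HbA1c values to missing", int(implausible.sum()))
            h[implausible] = pd.NA
        frame["hba1c_percent"] = h
    return frame


# ---------------------------------------------------------------------------
# Regimen classification
# ---------------------------------------------------------------------------

def classify_regimen(entries: Iterable[DrugEntry]) -> str:
    """Classify a set of concurrently supplied products into a regimen label.

    Returns one of ``monotherapy:<class>``, ``fixed:<c1/c2>``,
    ``unfixed:<c1+c2>``, ``triple`` or ``other``; class pairs are in
    canonical order.  Invariant to input ordering.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("cannot classify an empty set of products")
    classes = canonical_classes(
        cls for entry in entries for cls in entry.drug_classes
    )
    if len(classes) == 1:
        return f"monotherapy:{classes[0]}"
    if len(classes) == 2:
        if any(
            e.is_fixed_combination and frozenset(e.drug_classes) == frozenset(classes)
            for e in entries
        ):
            return f"fixed:{classes[0]}/{classes[1]}"
        if all(not e.is_fixed_combination for e in entries):
            return f"unfixed:{classes[0]}+{classes[1]}"
        return "other"
    if len(classes) == 3:
        return "triple"
    return "other"


def regimen_pair(label: str) -> tuple[str, ...]:
    """Extract the canonical class tuple from a regimen label."""
    if ":" not in label:
        raise ValueError(f"regimen label {label!r} has no class part")
    _, part = label.split(":", 1)
    return canonical_classes(part.replace("+", "/").split("/"))
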