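"""Domain types and CSV IO for longitudinal childhood-SLE cohorts.

A cohort is a pair of long-format tables: one row per patient with
baseline demographics and serology, and one row per clinical visit with
the disease-activity indices (SLEDAI-2K item scores, PGA, pBILAG-2004
domain grades), damage (SDI), steroid exposure and weight.

SLEDAI-2K item scores are kept at item granularity (an item -> score
map) rather than as a single total, because the treat-to-target rules
need to know *which* organ domains are active and whether an item is
serologic (low complement, anti-dsDNA) — the clinical SLEDAI (cSLEDAI)
excludes the serologic items.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SLEDAI_ITEMS",
    "SLEDAI_ITEM_NAMES",
    "PBILAG_DOMAINS",
    "ETHNICITIES",
    "SEXES",
    "WEIGHT_PROVENANCES",
    "IMSN_CHANGES",
    "PBILAG_GRADES",
    "SledaiItem",
    "PatientRecord",
    "VisitRecord",
    "CohortParseError",
    "InvalidRecordError",
    "sledai2k_total",
    "csledai",
    "read_cohort",
    "write_cohort",
    "visits_by_patient",
]

DAYS_PER_MONTH = 30.4375  # durations computed in days, reported in months


@dataclass(frozen=True)
class SledaiItem:
    """One SLEDAI-2K descriptor: its weight, organ domain and serologic flag."""

    weight: int
    domain: str
    serologic: bool = False


# SLEDAI-2K descriptor catalogue. Weights are the standard index weights;
# the ``domain`` tag is what the target rules consult for "major active
# organ involvement" (cardiopulmonary, cns, fever, renal, vasculitis).
SLEDAI_ITEMS: dict[str, SledaiItem] = {
    "seizure": SledaiItem(8, "cns"),
    "psychosis": SledaiItem(8, "cns"),
    "organic_brain_syndrome": SledaiItem(8, "cns"),
    "visual_disturbance": SledaiItem(8, "cns"),
    "cranial_nerve_disorder": SledaiItem(8, "cns"),
    "lupus_headache": SledaiItem(8, "cns"),
    "cva": SledaiItem(8, "cns"),
    "vasculitis": SledaiItem(8, "vasculitis"),
    "arthritis": SledaiItem(4, "musculoskeletal"),
    "myositis": SledaiItem(4, "musculoskeletal"),
    "urinary_casts": SledaiItem(4, "renal"),
    "hematuria": SledaiItem(4, "renal"),
    "proteinuria": SledaiItem(4, "renal"),
    "pyuria": SledaiItem(4, "renal"),
    "rash": SledaiItem(2, "mucocutaneous"),
    "alopecia": SledaiItem(2, "mucocutaneous"),
    "mucosal_ulcers": SledaiItem(2, "mucocutaneous"),
    "pleurisy": SledaiItem(2, "cardiopulmonary"),
    "pericarditis": SledaiItem(2, "cardiopulmonary"),
    "low_complement": SledaiItem(2, "serology", serologic=True),
    "anti_dsdna": SledaiItem(2, "serology", serologic=True),
    "fever": SledaiItem(1, "fever"),
    "thrombocytopenia": SledaiItem(1, "haematology"),
    "leukopenia": SledaiItem(1, "haematology"),
}
SLEDAI_ITEM_NAMES: tuple[str, ...] = tuple(SLEDAI_ITEMS)

# pBILAG-2004 organ domains (one grade A..E each). The engine only
# consumes the A/B vs other distinction, so the naming is conventional.
PBILAG_DOMAINS: tuple[str, ...] = (
    "general",
    "mucocutaneous",
    "neurological",
    "musculoskeletal",
    "cardiorespiratory",
    "gastrointestinal",
    "ophthalmic",
    "renal",
    "haematological",
)

ETHNICITIES = ("white_british", "asian", "african_caribbean", "other")
SEXES = ("male", "female")
WEIGHT_PROVENANCES = ("measured", "window_imputed", "who_centile", "locf", "missing")
IMSN_CHANGES = ("none", "activity_driven", "non_activity_reason")
PBILAG_GRADES = ("A", "B", "C", "D", "E")


class CohortParseError(ValueError):
    """A cohort CSV contains a token outside the closed vocabulary."""


class InvalidRecordError(ValueError):
    """A record violates a domain invariant (e.g. negative item score)."""


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    ethnicity: str
    diagnosis_date: dt.date
    age_at_diagnosis: float
    ana_positive: bool = True
    anti_dsdna_positive: bool = False
    low_c3: bool = False
    low_c4: bool = False
    lymphopenia: bool = False
    baseline_sdi: int = 0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortParseError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise CohortParseError(f"unknown ethnicity {self.ethnicity!r}")
        if not 0 < self.age_at_diagnosis <= 18:
            raise InvalidRecordError(
                f"age_at_diagnosis must lie in (0, 18], got {self.age_at_diagnosis}"
            )
        if self.baseline_sdi < 0:
            raise InvalidRecordError("baseline_sdi must be non-negative")


@dataclass
class VisitRecord:
    patient_id: str
    visit_date: dt.date
    age_at_visit: float
    weight_kg: float | None = None
    weight_provenance: str = "missing"
    sledai_items: dict[str, int] = field(default_factory=dict)
    pga: float | None = None
    pbilag_grades: dict[str, str] = field(default_factory=dict)
    sdi: int = 0
    prednisolone_mg_day: float = 0.0
    iv_methylpred: bool = False
    imsn_change: str = "none"
    # serology flags are None when not assessed at the visit
    anti_dsdna_positive: bool | None = None
    low_c3: bool | None = None
    low_c4: bool | None = None

    def __post_init__(self) -> None:
        if self.weight_provenance not in WEIGHT_PROVENANCES:
            raise CohortParseError(
                f"unknown weight provenance {self.weight_provenance!r}"
            )
        if self.imsn_change not in IMSN_CHANGES:
            raise CohortParseError(f"unknown imsn_change {self.imsn_change!r}")
        for name, score in self.sledai_items.items():
            if score < 0:
                raise InvalidRecordError(
                    f"negative SLEDAI item score {name}={score} "
                    f"for patient {self.patient_id}"
                )
        for domain, grade in self.pbilag_grades.items():
            if grade not in PBILAG_GRADES:
                raise CohortParseError(
                    f"unknown pBILAG grade {grade!r} in domain {domain!r}"
                )
        if self.pga is not None and not 0 <= self.pga <= 3:
            raise InvalidRecordError(f"PGA must lie in [0, 3], got {self.pga}")
        if self.sdi < 0:
            raise InvalidRecordError("SDI must be non-negative")
        if self.prednisolone_mg_day < 0:
            raise InvalidRecordError("prednisolone_mg_day must be non-negative")


def sledai2k_total(visit: VisitRecord) -> int:
    """Full SLEDAI-2K score: sum of all item scores, serology included."""
    total = 0
    for name, score in visit.sledai_items.items():
        if score < 0:
            raise InvalidRecordError(f"negative SLEDAI item score {name}={score}")
        total += score
    return total


def csledai(visit: VisitRecord) -> int:
    """Clinical SLEDAI: SLEDAI-2K excluding the serologic items.

    The serologic items are low complement (C3/C4) and anti-dsDNA binding.
    Items absent from the catalogue are treated as clinical (non-serologic).
    """
    total = 0
    for name, score in visit.sledai_items.items():
        if score < 0:
            raise InvalidRecordError(f"negative SLEDAI item score {name}={score}")
        item = SLEDAI_ITEMS.get(name)
        if item is not None and item.serologic:
            continue
        total += score
    return total


def visits_by_patient(visits: Iterable[VisitRecord]) -> dict[str, list[VisitRecord]]:
    """Group visits by patient id, sorted by visit date within patient."""
    grouped: dict[str, list[VisitRecord]] = {}
    for v in visits:
        grouped.setdefault(v.patient_id, []).append(v)
    for pid in grouped:
        grouped[pid].sort(key=lambda v: v.visit_date)
    return grouped


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

_PATIENT_COLS = [
    "patient_id",
    "sex",
    "ethnicity",
    "diagnosis_date",
    "age_at_diagnosis",
    "ana_positive",
    "anti_dsdna_positive",
    "low_c3",
    "low_c4",
    "lymphopenia",
    "baseline_sdi",
]

_VISIT_SCALAR_COLS = [
    "patient_id",
    "visit_date",
    "age_at_visit",
    "weight_kg",
    "weight_provenance",
    "pga",
    "sdi",
    "prednisolone_mg_day",
    "iv_methylpred",
    "imsn_change",
    "anti_dsdna_positive",
    "low_c3",
    "low_c4",
]


def _bool_out(x: bool) -> int:
    return int(bool(x))


def _bool_in(x) -> bool:
    return bool(int(x))


def write_cohort(
    patients: Sequence[PatientRecord],
    visits: Sequence[VisitRecord],
    patients_path,
    visits_path,
) -> None:
    """Write a cohort to two UTF-8 CSV files (patients, visits).

    Visits are written sorted by (patient_id, visit_date); dates ISO-8601.
    ``read_cohort`` of the written files reproduces the records
    field-for-field (canonical float formatting via ``repr``).
    """
    prow = []
    for p in patients:
        d = dataclasses.asdict(p)
        d["diagnosis_date"] = p.diagnosis_date.isoformat()
        for c in ("ana_positive", "anti_dsdna_positive", "low_c3", "low_c4", "lymphopenia"):
            d[c] = _bool_out(d[c])
        prow.append(d)
    pd.DataFrame(prow, columns=_PATIENT_COLS).to_csv(patients_path, index=False)

    vrows = []
    for v in sorted(visits, key=lambda v: (v.patient_id, v.visit_date)):
        d = {c: getattr(v, c) for c in _VISIT_SCALAR_COLS}
        d["visit_date"] = v.visit_date.isoformat()
        d["weight_kg"] = "" if v.weight_kg is None else repr(float(v.weight_kg))
        d["pga"] = "" if v.pga is None else repr(float(v.pga))
        d["iv_methylpred"] = _bool_out(d["iv_methylpred"])
        for c in ("anti_dsdna_positive", "low_c3", "low_c4"):
            d[c] = "" if d[c] is None else _bool_out(d[c])
        for name in SLEDAI_ITEM_NAMES:
            d[f"sledai_{name}"] = v.sledai_items.get(name, 0)
        for dom in PBILAG_DOMAINS:
            d[f"pbilag_{dom}"] = v.pbilag_grades.get(dom, "E")
        vrows.append(d)
    cols = (
        _VISIT_SCALAR_COLS
        + [f"sledai_{n}" for n in SLEDAI_ITEM_NAMES]
        + [f"pbilag_{d}" for d in PBILAG_DOMAINS]
    )
    pd.DataFrame(vrows, columns=cols).to_csv(visits_path, index=False)


def read_cohort(patients_path, visits_path) -> tuple[list[PatientRecord], list[VisitRecord]]:
    """Read a cohort from the two-CSV layout written by :func:`write_cohort`.

    Raises
    ------
    CohortParseError
        On a token outside the closed vocabularies (ethnicity, grade, ...)
        or a duplicate (patient_id, visit_date) pair; the message names
        the offending row.
    """
    pdf = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    patients = []
    for i, row in pdf.iterrows():
        try:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    sex=row["sex"],
                    ethnicity=row["ethnicity"],
                    diagnosis_date=dt.date.fromisoformat(row["diagnosis_date"]),
                    age_at_diagnosis=float(row["age_at_diagnosis"]),
                    ana_positive=_bool_in(row["ana_positive"]),
                    anti_dsdna_positive=_bool_in(row["anti_dsdna_positive"]),
                    low_c3=_bool_in(row["low_c3"]),
                    low_c4=_bool_in(row["low_c4"]),
                    lymphopenia=_bool_in(row["lymphopenia"]),
                    baseline_sdi=int(row["baseline_sdi"]),
                )
            )
        except (CohortParseError, ValueError) as exc:
            raise CohortParseError(f"patients row {i}: {exc}") from exc

    vdf = pd.read_csv(visits_path, dtype=str, keep_default_na=False)
    visits: list[VisitRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in vdf.iterrows():
        key = (row["patient_id"], row["visit_date"])
        if key in seen:
            raise CohortParseError(
                f"visits row {i}: duplicate (patient, date) {key}"
            )
        seen.add(key)
        try:
            items = {}
            for name in SLEDAI_ITEM_NAMES:
                score = int(row[f"sledai_{name}"])
                if score:
                    items[name] = score
            grades = {dom: row[f"pbilag_{dom}"] for dom in PBILAG_DOMAINS}
            visits.append(
                VisitRecord(
                    patient_id=row["patient_id"],
                    visit_date=dt.date.fromisoformat(row["visit_date"]),
                    age_at_visit=float(row["age_at_visit"]),
                    weight_kg=None if row["weight_kg"] == "" else float(row["weight_kg"]),
                    weight_provenance=row["weight_provenance"],
                    sledai_items=items,
                    pga=None if row["pga"] == "" else float(row["pga"]),
                    pbilag_grades=grades,
                    sdi=int(row["sdi"]),
                    prednisolone_mg_day=float(row["prednisolone_mg_day"]),
                    iv_methylpred=_bool_in(row["iv_methylpred"]),
                    imsn_change=row["imsn_change"],
                    anti_dsdna_positive=(
                        None
                        if row["anti_dsdna_positive"] == ""
                        else _bool_in(row["anti_dsdna_positive"])
                    ),
                    low_c3=None if row["low_c3"] == "" else _bool_in(row["low_c3"]),
                    low_c4=None if row["low_c4"] == "" else _bool_in(row["low_c4"]),
                )
            )
        except (CohortParseError, InvalidRecordError, ValueError) as exc:
            raise CohortParseError(f"visits row {i}: {exc}") from exc

    visits.sort(key=lambda v: (v.patient_id, v.visit_date))
    return patients, visits
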