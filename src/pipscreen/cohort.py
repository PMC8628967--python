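"""Longitudinal cohort data model and I/O.

The cohort mirrors the structure of a geriatric trial database: one row of
baseline attributes per patient, interval-coded prescriptions (ATC level-5,
dose, start/end dates), date-stamped coded comorbidities, and one clinical
snapshot per 6-month follow-up visit (blood pressure supine/standing, heart
rate, GDS, Fried frailty, IADL).  ``state_at_visit`` resolves "what is true
for this patient at this visit": the prescriptions in force, the
comorbidities with onset at or before the visit date (with elapsed months,
for recency windows), and the most recent clinical snapshot.

Prescription activity is a closed interval [start_date, end_date]; an absent
end date means the prescription is ongoing.  Visits are indexed by month
offset from baseline (0, 6, ..., 36) and mapped to calendar dates through
the patient's baseline date.  Dates parse as ISO-8601 only.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

from .atc import is_level5

__all__ = [
    "CONDITION_VOCABULARY",
    "PatientRecord",
    "Prescription",
    "Comorbidity",
    "ClinicalSnapshot",
    "Cohort",
    "PatientState",
    "CohortLoadError",
    "load_cohort",
    "write_cohort",
    "active_prescriptions",
    "state_at_visit",
]

#: Controlled vocabulary for coded comorbidities (free-text coding is done
#: upstream by humans; the loader accepts only these labels in strict mode).
CONDITION_VOCABULARY: frozenset[str] = frozenset(
    {
        "hypertension",
        "myocardial_infarction",
        "heart_failure",
        "peripheral_vascular_disease",
        "cerebrovascular_accident_or_tia",
        "copd",
        "peptic_ulcer",
        "diabetes",
        "severe_chronic_kidney_disease",
        "cancer",
        "metastatic_cancer",
        "liver_failure",
        "severe_liver_disease",
        "nephrotic_syndrome",
        "renal_syndrome",
        "dementia",
        "prostatism",
        "prostatectomy",
        "oesogastric_damage",
        "osteoporosis",
        "aids",
    }
)

SEX_LEVELS = ("female", "male")
EDUCATION_LEVELS = (
    "no_diploma_or_primary",
    "secondary",
    "high_school",
    "university",
)
INTERVENTION_LEVELS = (
    "multidomain_pufa",
    "pufa",
    "multidomain_placebo",
    "placebo",
)
FRAILTY_LEVELS = ("robust", "prefrail", "frail")


class PatientRecord(BaseModel):
    patient_id: str
    sex: Literal["female", "male"]
    age_baseline: int
    education: Optional[Literal[EDUCATION_LEVELS]] = None
    intervention_group: Literal[INTERVENTION_LEVELS]
    baseline_date: dt.date
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24, 30, 36)

    @field_validator("age_baseline")
    @classmethod
    def _age_floor(cls, v: int) -> int:
        if v < 70:
            raise ValueError(f"age_baseline must be >= 70, got {v}")
        return v

    @model_validator(mode="after")
    def _visits_valid(self) -> "PatientRecord":
        vm = self.visit_months
        if not vm or list(vm) != sorted(set(vm)):
            raise ValueError("visit_months must be strictly increasing")
        if any(m < 0 or m > 36 for m in vm):
            raise ValueError("visit_months must lie within [0, 36]")
        return self

    def visit_date(self, visit_month: int) -> dt.date:
        """Calendar date of the visit at the given month offset."""
        return _add_months(self.baseline_date, visit_month)


class Prescription(BaseModel):
    patient_id: str
    atc_code: str
    name: str = ""
    inn: str = ""
    dose_value: Optional[float] = None
    dose_unit: str = ""
    start_date: dt.date
    end_date: Optional[dt.date] = None
    otc: bool = False

    @field_validator("atc_code")
    @classmethod
    def _atc_level5(cls, v: str) -> str:
        if not is_level5(v):
            raise ValueError(f"prescriptions must carry full level-5 ATC codes, got {v!r}")
        return v

    @model_validator(mode="after")
    def _dates_ordered(self) -> "Prescription":
        if self.end_date is not None and self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        return self

    def active_on(self, date: dt.date) -> bool:
        """Closed-interval activity check (end-inclusive; no end = ongoing)."""
        return self.start_date <= date and (self.end_date is None or self.end_date >= date)

    def duration_months_at(self, date: dt.date) -> float:
        """Months elapsed between start_date and *date* (for duration atoms)."""
        return (date - self.start_date).days / 30.4375


class Comorbidity(BaseModel):
    patient_id: str
    condition: str
    onset_date: dt.date


class ClinicalSnapshot(BaseModel):
    patient_id: str
    visit_month: int
    sbp_supine: Optional[float] = None
    dbp_supine: Optional[float] = None
    sbp_standing: Optional[float] = None
    dbp_standing: Optional[float] = None
    heart_rate: Optional[float] = None
    gds: Optional[float] = None
    frailty: Optional[Literal[FRAILTY_LEVELS]] = None
    iadl: Optional[float] = None

    def measure(self, field_name: str) -> Optional[float]:
        """Clinical value by name, including the derived orthostatic drop."""
        if field_name == "orthostatic_sbp_drop":
            if self.sbp_supine is None or self.sbp_standing is None:
                return None
            return self.sbp_supine - self.sbp_standing
        if field_name == "orthostatic_dbp_drop":
            if self.dbp_supine is None or self.dbp_standing is None:
                return None
            return self.dbp_supine - self.dbp_standing
        if not hasattr(self, field_name) or field_name in ("patient_id", "visit_month"):
            raise KeyError(f"unknown clinical field: {field_name!r}")
        return getattr(self, field_name)


class CohortLoadError(ValueError):
    """Raised when cohort CSVs violate the schema; carries row diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("cohort load failed:\n" + "\n".join(self.diagnostics))


@dataclass
class Cohort:
    """Validated in-memory cohort with per-patient indexes."""

    patients: dict[str, PatientRecord]
    prescriptions: dict[str, list[Prescription]] = field(default_factory=dict)
    comorbidities: dict[str, list[Comorbidity]] = field(default_factory=dict)
    snapshots: dict[str, dict[int, ClinicalSnapshot]] = field(default_factory=dict)
    visit_interval_months: int = 6

    def __post_init__(self) -> None:
        for pid in self.patients:
            self.prescriptions.setdefault(pid, [])
            self.comorbidities.setdefault(pid, [])
            self.snapshots.setdefault(pid, {})

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_visits(self) -> list[tuple[str, int]]:
        """All (patient_id, visit_month) pairs in schedule order."""
        return [
            (pid, m)
            for pid in sorted(self.patients)
            for m in self.patients[pid].visit_months
        ]

    def check_integrity(self) -> list[str]:
        """Referential-integrity diagnostics (empty when clean)."""
        problems = []
        for pid in set(self.prescriptions) - set(self.patients):
            problems.append(f"prescriptions reference unknown patient {pid!r}")
        for pid in set(self.comorbidities) - set(self.patients):
            problems.append(f"comorbidities reference unknown patient {pid!r}")
        for pid in set(self.snapshots) - set(self.patients):
            problems.append(f"snapshots reference unknown patient {pid!r}")
        return problems


@dataclass
class PatientState:
    """Everything the rules can read about one patient at one visit."""

    patient: PatientRecord
    visit_month: int
    visit_date: dt.date
    active: list[Prescription]
    #: condition label -> months elapsed since onset at this visit
    conditions: dict[str, float]
    snapshot: Optional[ClinicalSnapshot]

    @property
    def clinical_missing(self) -> bool:
        return self.snapshot is None


def _add_months(date: dt.date, months: int) -> dt.date:
    y, m = divmod(date.month - 1 + months, 12)
    year, month = date.year + y, m + 1
    # clamp day for short months
    day = min(date.day, [31, 29 if _leap(year) else 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1])
    return dt.date(year, month, day)


def _leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def months_between(earlier: dt.date, later: dt.date) -> float:
    """Elapsed months between two dates (mean month length)."""
    return (later - earlier).days / 30.4375


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FILES = ("patients", "prescriptions", "comorbidities", "clinical")


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def load_cohort(
    paths: Mapping[str, str | Path],
    *,
    strict_vocabulary: bool = True,
    extra_conditions: frozenset[str] | set[str] = frozenset(),
) -> Cohort:
    """Load and validate the four cohort CSVs.

    Parameters
    ----------
    paths
        Mapping with keys ``patients``, ``prescriptions``, ``comorbidities``,
        ``clinical`` to CSV file paths.
    strict_vocabulary
        If True (default), comorbidity labels outside the registered
        vocabulary are rejected with a diagnostic; if False, unknown labels
        pass through (flagged in the returned diagnostics-free cohort).
    extra_conditions
        Additional labels to register alongside the built-in vocabulary.

    Raises
    ------
    FileNotFoundError
        If a required file is missing.
    CohortLoadError
        If any row violates an invariant; the error carries one diagnostic
        per offending row (file, row index, reason).
    """
    vocab = CONDITION_VOCABULARY | frozenset(extra_conditions)
    for key in _FILES:
        if key not in paths:
            raise FileNotFoundError(f"missing path for {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"cohort file not found: {paths[key]}")

    diagnostics: list[str] = []

    def _rows(key):
        df = pd.read_csv(paths[key], dtype=str, keep_default_na=False)
        return df.to_dict("records")

    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(_rows("patients")):
        try:
            rec = PatientRecord(
                patient_id=row["patient_id"],
                sex=row["sex"],
                age_baseline=int(row["age_baseline"]),
                education=row["education"] or None,
                intervention_group=row["intervention_group"],
                baseline_date=_parse_date(row["baseline_date"]),
                visit_months=tuple(int(x) for x in row["visit_months"].split(";")),
            )
            if rec.patient_id in patients:
                raise ValueError(f"duplicate patient_id {rec.patient_id!r}")
            patients[rec.patient_id] = rec
        except (ValueError, KeyError) as exc:
            diagnostics.append(f"patients row {i}: {exc}")

    prescriptions: dict[str, list[Prescription]] = {}
    for i, row in enumerate(_rows("prescriptions")):
        try:
            rx = Prescription(
                patient_id=row["patient_id"],
                atc_code=row["atc_code"],
                name=row.get("name", ""),
                inn=row.get("inn", ""),
                dose_value=float(row["dose_value"]) if row.get("dose_value") else None,
                dose_unit=row.get("dose_unit", ""),
                start_date=_parse_date(row["start_date"]),
                end_date=_parse_date(row["end_date"]) if row.get("end_date") else None,
                otc=row.get("otc", "false").lower() in ("1", "true", "yes"),
            )
            if rx.patient_id not in patients:
                raise ValueError(f"unknown patient_id {rx.patient_id!r}")
            prescriptions.setdefault(rx.patient_id, []).append(rx)
        except (ValueError, KeyError) as exc:
            diagnostics.append(f"prescriptions row {i}: {exc}")

    comorbidities: dict[str, list[Comorbidity]] = {}
    for i, row in enumerate(_rows("comorbidities")):
        try:
            if strict_vocabulary and row["condition"] not in vocab:
                raise ValueError(f"condition {row['condition']!r} not in vocabulary")
            cm = Comorbidity(
                patient_id=row["patient_id"],
                condition=row["condition"],
                onset_date=_parse_date(row["onset_date"]),
            )
            if cm.patient_id not in patients:
                raise ValueError(f"unknown patient_id {cm.patient_id!r}")
            comorbidities.setdefault(cm.patient_id, []).append(cm)
        except (ValueError, KeyError) as exc:
            diagnostics.append(f"comorbidities row {i}: {exc}")

    snapshots: dict[str, dict[int, ClinicalSnapshot]] = {}
    for i, row in enumerate(_rows("clinical")):
        try:
            snap = ClinicalSnapshot(
                patient_id=row["patient_id"],
                visit_month=int(row["visit_month"]),
                **{
                    k: (float(row[k]) if row.get(k) else None)
                    for k in (
                        "sbp_supine",
                        "dbp_supine",
                        "sbp_standing",
                        "dbp_standing",
                        "heart_rate",
                        "gds",
                        "iadl",
                    )
                },
                frailty=row.get("frailty") or None,
            )
            if snap.patient_id not in patients:
                raise ValueError(f"unknown patient_id {snap.patient_id!r}")
            snapshots.setdefault(snap.patient_id, {})[snap.visit_month] = snap
        except (ValueError, KeyError) as exc:
            diagnostics.append(f"clinical row {i}: {exc}")

    if diagnostics:
        raise CohortLoadError(diagnostics)
    return Cohort(
        patients=patients,
        prescriptions=prescriptions,
        comorbidities=comorbidities,
        snapshots=snapshots,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs (ISO-8601 dates, empty string for missing)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in _FILES}

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "age_baseline": p.age_baseline,
                "education": p.education or "",
                "intervention_group": p.intervention_group,
                "baseline_date": p.baseline_date.isoformat(),
                "visit_months": ";".join(str(m) for m in p.visit_months),
            }
            for p in cohort.patients.values()
        ]
    ).to_csv(paths["patients"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": rx.patient_id,
                "atc_code": rx.atc_code,
                "name": rx.name,
                "inn": rx.inn,
                "dose_value": "" if rx.dose_value is None else rx.dose_value,
                "dose_unit": rx.dose_unit,
                "start_date": rx.start_date.isoformat(),
                "end_date": "" if rx.end_date is None else rx.end_date.isoformat(),
                "otc": str(rx.otc).lower(),
            }
            for rxs in cohort.prescriptions.values()
            for rx in rxs
        ],
        columns=[
            "patient_id", "atc_code", "name", "inn", "dose_value",
            "dose_unit", "start_date", "end_date", "otc",
        ],
    ).to_csv(paths["prescriptions"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "condition": c.condition,
                "onset_date": c.onset_date.isoformat(),
            }
            for cms in cohort.comorbidities.values()
            for c in cms
        ],
        columns=["patient_id", "condition", "onset_date"],
    ).to_csv(paths["comorbidities"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "visit_month": s.visit_month,
                **{
                    k: ("" if getattr(s, k) is None else getattr(s, k))
                    for k in (
                        "sbp_supine", "dbp_supine", "sbp_standing", "dbp_standing",
                        "heart_rate", "gds",
                    )
                },
                "frailty": s.frailty or "",
                "iadl": "" if s.iadl is None else s.iadl,
            }
            for snaps in cohort.snapshots.values()
            for s in snaps.values()
        ],
        columns=[
            "patient_id", "visit_month", "sbp_supine", "dbp_supine",
            "sbp_standing", "dbp_standing", "heart_rate", "gds", "frailty", "iadl",
        ],
    ).to_csv(paths["clinical"], index=False)

    return paths


# ---------------------------------------------------------------------------
# Temporal resolution
# ---------------------------------------------------------------------------

def active_prescriptions(
    cohort: Cohort, patient_id: str, visit_date: dt.date
) -> list[Prescription]:
    """Prescriptions in force on *visit_date* (closed interval, end-inclusive).

    Order is stable by (start_date, atc_code).
    """
    if patient_id not in cohort.patients:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    hits = [rx for rx in cohort.prescriptions[patient_id] if rx.active_on(visit_date)]
    hits.sort(key=lambda rx: (rx.start_date, rx.atc_code))
    return hits


def state_at_visit(cohort: Cohort, patient_id: str, visit_month: int) -> PatientState:
    """Assemble the full patient state the rules read at one visit.

    Bundles the active prescriptions, the comorbidities with onset on or
    before the visit date (with months elapsed since onset), and the most
    recent clinical snapshot at or before the visit.  A missing snapshot is
    not an error: the state carries ``snapshot=None`` and criteria reading
    clinical values abstain.
    """
    if patient_id not in cohort.patients:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    patient = cohort.patients[patient_id]
    if visit_month not in patient.visit_months:
        raise ValueError(
            f"visit_month {visit_month} not in schedule of patient {patient_id!r}"
        )
    visit_date = patient.visit_date(visit_month)
    conditions: dict[str, float] = {}
    for cm in cohort.comorbidities[patient_id]:
        if cm.onset_date <= visit_date:
            elapsed = months_between(cm.onset_date, visit_date)
            # keep the most recent onset per label (shortest elapsed time)
            if cm.condition not in conditions or elapsed < conditions[cm.condition]:
                conditions[cm.condition] = elapsed
    snaps = cohort.snapshots[patient_id]
    eligible = [m for m in snaps if m <= visit_month]
    snapshot = snaps[max(eligible)] if eligible else None
    return PatientState(
        patient=patient,
        visit_month=visit_month,
        visit_date=visit_date,
        active=active_prescriptions(cohort, patient_id, visit_date),
        conditions=conditions,
        snapshot=snapshot,
    )
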