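import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pipscreen import (
    ClinicalSnapshot,
    Cohort,
    Comorbidity,
    PatientRecord,
    Prescription,
    builtin_rulebank,
)

BASELINE = dt.date(2015, 1, 15)


@pytest.fixture(scope="session")
def bank():
    return builtin_rulebank()


def make_patient(pid="P1", sex="female", age=75, education="secondary",
                 intervention="placebo", visits=(0, 6, 12, 18, 24, 30, 36)):
    return PatientRecord(
        patient_id=pid, sex=sex, age_baseline=age, education=education,
        intervention_group=intervention, baseline_date=BASELINE,
        visit_months=tuple(visits),
    )


def make_rx(pid="P1", atc="N05BA01", start=None, end=None, dose=None, unit="mg"):
    start = start if start is not None else BASELINE - dt.timedelta(days=30)
    return Prescription(
        patient_id=pid, atc_code=atc, name=atc, inn=atc,
        dose_value=dose, dose_unit=unit, start_date=start, end_date=end,
    )


def make_cohort(patients, prescriptions=(), comorbidities=(), snapshots=()):
    """Assemble a cohort from record lists (validated model instances)."""
    pats = {p.patient_id: p for p in patients}
    rx: dict[str, list] = {pid: [] for pid in pats}
    for r in prescriptions:
        rx[r.patient_id].append(r)
    cms: dict[str, list] = {pid: [] for pid in pats}
    for c in comorbidities:
        cms[c.patient_id].append(c)
    snaps: dict[str, dict] = {pid: {} for pid in pats}
    for s in snapshots:
        snaps[s.patient_id][s.visit_month] = s
    return Cohort(patients=pats, prescriptions=rx, comorbidities=cms,
                  snapshots=snaps)


def make_condition(pid, condition, months_before_baseline=24.0):
    return Comorbidity(
        patient_id=pid, condition=condition,
        onset_date=BASELINE - dt.timedelta(days=round(months_before_baseline * 30.4375)),
    )


def make_snapshot(pid, month=0, **kw):
    defaults = dict(sbp_supine=135.0, dbp_supine=80.0, sbp_standing=130.0,
                    dbp_standing=78.0, heart_rate=70.0, gds=2.0,
                    frailty="robust", iadl=8.0)
    defaults.update(kw)
    return ClinicalSnapshot(patient_id=pid, visit_month=month, **defaults)
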