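"""Synthetic longitudinal cohorts with exactly known planted PIP truth.

The generator emulates a 3-year community-dwelling geriatric cohort (ages
>= 70, 6-month visit grid) whose covariate marginals follow the reference
study population: age groups 0.50/0.32/0.18 at the 75/80 thresholds, 64%
female, the published education / intervention / comorbidity / medication-
count marginals.  Its purpose is testability: every rule firing is
*constructed*, never sampled and re-discovered, so the ground truth ledger
(:class:`SimTruth`) is exact by construction.

Two planting modes:

* **Outcome-model mode** (default): each patient-visit receives a latent
  PIP status from a random-intercept logistic model over age group,
  polypharmacy category and Charlson category (the planted effect sizes are
  the generator's parameters, enabling parameter-recovery experiments).
  A PIP-positive visit gets one or more *trigger constructs* — curated drug
  / condition / measurement bundles that satisfy a known rule set exactly —
  and a PIP-negative visit gets only neutral filler drugs verified at
  generator start to match no rule atom.
* **Tool-prevalence mode** (``tool_prevalences`` set): at baseline, each
  tool independently plants its tool-pure construct with the configured
  probability, so per-tool patient prevalences are exact Bernoulli draws.

Constructive bookkeeping keeps the ledger exact across the visit grid:
planted prescriptions live in short windows covering a single visit;
planted omission conditions onset just before their visit and are "cured"
(the omitted drug is started) one month later; medication counts are
topped up with fillers to the patient's target count, so planting never
moves a patient across a polypharmacy category boundary.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .charlson import charlson_category, charlson_index
from .cohort import (
    ClinicalSnapshot,
    Cohort,
    Comorbidity,
    PatientRecord,
    Prescription,
)
from .rules import CoPrescribedCount, DrugAbsent, DrugActive, RuleBank
from .stats import categorize_age, categorize_polypharmacy

__all__ = ["PlantedEffects", "SimConfig", "SimTruth", "generate_cohort",
           "planted_outcome_dataset"]

_BASELINE_DATE = dt.date(2015, 1, 15)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class PlantedEffects:
    """Log-odds structure of the latent PIP outcome model."""

    intercept: float = _logit(0.15)
    age_75_79: float = math.log(2.75)
    age_ge80: float = math.log(5.36)
    poly_5_9: float = math.log(26.64)
    poly_ge10: float = math.log(662.16)
    charlson_1: float = math.log(10.89)
    charlson_ge2: float = math.log(21.93)
    sigma_u: float = 1.0

    @classmethod
    def null(cls, prevalence: float = 0.3, sigma_u: float = 1.0) -> "PlantedEffects":
        """No covariate effects; overall prevalence set by the intercept."""
        return cls(
            intercept=_logit(prevalence),
            age_75_79=0.0, age_ge80=0.0, poly_5_9=0.0, poly_ge10=0.0,
            charlson_1=0.0, charlson_ge2=0.0, sigma_u=sigma_u,
        )


@dataclass
class SimConfig:
    n_patients: int = 1525
    seed: int = 0
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24, 30, 36)
    age_group_probs: tuple[float, float, float] = (0.50, 0.32, 0.18)
    female_prob: float = 0.64
    education_probs: tuple[float, float, float, float] = (0.22, 0.34, 0.15, 0.29)
    intervention_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.66,
            "myocardial_infarction": 0.06,
            "heart_failure": 0.04,
            "peripheral_vascular_disease": 0.03,
            "cerebrovascular_accident_or_tia": 0.03,
            "copd": 0.03,
            "peptic_ulcer": 0.04,
            "diabetes": 0.01,
            "severe_chronic_kidney_disease": 0.01,
            "cancer": 0.01,
        }
    )
    polypharmacy_probs: tuple[float, float, float] = (0.53, 0.39, 0.08)
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    #: per-tool baseline planting probabilities; switches to
    #: tool-prevalence mode when set
    tool_prevalences: Optional[dict[str, float]] = None
    frailty_missing: float = 0.05
    education_missing: float = 0.02
    dropout_per_visit: float = 0.0
    #: distribution of the number of constructs planted at a PIP visit
    n_trigger_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def validate(self) -> None:
        for name, probs in (
            ("age_group_probs", self.age_group_probs),
            ("education_probs", self.education_probs),
            ("intervention_probs", self.intervention_probs),
            ("polypharmacy_probs", self.polypharmacy_probs),
            ("n_trigger_probs", self.n_trigger_probs),
        ):
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        for c, p in self.comorbidity_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {c} out of [0,1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class SimTruth:
    """Exact ground truth of one generated cohort."""

    #: (patient_id, visit_month) -> rule ids expected to fire (non-PIP
    #: visits are absent and expected to fire nothing)
    planted: dict[tuple[str, int], frozenset[str]]
    #: one record per patient-visit: covariates + true PIP status
    rows: list[dict]
    effects: PlantedEffects
    seed: int

    def expected_rules(self, patient_id: str, visit_month: int) -> frozenset[str]:
        return self.planted.get((patient_id, visit_month), frozenset())

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "effects": asdict(self.effects),
            "planted": [
                {"patient_id": p, "visit_month": v, "rule_ids": sorted(rs)}
                for (p, v), rs in sorted(self.planted.items())
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Trigger constructs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Construct:
    name: str
    tool: str
    fires: frozenset[str]
    #: (atc, dose_value, dose_unit, months_before_visit, months_after_visit)
    drugs: tuple[tuple[str, float, str, float, float], ...] = ()
    needs_existing: tuple[str, ...] = ()   # conditions the patient must already have
    forbids: tuple[str, ...] = ()          # conditions that make it infeasible
    adds_condition: Optional[str] = None   # onset 1 month before the visit
    cure_atc: Optional[str] = None         # started 1 month after the visit, ongoing
    male_only: bool = False
    orthostatic: bool = False              # force standing SBP drop >= 20 at visit
    once_per_patient: bool = False
    exclusive_group: Optional[str] = None


_CONSTRUCTS: tuple[_Construct, ...] = (
    _Construct("eu7_benzo", "EU7_PIM",
               frozenset({"EU7_N05BA01", "AMI_BENZO_LONG"}),
               drugs=((("N05BA01"), 5.0, "mg", 1.0, 1.0),)),
    _Construct("eu7_amiodarone", "EU7_PIM", frozenset({"EU7_C01BD01"}),
               drugs=(("C01BD01", 200.0, "mg", 1.0, 1.0),)),
    _Construct("eu7_nsaid", "EU7_PIM", frozenset({"EU7_M01AB05"}),
               drugs=(("M01AB05", 50.0, "mg", 1.0, 1.0),)),
    _Construct("stopp_a1a_statin", "STOPP", frozenset({"STOPP_A1A"}),
               drugs=(("C10AA01", 20.0, "mg", 1.0, 1.0),),
               forbids=("myocardial_infarction", "cerebrovascular_accident_or_tia",
                        "peripheral_vascular_disease")),
    _Construct("stopp_a1a_aspirin", "STOPP", frozenset({"STOPP_A1A"}),
               drugs=(("B01AC06", 75.0, "mg", 1.0, 1.0),),
               forbids=("myocardial_infarction", "cerebrovascular_accident_or_tia",
                        "peripheral_vascular_disease")),
    _Construct("stopp_a1b_ppi", "STOPP", frozenset({"STOPP_A1B"}),
               drugs=(("A02BC01", 20.0, "mg", 1.0, 1.0),),
               forbids=("oesogastric_damage",)),
    _Construct("stopp_b6", "STOPP", frozenset({"STOPP_B6"}),
               drugs=(("C03CA01", 40.0, "mg", 1.0, 1.0),),
               needs_existing=("hypertension",),
               forbids=("heart_failure", "liver_failure", "nephrotic_syndrome",
                        "renal_syndrome"),
               exclusive_group="antihypertensive"),
    _Construct("ami_ortho", "AMI", frozenset({"AMI_ORTHOSTATIC"}),
               drugs=(("C07AB07", 5.0, "mg", 1.0, 1.0),),
               orthostatic=True, exclusive_group="antihypertensive"),
    _Construct("ami_psycho", "AMI", frozenset({"AMI_PSYCHOTROPIC_3"}),
               drugs=(("N06AB06", 50.0, "mg", 1.0, 1.0),
                      ("N06AX11", 15.0, "mg", 1.0, 1.0),
                      ("N06AX05", 100.0, "mg", 1.0, 1.0))),
    _Construct("ami_nsaid", "AMI", frozenset({"AMI_NSAID_DURATION"}),
               drugs=(("M01AE01", 400.0, "mg", 4.0, 1.0),)),
    _Construct("start_g1", "START", frozenset({"START_G1G2"}),
               adds_condition="prostatism", cure_atc="G04CA02",
               forbids=("prostatism", "prostatectomy"),
               male_only=True, once_per_patient=True),
    _Construct("start_e3", "START", frozenset({"START_E3"}),
               adds_condition="osteoporosis", cure_atc="M05BA04",
               forbids=("osteoporosis",), once_per_patient=True),
    _Construct("wd_sibutramine", "WITHDRAWAL", frozenset({"WD_A08AA10"}),
               drugs=(("A08AA10", 10.0, "mg", 1.0, 1.0),)),
    _Construct("ci_nitrate_pde5", "CONTRAINDICATION", frozenset({"CI_NITRATE_PDE5"}),
               drugs=(("C01DA14", 40.0, "mg", 1.0, 1.0),
                      ("G04BE03", 50.0, "mg", 1.0, 1.0))),
)

#: tool -> construct used in tool-prevalence mode (fires only its own tool)
_TOOL_PURE = {
    "EU7_PIM": "eu7_amiodarone",
    "STOPP": "stopp_a1b_ppi",
    "START": "start_e3",
    "AMI": "ami_psycho",
    "WITHDRAWAL": "wd_sibutramine",
    "CONTRAINDICATION": "ci_nitrate_pde5",
}

#: neutral filler drugs, checked against the rulebank at generator start
_FILLER_POOL: tuple[str, ...] = (
    "A02AD01", "A06AD11", "A06AD15", "A10BA02", "A11DA01", "A11GA01",
    "B01AA03", "B03AA07", "B03BA01", "B03BB01", "D01AC01", "H03AA01",
    "J01CA04", "M02AA15", "N02BE01", "N07CA01", "R03AC02", "R03BB04",
    "S01XA20",
)


def _assert_fillers_neutral(bank: RuleBank) -> None:
    """Every filler and cure drug must match no rule drug atom."""
    watched: set[str] = set()
    for rule in bank.rules:
        for node in rule.trigger.walk():
            if isinstance(node, DrugActive):
                watched.update(node.atc)
            elif isinstance(node, CoPrescribedCount):
                watched.update(node.atc)
            elif isinstance(node, DrugAbsent):
                watched.update(node.atc)
    offenders = [
        code
        for code in _FILLER_POOL
        if any(code.startswith(p) for p in watched)
    ]
    if offenders:
        raise ValueError(f"filler drugs collide with rule atoms: {offenders}")


def _missing_constructs(bank: RuleBank) -> list[str]:
    have = set(bank.rule_ids())
    missing = sorted(
        {rid for c in _CONSTRUCTS for rid in c.fires if rid not in have}
    )
    return missing


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _add_months_date(date: dt.date, months: float) -> dt.date:
    return date + dt.timedelta(days=round(months * 30.4375))


def generate_cohort(config: SimConfig, bank: RuleBank) -> tuple[Cohort, SimTruth]:
    """Generate a cohort plus its exact planted-truth ledger.

    Reproducible: the output is a pure function of (config, bank).  Raises
    if the rulebank lacks any rule the trigger constructs rely on, or if a
    filler drug would collide with a rule atom.
    """
    config.validate()
    _assert_fillers_neutral(bank)
    missing = _missing_constructs(bank)
    if missing:
        raise ValueError(f"rulebank is missing planted rules: {missing}")
    if config.tool_prevalences:
        unknown = sorted(set(config.tool_prevalences) - set(_TOOL_PURE))
        if unknown:
            raise ValueError(f"unknown tools in tool_prevalences: {unknown}")

    rng = np.random.default_rng(config.seed)
    eff = config.effects
    by_name = {c.name: c for c in _CONSTRUCTS}

    patients: dict[str, PatientRecord] = {}
    prescriptions: dict[str, list[Prescription]] = {}
    comorbidities: dict[str, list[Comorbidity]] = {}
    snapshots: dict[str, dict[int, ClinicalSnapshot]] = {}
    planted: dict[tuple[str, int], frozenset[str]] = {}
    rows: list[dict] = []

    pad = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{pad}d}"
        # --- baseline covariates ------------------------------------------
        age_grp = rng.choice(3, p=config.age_group_probs)
        age = int(rng.integers(*((70, 75), (75, 80), (80, 90))[age_grp]))
        sex = "female" if rng.random() < config.female_prob else "male"
        education = ("no_diploma_or_primary", "secondary", "high_school",
                     "university")[rng.choice(4, p=config.education_probs)]
        if rng.random() < config.education_missing:
            education = None
        intervention = ("multidomain_pufa", "pufa", "multidomain_placebo",
                        "placebo")[rng.choice(4, p=config.intervention_probs)]
        conditions = {
            c for c, prev in config.comorbidity_prevalence.items()
            if rng.random() < prev
        }
        charl_cat = charlson_category(charlson_index(conditions))

        visit_months = list(config.visit_months)
        if config.dropout_per_visit > 0:
            kept = [visit_months[0]]
            for m in visit_months[1:]:
                if rng.random() < config.dropout_per_visit:
                    break
                kept.append(m)
            visit_months = kept

        rec = PatientRecord.model_construct(
            patient_id=pid, sex=sex, age_baseline=age, education=education,
            intervention_group=intervention, baseline_date=_BASELINE_DATE,
            visit_months=tuple(visit_months),
        )
        patients[pid] = rec
        comorbidities[pid] = [
            Comorbidity.model_construct(
                patient_id=pid, condition=c,
                onset_date=_add_months_date(
                    _BASELINE_DATE, -float(rng.integers(6, 120))
                ),
            )
            for c in sorted(conditions)
        ]

        poly_cat_idx = rng.choice(3, p=config.polypharmacy_probs)
        n_target = int(rng.integers(*((0, 5), (5, 10), (10, 14))[poly_cat_idx]))

        u_i = rng.normal(0.0, eff.sigma_u)
        frailty_state = rng.choice(3, p=(0.55, 0.42, 0.03))

        rx_list: list[Prescription] = []
        cures: list[tuple[float, str]] = []  # (start month offset, atc)
        planted_conditions: set[str] = set()
        once_used: set[str] = set()

        for month in visit_months:
            visit_date = rec.visit_date(month)

            # --- latent PIP and construct selection -----------------------
            if config.tool_prevalences is not None:
                chosen = (
                    [
                        by_name[_TOOL_PURE[tool]]
                        for tool, q in sorted(config.tool_prevalences.items())
                        if rng.random() < q
                        and _feasible(by_name[_TOOL_PURE[tool]], sex, conditions,
                                      planted_conditions, once_used)
                    ]
                    if month == 0
                    else []
                )
                pip = bool(chosen)
            else:
                eta = (
                    eff.intercept
                    + (0.0, eff.age_75_79, eff.age_ge80)[age_grp]
                    + (0.0, eff.poly_5_9, eff.poly_ge10)[poly_cat_idx]
                    + {"0": 0.0, "1": eff.charlson_1, ">=2": eff.charlson_ge2}[charl_cat]
                    + u_i
                )
                pip = rng.random() < 1.0 / (1.0 + math.exp(-eta))
                chosen = []
                if pip:
                    k = 1 + rng.choice(3, p=config.n_trigger_probs)
                    cures_active = sum(1 for off, _ in cures if off <= month)
                    capacity = n_target - cures_active
                    groups_used: set[str] = set()
                    order = rng.permutation(len(_CONSTRUCTS))
                    for j in order:
                        if len(chosen) >= k:
                            break
                        c = _CONSTRUCTS[j]
                        if c.exclusive_group and c.exclusive_group in groups_used:
                            continue
                        if not _feasible(c, sex, conditions, planted_conditions,
                                         once_used):
                            continue
                        if c.drugs and len(c.drugs) > capacity:
                            continue
                        chosen.append(c)
                        capacity -= len(c.drugs)
                        if c.exclusive_group:
                            groups_used.add(c.exclusive_group)
                        if c.adds_condition:
                            planted_conditions.add(c.adds_condition)
                        if c.once_per_patient:
                            once_used.add(c.name)
                    if not chosen:
                        # capacity exhausted and omissions spent: plant the
                        # smallest feasible drug construct (count may exceed
                        # the target by one, never crossing a category edge)
                        for j in order:
                            c = _CONSTRUCTS[j]
                            if len(c.drugs) == 1 and _feasible(
                                c, sex, conditions, planted_conditions, once_used
                            ):
                                chosen.append(c)
                                break
                    if not chosen:  # pragma: no cover - defensive
                        raise RuntimeError("no feasible trigger construct")

            # --- materialize the chosen constructs ------------------------
            fired: set[str] = set()
            ortho = False
            n_planted_drugs = 0
            for c in chosen:
                fired |= c.fires
                ortho = ortho or c.orthostatic
                for atc, dose, unit, before, after in c.drugs:
                    rx_list.append(
                        Prescription.model_construct(
                            patient_id=pid, atc_code=atc, name=atc, inn=atc,
                            dose_value=dose, dose_unit=unit,
                            start_date=_add_months_date(visit_date, -before),
                            end_date=_add_months_date(visit_date, after),
                            otc=False,
                        )
                    )
                    n_planted_drugs += 1
                if c.adds_condition:
                    comorbidities[pid].append(
                        Comorbidity.model_construct(
                            patient_id=pid, condition=c.adds_condition,
                            onset_date=_add_months_date(visit_date, -1.0),
                        )
                    )
                if c.cure_atc:
                    cures.append((month + 1.0, c.cure_atc))
                    rx_list.append(
                        Prescription.model_construct(
                            patient_id=pid, atc_code=c.cure_atc, name=c.cure_atc,
                            inn=c.cure_atc, dose_value=1.0, dose_unit="mg",
                            start_date=_add_months_date(visit_date, 1.0),
                            end_date=None, otc=False,
                        )
                    )
            if fired:
                planted[(pid, month)] = frozenset(fired)

            # --- fillers up to the medication-count target ----------------
            cures_active = sum(1 for off, _ in cures if off <= month)
            n_fill = max(0, n_target - n_planted_drugs - cures_active)
            if n_fill:
                for code in rng.choice(
                    _FILLER_POOL, size=min(n_fill, len(_FILLER_POOL)), replace=False
                ):
                    rx_list.append(
                        Prescription.model_construct(
                            patient_id=pid, atc_code=str(code), name=str(code),
                            inn=str(code), dose_value=1.0, dose_unit="tablet",
                            start_date=_add_months_date(visit_date, -1.0),
                            end_date=_add_months_date(visit_date, 1.0),
                            otc=False,
                        )
                    )
            n_active = max(n_target, n_planted_drugs + cures_active)

            # --- clinical snapshot ----------------------------------------
            sbp = float(rng.normal(135, 15))
            # clip the orthostatic drop one unit away from the 20 mmHg rule
            # threshold so one-decimal rounding cannot flip a planted state
            drop = float(min(rng.normal(5, 5), 13.0))
            if ortho:
                drop = float(max(rng.normal(25, 4), 21.0))
            frailty_state = _frailty_step(frailty_state, rng)
            frailty = ("robust", "prefrail", "frail")[frailty_state]
            frailty_out = (
                None if rng.random() < config.frailty_missing else frailty
            )
            snapshots.setdefault(pid, {})[month] = ClinicalSnapshot.model_construct(
                patient_id=pid, visit_month=month,
                sbp_supine=round(sbp, 1), dbp_supine=round(sbp * 0.6, 1),
                sbp_standing=round(sbp - drop, 1),
                dbp_standing=round(sbp * 0.6 - drop / 2, 1),
                heart_rate=round(float(rng.normal(70, 10)), 1),
                gds=float(rng.integers(0, 8)),
                frailty=frailty_out,
                iadl=8.0 + (float(rng.integers(1, 5)) if rng.random() < 0.04 else 0.0),
            )

            rows.append(
                {
                    "patient_id": pid,
                    "visit_month": month,
                    "pip": int(pip),
                    "sex": sex,
                    "age_group": categorize_age(age),
                    "education": education,
                    "intervention_group": intervention,
                    "polypharmacy_category": categorize_polypharmacy(n_active),
                    "charlson_category": charl_cat,
                    "frailty": frailty_out,
                }
            )

        prescriptions[pid] = rx_list

    cohort = Cohort(
        patients=patients,
        prescriptions=prescriptions,
        comorbidities=comorbidities,
        snapshots=snapshots,
    )
    truth = SimTruth(planted=planted, rows=rows, effects=eff, seed=config.seed)
    return cohort, truth


def _feasible(
    c: _Construct,
    sex: str,
    conditions: set[str],
    planted_conditions: set[str],
    once_used: set[str],
) -> bool:
    if c.male_only and sex != "male":
        return False
    if c.name in once_used:
        return False
    present = conditions | planted_conditions
    if any(f in present for f in c.forbids):
        return False
    if any(r not in present for r in c.needs_existing):
        return False
    return True


def _frailty_step(state: int, rng: np.random.Generator) -> int:
    """Slow Markov drift over robust / prefrail / frail."""
    r = rng.random()
    if r < 0.9:
        return state
    if state == 0:
        return 1
    if state == 2:
        return 1 if r < 0.95 else 2
    return 0 if r < 0.95 else 2


def planted_outcome_dataset(cohort: Cohort, truth: SimTruth) -> pd.DataFrame:
    """One row per patient-visit with *true* PIP status and covariates.

    This is the bridge to model calibration and parameter-recovery
    experiments: the outcome comes from the planted latent model, not from
    running the rule engine.
    """
    df = pd.DataFrame(truth.rows)
    n_expected = sum(len(p.visit_months) for p in cohort.patients.values())
    if len(df) != n_expected:
        raise ValueError("truth rows do not match the cohort visit schedule")
    return df
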