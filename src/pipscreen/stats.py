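"""Construct-validity statistics: categorization, baseline contingency tests.

Covariates follow the conventions of geriatric PIP studies: age grouped at
the 75- and 80-year thresholds; medication counts grouped as
non-polypharmacy (0-4), polypharmacy (5-9) and hyperpolypharmacy (>=10);
the Charlson index as 0 / 1 / >=2.

Baseline group comparisons (patients with vs without PIP) use the Pearson
chi-square test *without* continuity correction, switching to Fisher's
exact test when any expected cell count is below 5 (2x2 tables only).  The
two-sided Fisher p-value follows the minimum-likelihood rule: the sum of
the probabilities of all tables with the observed margins whose point
probability does not exceed that of the observed table.

A packaged reference dataset of published baseline cross-tabulations for a
cohort of 1,525 community-dwelling adults aged >=70 is provided to
exercise the full test-selection path against printed results.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .charlson import charlson_category, charlson_index
from .cohort import Cohort, state_at_visit
from .engine import PIPFlag

__all__ = [
    "AGE_GROUPS",
    "POLYPHARMACY_CATEGORIES",
    "categorize_age",
    "categorize_polypharmacy",
    "ContingencyTable",
    "TestResult",
    "expected_counts",
    "chi_square_p",
    "fisher_two_sided_p",
    "select_test",
    "run_selected_test",
    "baseline_table",
    "build_analysis_dataset",
    "reference_baseline_tables",
]

AGE_GROUPS = ("<=74", "75-79", ">=80")
POLYPHARMACY_CATEGORIES = ("0-4", "5-9", ">=10")


def categorize_age(age: int | float) -> str:
    """Age group at thresholds 75 and 80 years."""
    if age < 70:
        warnings.warn(f"age {age} below the cohort definition (>=70)", stacklevel=2)
    if age <= 74:
        return "<=74"
    if age <= 79:
        return "75-79"
    return ">=80"


def categorize_polypharmacy(n_drugs: int) -> str:
    """Non-polypharmacy (0-4), polypharmacy (5-9), hyperpolypharmacy (>=10)."""
    if n_drugs < 0:
        raise ValueError(f"number of medications must be >= 0, got {n_drugs}")
    if n_drugs <= 4:
        return "0-4"
    if n_drugs <= 9:
        return "5-9"
    return ">=10"


@dataclass
class ContingencyTable:
    """PIP-status x category cross-tabulation."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (n_rows, n_cols), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match counts shape")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def column_percents(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / col_tot


@dataclass
class TestResult:
    method: str  # "pearson_chi_square" | "fisher_exact"
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence: E_ij = R_i C_j / N."""
    r = table.counts.sum(axis=1)
    c = table.counts.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    return np.outer(r, c) / table.total


def chi_square_p(table: ContingencyTable) -> TestResult:
    """Pearson chi-square without continuity correction."""
    e = expected_counts(table)  # raises on degenerate margins
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    stat, p, df, _ = sps.chi2_contingency(table.counts, correction=False)
    return TestResult(method="pearson_chi_square", p_value=float(p),
                      statistic=float(stat), df=int(df))


def fisher_two_sided_p(table: ContingencyTable) -> TestResult:
    """Exact two-sided Fisher p (minimum-likelihood rule), 2x2 only."""
    if table.counts.shape != (2, 2):
        raise ValueError("Fisher's exact test supports only 2x2 tables")
    _, p = sps.fisher_exact(table.counts.astype(int), alternative="two-sided")
    return TestResult(method="fisher_exact", p_value=float(p))


def select_test(table: ContingencyTable) -> str:
    """Fisher iff any expected count < 5 and the table is 2x2, else chi-square."""
    e = expected_counts(table)
    if (e < 5).any():
        if table.counts.shape == (2, 2):
            return "fisher_exact"
        warnings.warn(
            "expected count < 5 on a non-2x2 table; falling back to chi-square",
            stacklevel=2,
        )
    return "pearson_chi_square"


def run_selected_test(table: ContingencyTable) -> TestResult:
    """Apply the automatically selected test to the table."""
    if select_test(table) == "fisher_exact":
        return fisher_two_sided_p(table)
    return chi_square_p(table)


# ---------------------------------------------------------------------------
# Analysis dataset and baseline table
# ---------------------------------------------------------------------------

_CONDITION_VARIABLES_HINT = "a covariate name or a condition label"


def build_analysis_dataset(cohort: Cohort, flags: list[PIPFlag]) -> pd.DataFrame:
    """One row per patient-visit: PIP status plus model covariates.

    Polypharmacy and frailty are time-varying (resolved at each visit); age
    group, education, intervention and the Charlson category are baseline
    attributes.  Missing cells are NaN.
    """
    rows = []
    charlson_cache: dict[str, str] = {}
    for f in flags:
        p = cohort.patients[f.patient_id]
        if f.patient_id not in charlson_cache:
            baseline_conditions = [
                c.condition
                for c in cohort.comorbidities[f.patient_id]
                if c.onset_date <= p.baseline_date
            ]
            charlson_cache[f.patient_id] = charlson_category(
                charlson_index(baseline_conditions)
            )
        state = state_at_visit(cohort, f.patient_id, f.visit_month)
        frailty = state.snapshot.frailty if state.snapshot is not None else None
        rows.append(
            {
                "patient_id": f.patient_id,
                "visit_month": f.visit_month,
                "pip": int(f.pip),
                "sex": p.sex,
                "age_group": categorize_age(p.age_baseline),
                "education": p.education,
                "intervention_group": p.intervention_group,
                "polypharmacy_category": categorize_polypharmacy(len(state.active)),
                "charlson_category": charlson_cache[f.patient_id],
                "frailty": frailty,
            }
        )
    return pd.DataFrame(rows)


_BASELINE_VARIABLES = {
    "sex": ("female", "male"),
    "age_group": AGE_GROUPS,
    "education": ("no_diploma_or_primary", "secondary", "high_school", "university"),
    "intervention_group": ("multidomain_pufa", "pufa", "multidomain_placebo", "placebo"),
    "polypharmacy_category": POLYPHARMACY_CATEGORIES,
    "charlson_category": ("0", "1", ">=2"),
    "frailty": ("robust", "prefrail", "frail"),
}


def baseline_table(
    cohort: Cohort, flags: list[PIPFlag], variable: str
) -> tuple[ContingencyTable, TestResult]:
    """Cross-tabulate baseline PIP status against one covariate and test it.

    *variable* is either a registered categorical covariate (sex, age_group,
    education, intervention_group, polypharmacy_category, charlson_category,
    frailty) or a condition label, which is tabulated present/absent.
    Rows with a missing covariate are dropped (complete-case, baseline only).
    """
    baseline_flags = [f for f in flags if f.visit_month == 0]
    if not baseline_flags:
        raise ValueError("no baseline (visit 0) PIP flags supplied")
    ds = build_analysis_dataset(cohort, baseline_flags)

    if variable in _BASELINE_VARIABLES:
        levels = _BASELINE_VARIABLES[variable]
        sub = ds.dropna(subset=[variable])
        counts = np.array(
            [
                [((sub["pip"] == pip) & (sub[variable] == lv)).sum() for lv in levels]
                for pip in (0, 1)
            ],
            dtype=float,
        )
        col_labels = tuple(levels)
    else:
        known_conditions = {
            c.condition for cms in cohort.comorbidities.values() for c in cms
        }
        from .cohort import CONDITION_VOCABULARY

        if variable not in CONDITION_VOCABULARY and variable not in known_conditions:
            raise KeyError(f"unknown variable {variable!r}; expected {_CONDITION_VARIABLES_HINT}")
        has = {
            pid
            for pid, cms in cohort.comorbidities.items()
            if any(
                c.condition == variable
                and c.onset_date <= cohort.patients[pid].baseline_date
                for c in cms
            )
        }
        counts = np.zeros((2, 2))
        for f in baseline_flags:
            counts[int(f.pip), 0 if f.patient_id in has else 1] += 1
        counts = counts[:, ::-1]  # present first
        col_labels = ("present", "absent")

    table = ContingencyTable(("without_PIP", "with_PIP"), col_labels, counts)
    return table, run_selected_test(table)


def reference_baseline_tables() -> dict[str, ContingencyTable]:
    """Packaged published baseline cross-tabulations (counts only).

    Returns one PIP-status x category table per variable for the reference
    cohort of 1,525 community-dwelling adults aged >=70; used to validate
    the test-selection and p-value machinery against printed results.
    """
    src = importlib.resources.files("pipscreen.data") / "reference_baseline_tables.csv"
    with importlib.resources.as_file(src) as p:
        df = pd.read_csv(p, dtype={"variable": str, "category": str})
    out: dict[str, ContingencyTable] = {}
    for var, grp in df.groupby("variable", sort=False):
        out[var] = ContingencyTable(
            ("without_PIP", "with_PIP"),
            tuple(grp["category"]),
            np.vstack([grp["without_pip"].to_numpy(), grp["with_pip"].to_numpy()]),
        )
    return out
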