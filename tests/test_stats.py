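"""Contingency machinery: categorization, test selection, exact p-values."""

import numpy as np
import pytest

from pipscreen import (
    ContingencyTable,
    baseline_table,
    categorize_age,
    categorize_polypharmacy,
    chi_square_p,
    expected_counts,
    fisher_two_sided_p,
    reference_baseline_tables,
    run_selected_test,
    select_test,
)
from pipscreen.engine import PIPFlag

from oracles import chi2_permutation_p, fisher_enum_p


@pytest.mark.parametrize("age,group", [(70, "<=74"), (74, "<=74"), (75, "75-79"),
                                       (79, "75-79"), (80, ">=80"), (93, ">=80")])
def test_age_thresholds(age, group):
    assert categorize_age(age) == group


def test_age_below_cohort_definition_warns_but_categorizes():
    with pytest.warns(UserWarning):
        assert categorize_age(65) == "<=74"


@pytest.mark.parametrize("n,cat", [(0, "0-4"), (4, "0-4"), (5, "5-9"),
                                   (9, "5-9"), (10, ">=10"), (15, ">=10")])
def test_polypharmacy_categories(n, cat):
    assert categorize_polypharmacy(n) == cat


def test_negative_drug_count_rejected():
    with pytest.raises(ValueError):
        categorize_polypharmacy(-1)


def _t(counts, cols=None):
    counts = np.asarray(counts)
    cols = cols or tuple(f"c{j}" for j in range(counts.shape[1]))
    return ContingencyTable(("without_PIP", "with_PIP"), tuple(cols), counts)


def test_expected_counts_closed_form():
    gender = _t([[187, 100], [791, 447]])
    e = expected_counts(gender)
    assert e[0, 0] == pytest.approx(287 * 978 / 1525, abs=0.01)  # 184.06
    assert e.sum() == pytest.approx(gender.total)


def test_expected_counts_symmetric_table():
    assert np.allclose(expected_counts(_t([[10, 10], [10, 10]])), 10.0)


def test_degenerate_margin_raises():
    with pytest.raises(ValueError, match="degenerate"):
        expected_counts(_t([[0, 0], [5, 7]]))


def test_chi_square_reproduces_reference_gender_p():
    res = chi_square_p(_t([[187, 100], [791, 447]]))
    assert res.method == "pearson_chi_square"
    assert res.df == 1
    assert round(res.p_value, 3) == 0.688  # only without continuity correction


def test_chi_square_proportional_table_is_null():
    res = chi_square_p(_t([[20, 10], [40, 20]]))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_invariance_under_permutation():
    base = _t([[30, 12, 8], [22, 35, 14]])
    permuted = _t(np.asarray(base.counts)[:, [2, 0, 1]][::-1])
    assert chi_square_p(base).p_value == pytest.approx(chi_square_p(permuted).p_value)


def test_chi_square_agrees_with_permutation_null():
    # large balanced tables: the asymptotic p matches the exact
    # conditional (fixed-margin) null within Monte-Carlo error
    rng = np.random.default_rng(5)
    for k in range(3):
        n, n1 = 100_000, 45_000
        pc = rng.dirichlet([10, 10, 10])
        delta = rng.uniform(-0.01, 0.01, 3)
        delta -= delta.mean()
        top = np.floor((pc + delta) * n1).astype(int)
        bot = np.floor((pc - delta) * (n - n1)).astype(int)
        table = _t(np.vstack([top, bot]))
        p_asym = chi_square_p(table).p_value
        p_mc, se = chi2_permutation_p(table.counts, n_mc=100_000, seed=50 + k)
        assert abs(p_asym - p_mc) <= 3 * max(se, 1e-6)


def test_fisher_reproduces_reference_diabetes_and_cancer_p():
    assert round(fisher_two_sided_p(_t([[0, 287], [13, 1225]])).p_value, 3) == 0.145
    assert round(fisher_two_sided_p(_t([[0, 287], [9, 1229]])).p_value, 3) == 0.223


def test_fisher_tiny_table_full_enumeration():
    assert fisher_two_sided_p(_t([[1, 0], [0, 1]])).p_value == pytest.approx(1.0)


def test_fisher_rejects_non_2x2():
    with pytest.raises(ValueError, match="2x2"):
        fisher_two_sided_p(_t([[1, 2, 3], [4, 5, 6]]))


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(60):
        counts = rng.integers(0, 40, size=(2, 2))
        if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
            continue
        p = fisher_two_sided_p(_t(counts)).p_value
        assert p == pytest.approx(fisher_enum_p(counts), abs=1e-9)


def test_select_test_matches_expected_count_rule():
    diabetes = _t([[0, 287], [13, 1225]])   # min E ~ 2.45
    gender = _t([[187, 100], [791, 447]])   # min E ~ 102.9
    assert select_test(diabetes) == "fisher_exact"
    assert select_test(gender) == "pearson_chi_square"
    assert run_selected_test(diabetes).method == "fisher_exact"


def test_select_test_small_expected_non_2x2_falls_back_with_warning():
    tiny = _t([[1, 2, 30], [2, 1, 40]])
    with pytest.warns(UserWarning, match="falling back"):
        assert select_test(tiny) == "pearson_chi_square"


def test_reference_tables_reproduce_printed_method_assignment():
    tables = reference_baseline_tables()
    fisher_vars = {"diabetes", "severe_chronic_kidney_disease", "cancer"}
    for var, table in tables.items():
        expected = "fisher_exact" if var in fisher_vars else "pearson_chi_square"
        assert select_test(table) == expected, var


def test_reference_gender_counts_layout():
    gender = reference_baseline_tables()["gender"]
    assert gender.col_labels == ("female", "male")
    assert gender.counts.tolist() == [[187, 100], [791, 447]]
    pct = gender.column_percents()
    assert pct[0, 0] == pytest.approx(100 * 187 / 978, abs=0.01)


# ---------------------------------------------------------------------------
# Baseline table from cohort + flags
# ---------------------------------------------------------------------------

def _flagged_cohort():
    from conftest import make_cohort, make_condition, make_patient

    patients = [make_patient(pid=f"P{i}", sex="female" if i % 2 else "male",
                             visits=(0,)) for i in range(1, 9)]
    cohort = make_cohort(patients,
                         comorbidities=[make_condition("P1", "diabetes")])
    flags = [PIPFlag(p.patient_id, 0, int(i % 3 == 0), int(i % 3 == 0))
             for i, p in enumerate(patients)]
    return cohort, flags


def test_baseline_table_sex_counts_and_test():
    cohort, flags = _flagged_cohort()
    table, res = baseline_table(cohort, flags, "sex")
    assert table.counts.sum() == 8
    assert 0 <= res.p_value <= 1


def test_baseline_table_condition_variable_is_2x2():
    cohort, flags = _flagged_cohort()
    table, res = baseline_table(cohort, flags, "diabetes")
    assert table.col_labels == ("present", "absent")
    assert table.counts.sum() == 8


def test_baseline_table_degenerate_when_all_pip():
    cohort, flags = _flagged_cohort()
    all_pip = [PIPFlag(f.patient_id, 0, 1, 1) for f in flags]
    with pytest.raises(ValueError):
        baseline_table(cohort, all_pip, "sex")


def test_baseline_table_unknown_variable():
    cohort, flags = _flagged_cohort()
    with pytest.raises(KeyError):
        baseline_table(cohort, flags, "shoe_size")


def test_baseline_p_uniform_when_pip_independent_of_sex():
    # type-I calibration: independent binomial draws in a 2x2 layout
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(300):
        sex = rng.random(400) < 0.64
        pip = rng.random(400) < 0.4
        counts = np.array(
            [[(~pip & sex).sum(), (~pip & ~sex).sum()],
             [(pip & sex).sum(), (pip & ~sex).sum()]]
        )
        pvals.append(run_selected_test(_t(counts)).p_value)
    from scipy.stats import kstest

    assert kstest(pvals, "uniform").pvalue > 0.01
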