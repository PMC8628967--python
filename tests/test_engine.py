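"""Rule engine: MRNC emission multiplicity, deduplication, PIP flags."""

import pytest

from pipscreen import (
    deduplicate_strict,
    evaluate_cohort,
    evaluate_rule,
    flag_pip,
    mrnc_distribution,
    tool_prevalence,
)
from pipscreen.cohort import state_at_visit
from pipscreen.rules import RuleBank, _rule_from_obj

from conftest import make_cohort, make_condition, make_patient, make_rx, make_snapshot
from oracles import brute_force_mrncs


def _rule(rid="R1", tool="EU7_PIM", kind="list_match", dedup="k1",
          trigger=None):
    return _rule_from_obj(
        {
            "id": rid, "tool": tool, "kind": kind, "dedup_key": dedup,
            "trigger": trigger or {"drug_active": {"atc": ["N05BA"]}},
        }
    )


def _single_state(prescriptions=(), conditions=(), snapshot=None):
    cohort = make_cohort([make_patient(sex="male")], prescriptions=list(prescriptions),
                         comorbidities=list(conditions),
                         snapshots=[snapshot] if snapshot else [])
    return cohort, state_at_visit(cohort, "P1", 0)


def test_list_rule_emits_one_mrnc_per_matching_prescription():
    _, state = _single_state([make_rx(atc="N05BA01"), make_rx(atc="N05BA06"),
                              make_rx(atc="A06AD11")])
    out = evaluate_rule(_rule(), state)
    assert {m.detail for m in out} == {"N05BA01", "N05BA06"}
    assert all(m.trigger_atc_codes for m in out)


def test_no_prescriptions_no_mrncs(bank):
    _, state = _single_state([])
    for rule in bank.rules:
        if rule.rule_kind != "omission":
            assert evaluate_rule(rule, state) == []


def test_omission_emits_single_mrnc_with_empty_trigger_set(bank):
    _, state = _single_state(conditions=[make_condition("P1", "prostatism")])
    out = evaluate_rule(bank.get("START_G1G2"), state)
    assert len(out) == 1
    assert out[0].trigger_atc_codes == frozenset()


def test_interaction_emits_one_mrnc_per_coactive_pair(bank):
    _, state = _single_state([make_rx(atc="C01DA14"), make_rx(atc="C01DA08"),
                              make_rx(atc="G04BE03")])
    out = evaluate_rule(bank.get("CI_NITRATE_PDE5"), state)
    assert {m.trigger_atc_codes for m in out} == {
        frozenset({"C01DA14", "G04BE03"}), frozenset({"C01DA08", "G04BE03"}),
    }


def test_missing_clinical_value_causes_abstention_not_firing(bank):
    cohort, _ = _single_state(
        [make_rx(atc="C07AB07")],
        snapshot=make_snapshot("P1", sbp_supine=None, sbp_standing=None),
    )
    report = evaluate_cohort(cohort, bank)
    assert not any(m.rule_id == "AMI_ORTHOSTATIC" for m in report.mrncs)
    assert any(
        a["rule_id"] == "AMI_ORTHOSTATIC" and "insufficient data" in a["reason"]
        for a in report.abstentions
    )


def test_evaluate_cohort_single_trigger(bank):
    cohort, _ = _single_state([make_rx(pid="P1", atc="C01BD01", dose=200.0)])
    cohort.patients["P1"] = make_patient(sex="male", visits=(0,))
    report = evaluate_cohort(cohort, bank)
    assert [m.rule_id for m in report.mrncs] == ["EU7_C01BD01"]


def test_evaluate_cohort_deterministic_and_ordered(bank):
    cohort, _ = _single_state(
        [make_rx(atc="N05BA01"), make_rx(atc="C03CA01", dose=40.0)],
        conditions=[make_condition("P1", "hypertension")],
    )
    r1 = evaluate_cohort(cohort, bank)
    r2 = evaluate_cohort(cohort, bank)
    assert r1.mrncs == r2.mrncs
    assert r1.mrncs == sorted(r1.mrncs, key=lambda m: m.sort_key())


def test_removing_a_rule_never_increases_mrncs(bank):
    cohort, _ = _single_state([make_rx(atc="N05BA01"), make_rx(atc="M01AB05")])
    full = evaluate_cohort(cohort, bank).mrncs
    smaller_bank = RuleBank(rules=[r for r in bank.rules if r.rule_id != "EU7_N05BA01"],
                            version=bank.version)
    reduced = evaluate_cohort(cohort, smaller_bank).mrncs
    assert len(reduced) <= len(full)
    assert {m.rule_id for m in reduced} <= {m.rule_id for m in full}


def test_engine_matches_brute_force_on_handmade_cohort(bank):
    cohort = make_cohort(
        [make_patient(pid="P1", sex="male", visits=(0, 6)),
         make_patient(pid="P2", visits=(0, 6))],
        prescriptions=[
            make_rx(pid="P1", atc="N05BA01", dose=5.0),
            make_rx(pid="P1", atc="C03CA01", dose=40.0),
            make_rx(pid="P2", atc="C01DA14", dose=40.0),
            make_rx(pid="P2", atc="G04BE03", dose=50.0),
        ],
        comorbidities=[make_condition("P1", "hypertension"),
                       make_condition("P2", "prostatism")],
        snapshots=[make_snapshot("P1"), make_snapshot("P2")],
    )
    got = {
        (m.patient_id, m.visit_month, m.rule_id, m.trigger_atc_codes)
        for m in evaluate_cohort(cohort, bank).mrncs
    }
    assert got == brute_force_mrncs(cohort, bank)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _mrnc_pair_same_key():
    eu7 = _rule("EU7_X", tool="EU7_PIM", dedup="benzo")
    stopp = _rule("STOPP_X", tool="STOPP", kind="conditional", dedup="benzo")
    _, state = _single_state([make_rx(atc="N05BA01")])
    return evaluate_rule(eu7, state) + evaluate_rule(stopp, state)


def test_dedup_retains_highest_priority_tool():
    both = _mrnc_pair_same_key()
    kept = deduplicate_strict(both)
    assert len(kept) == 1 and kept[0].source_tool == "STOPP"


def test_dedup_is_idempotent_and_never_increases():
    both = _mrnc_pair_same_key()
    once = deduplicate_strict(both)
    assert deduplicate_strict(once) == once
    assert len(once) <= len(both)
    assert deduplicate_strict([]) == []


def test_dedup_key_includes_visit_and_trigger_drugs():
    rule = _rule()
    cohort = make_cohort([make_patient(visits=(0, 6))],
                         prescriptions=[make_rx(atc="N05BA01", end=None)])
    mrncs = evaluate_cohort(cohort, RuleBank(rules=[rule])).mrncs
    assert len(mrncs) == 2  # one per visit
    assert len(deduplicate_strict(mrncs)) == 2


# ---------------------------------------------------------------------------
# PIP flags and summaries
# ---------------------------------------------------------------------------

def test_flag_pip_covers_full_schedule(bank):
    patients = [make_patient(pid=f"P{i}") for i in range(1, 11)]
    cohort = make_cohort(patients)
    flags = flag_pip([], cohort)
    assert len(flags) == 70
    assert all(not f.pip and f.n_mrnc_dedup == 0 for f in flags)


def test_flag_pip_counts(bank):
    cohort, state = _single_state([make_rx(atc="N05BA01")])
    report = evaluate_cohort(cohort, bank)
    deduped = deduplicate_strict(report.mrncs)
    flags = flag_pip(deduped, cohort, mrncs_raw=report.mrncs)
    at0 = next(f for f in flags if f.visit_month == 0)
    assert at0.pip and at0.n_mrnc_dedup == 1 and at0.n_mrnc_raw == 2
    assert all(f.n_mrnc_dedup <= f.n_mrnc_raw for f in flags)


def test_tool_prevalence_extremes(bank):
    patients = [make_patient(pid=f"P{i}", visits=(0,)) for i in range(1, 5)]
    rx = [make_rx(pid=p.patient_id, atc="N05BA01") for p in patients]
    cohort = make_cohort(patients, prescriptions=rx)
    report = evaluate_cohort(cohort, bank)
    prev = tool_prevalence(report.mrncs, cohort, at_visit=0).set_index("source_tool")
    assert prev.loc["EU7_PIM", "percent"] == 100.0
    assert prev.loc["WITHDRAWAL", "n_patients"] == 0
    assert prev.loc["WITHDRAWAL", "percent"] == 0.0


def test_mrnc_histogram_sums_to_100_and_matches_counting(bank):
    patients = [make_patient(pid=f"P{i:02d}", visits=(0,)) for i in range(1, 21)]
    rx = []
    for i, p in enumerate(patients):
        if i < 5:
            rx.append(make_rx(pid=p.patient_id, atc="M01AB05"))
        if i < 2:
            rx.append(make_rx(pid=p.patient_id, atc="A08AA10"))
    cohort = make_cohort(patients, prescriptions=rx)
    deduped = deduplicate_strict(evaluate_cohort(cohort, bank).mrncs)
    hist = mrnc_distribution(deduped, cohort, at_visit=0)
    assert hist["percent"].sum() == pytest.approx(100.0)
    assert hist.set_index("n_mrnc")["n_patients"].to_dict() == {
        "0": 15, "1": 3, "2": 2, "3": 0, "4": 0, "5": 0, ">=6": 0,
    }


def test_all_zero_histogram(bank):
    cohort = make_cohort([make_patient(visits=(0,))])
    hist = mrnc_distribution([], cohort, at_visit=0)
    assert hist.set_index("n_mrnc").loc["0", "percent"] == 100.0
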