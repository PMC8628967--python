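"""Rulebank schema, the packaged demonstration bank, and predicate semantics."""

import pytest
import yaml

from pipscreen import builtin_rulebank, load_rulebank, save_rulebank, validate_rulebank
from pipscreen.cohort import PatientState
from pipscreen.rules import RuleBank, RuleSchemaError, parse_predicate, _rule_from_obj
from pipscreen.cohort import state_at_visit

from conftest import make_cohort, make_condition, make_patient, make_rx, make_snapshot


def _state(prescriptions=(), conditions=(), snapshot=None, sex="male"):
    p = make_patient(sex=sex)
    cohort = make_cohort(
        [p],
        prescriptions=list(prescriptions),
        comorbidities=list(conditions),
        snapshots=[snapshot] if snapshot else [],
    )
    return state_at_visit(cohort, "P1", 0)


# ---------------------------------------------------------------------------
# Packaged demonstration bank
# ---------------------------------------------------------------------------

def test_builtin_bank_metadata_counts_match_contents(bank):
    counts = bank.counts_by_tool
    assert counts == {
        t: sum(r.source_tool == t for r in bank.rules) for t in counts
    }
    assert bank.metadata["n_rules"] == len(bank.rules)
    assert counts["EU7_PIM"] >= 30
    assert counts["CONTRAINDICATION"] >= 10


def test_builtin_bank_omits_overbroad_and_deprecated_criteria(bank):
    excluded = {"STOPP_K1", "STOPP_K2", "STOPP_K4", "START_C3"}
    assert not excluded & set(bank.rule_ids())
    assert not excluded & {r.dedup_key for r in bank.rules}


def test_every_builtin_rule_has_citation_and_dedup_key(bank):
    for r in bank.rules:
        assert r.citation and r.dedup_key


def test_builtin_bank_validates_clean(bank):
    diags = validate_rulebank(bank)
    assert [d for d in diags if d.severity in ("error", "warning")] == []
    # strict redundancies across tools are declared as info diagnostics
    assert any("benzodiazepine_long_halflife" in d.message for d in diags)


def test_stopp_b6_fires_on_lone_loop_diuretic_with_hypertension(bank):
    rule = bank.get("STOPP_B6")
    state = _state(
        prescriptions=[make_rx(atc="C03CA01", dose=40.0)],
        conditions=[make_condition("P1", "hypertension")],
    )
    assert rule.trigger.evaluate(state).value


def test_stopp_b6_blocked_by_concomitant_antihypertensive(bank):
    rule = bank.get("STOPP_B6")
    state = _state(
        prescriptions=[make_rx(atc="C03CA01", dose=40.0),
                       make_rx(atc="C09AA02", dose=5.0)],
        conditions=[make_condition("P1", "hypertension")],
    )
    assert not rule.trigger.evaluate(state).value


def test_stopp_b6_blocked_by_heart_failure(bank):
    rule = bank.get("STOPP_B6")
    state = _state(
        prescriptions=[make_rx(atc="C03CA01", dose=40.0)],
        conditions=[make_condition("P1", "hypertension"),
                    make_condition("P1", "heart_failure")],
    )
    assert not rule.trigger.evaluate(state).value


def test_stopp_a1a_aspirin_dose_threshold(bank):
    rule = bank.get("STOPP_A1A")
    low = _state(prescriptions=[make_rx(atc="B01AC06", dose=75.0)])
    high = _state(prescriptions=[make_rx(atc="B01AC06", dose=500.0)])
    assert rule.trigger.evaluate(low).value      # antiplatelet use, no CV history
    assert not rule.trigger.evaluate(high).value  # analgesic dose, not A1a


def test_stopp_a1a_blocked_by_cardiovascular_history(bank):
    rule = bank.get("STOPP_A1A")
    state = _state(
        prescriptions=[make_rx(atc="C10AA01", dose=20.0)],
        conditions=[make_condition("P1", "myocardial_infarction")],
    )
    assert not rule.trigger.evaluate(state).value


def test_stopp_a1b_recency_window(bank):
    rule = bank.get("STOPP_A1B")
    ppi = make_rx(atc="A02BC01", dose=20.0)
    recent = _state(prescriptions=[ppi],
                    conditions=[make_condition("P1", "oesogastric_damage", 3)])
    old = _state(prescriptions=[ppi],
                 conditions=[make_condition("P1", "oesogastric_damage", 30)])
    assert not rule.trigger.evaluate(recent).value  # recent damage: indicated
    assert rule.trigger.evaluate(old).value         # damage too old to justify


def test_start_g1g2_omission_logic(bank):
    rule = bank.get("START_G1G2")
    untreated = _state(conditions=[make_condition("P1", "prostatism")])
    treated = _state(prescriptions=[make_rx(atc="G04CA02", dose=0.4)],
                     conditions=[make_condition("P1", "prostatism")])
    post_surgery = _state(conditions=[make_condition("P1", "prostatism"),
                                      make_condition("P1", "prostatectomy")])
    assert rule.trigger.evaluate(untreated).value
    assert not rule.trigger.evaluate(treated).value
    assert not rule.trigger.evaluate(post_surgery).value


def test_predicate_evaluation_is_pure(bank):
    state = _state(prescriptions=[make_rx(atc="C03CA01", dose=40.0)],
                   conditions=[make_condition("P1", "hypertension")])
    rule = bank.get("STOPP_B6")
    assert rule.trigger.evaluate(state) == rule.trigger.evaluate(state)


# ---------------------------------------------------------------------------
# Schema and serialization
# ---------------------------------------------------------------------------

def test_serialization_round_trip(bank, tmp_path):
    path = tmp_path / "bank.yaml"
    save_rulebank(bank, path)
    again = load_rulebank(path)
    assert again.version == bank.version
    assert [r for r in again.rules] == [r for r in bank.rules]


def test_duplicate_rule_id_rejected(bank):
    rule = bank.rules[0]
    with pytest.raises(RuleSchemaError, match="duplicate rule_id"):
        RuleBank(rules=[rule, rule])


def test_unknown_atom_named_in_error():
    with pytest.raises(RuleSchemaError, match="drug_activ"):
        parse_predicate({"drug_activ": {"atc": ["N05BA01"]}})


def test_malformed_atc_set_rejected():
    with pytest.raises(RuleSchemaError, match="malformed ATC"):
        parse_predicate({"drug_active": {"atc": ["X99ZZ99"]}})
    with pytest.raises(RuleSchemaError, match="non-empty"):
        parse_predicate({"drug_active": {"atc": []}})


def test_omission_rules_restricted_to_start_and_ami():
    obj = {
        "id": "BAD", "tool": "EU7_PIM", "kind": "omission", "dedup_key": "x",
        "trigger": {"condition_present": {"conditions": ["prostatism"]}},
    }
    with pytest.raises(RuleSchemaError, match="START or AMI"):
        _rule_from_obj(obj)


def test_interaction_rules_need_disjoint_drug_sets():
    obj = {
        "id": "BAD", "tool": "CONTRAINDICATION", "kind": "interaction",
        "dedup_key": "x",
        "trigger": {"all": [{"drug_active": {"atc": ["C08DA01"]}},
                            {"drug_active": {"atc": ["C08DA01"]}}]},
    }
    with pytest.raises(RuleSchemaError, match="disjoint"):
        _rule_from_obj(obj)


def test_validate_flags_unknown_vocabulary_label(bank):
    rule = _rule_from_obj(
        {
            "id": "X1", "tool": "STOPP", "kind": "conditional", "dedup_key": "x",
            "trigger": {"condition_present": {"conditions": ["asthme"]}},
        }
    )
    diags = validate_rulebank(RuleBank(rules=[rule]))
    assert any(d.severity == "error" and "asthme" in d.message for d in diags)
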