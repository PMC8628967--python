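"""Evaluate a rulebank against a cohort: MRNCs, deduplication, PIP flags.

The engine walks every (patient, visit) state, evaluates every rule, and
emits medication-related potential noncompliances (MRNC).  Emission
multiplicity follows the rule kind:

- ``list_match`` / ``conditional``: one MRNC per active prescription
  matching the rule's drug atoms, when the full trigger holds;
- ``omission``: at most one MRNC per patient-visit, with an empty trigger
  drug set (the noncompliance is a missing treatment, not a drug line);
- ``interaction``: one MRNC per unordered co-active pair drawn from the
  first two drug atoms.

A rule that needs a missing clinical value abstains — it never fires — and
the abstention is logged with its reason, so missing data can only lower
sensitivity, never create false positives.

Strict duplicates (the same semantic criterion, same patient-visit, same
trigger drugs, detected by more than one tool) are collapsed to a single
MRNC, retaining the tool highest in STOPP > START > EU(7)-PIM > AMI >
WITHDRAWAL > CONTRAINDICATION order.  Per-tool prevalence summaries are
computed from the raw (pre-deduplication) stream; PIP flags and MRNC-count
histograms from the deduplicated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .cohort import Cohort, PatientState, state_at_visit
from .rules import Abstain, DrugActive, Rule, RuleBank, TOOL_PRIORITY

__all__ = [
    "MRNC",
    "PIPFlag",
    "EvaluationReport",
    "evaluate_rule",
    "evaluate_cohort",
    "deduplicate_strict",
    "flag_pip",
    "tool_prevalence",
    "mrnc_distribution",
]


@dataclass(frozen=True)
class MRNC:
    """One detected medication-related potential noncompliance."""

    patient_id: str
    visit_month: int
    rule_id: str
    source_tool: str
    dedup_key: str
    trigger_atc_codes: frozenset[str]
    detail: str = ""

    def sort_key(self):
        return (self.patient_id, self.visit_month, self.rule_id,
                tuple(sorted(self.trigger_atc_codes)))


@dataclass(frozen=True)
class PIPFlag:
    """Binary potentially-inappropriate-prescribing status for one visit."""

    patient_id: str
    visit_month: int
    n_mrnc_raw: int
    n_mrnc_dedup: int

    @property
    def pip(self) -> bool:
        return self.n_mrnc_dedup >= 1


@dataclass
class EvaluationReport:
    """Raw MRNC stream plus the abstention log of one engine run."""

    mrncs: list[MRNC]
    abstentions: list[dict] = field(default_factory=list)


def evaluate_rule(rule: Rule, state: PatientState) -> list[MRNC]:
    """Evaluate one rule against one patient state (pure, deterministic).

    Returns the emitted MRNCs; an abstaining rule raises :class:`Abstain`
    (callers log it).
    """
    res = rule.trigger.evaluate(state)
    if not res.value:
        return []
    base = dict(
        patient_id=state.patient.patient_id,
        visit_month=state.visit_month,
        rule_id=rule.rule_id,
        source_tool=rule.source_tool,
        dedup_key=rule.dedup_key,
    )
    if rule.rule_kind == "omission":
        return [MRNC(**base, trigger_atc_codes=frozenset(), detail=rule.description)]
    if rule.rule_kind == "interaction":
        atoms = rule.drug_atoms()
        a = atoms[0].evaluate(state).support
        b = atoms[1].evaluate(state).support
        out = []
        seen = set()
        for rx_a in a:
            for rx_b in b:
                pair = frozenset((rx_a.atc_code, rx_b.atc_code))
                if pair in seen:
                    continue
                seen.add(pair)
                out.append(
                    MRNC(**base, trigger_atc_codes=pair,
                         detail=f"{rx_a.atc_code} with {rx_b.atc_code}")
                )
        return out
    # list_match / conditional: one MRNC per supporting prescription
    out = []
    seen_codes = set()
    for rx in res.support:
        if rx.atc_code in seen_codes:
            continue
        seen_codes.add(rx.atc_code)
        out.append(
            MRNC(**base, trigger_atc_codes=frozenset((rx.atc_code,)), detail=rx.atc_code)
        )
    return out


def evaluate_cohort(cohort: Cohort, bank: RuleBank) -> EvaluationReport:
    """Evaluate every rule at every (patient, visit) of the cohort.

    Output order is stable by (patient_id, visit_month, rule_id, drugs);
    two runs on identical inputs are byte-identical.
    """
    mrncs: list[MRNC] = []
    abstentions: list[dict] = []
    for pid, month in cohort.patient_visits():
        state = state_at_visit(cohort, pid, month)
        for rule in bank.rules:
            try:
                mrncs.extend(evaluate_rule(rule, state))
            except Abstain as ab:
                abstentions.append(
                    {
                        "patient_id": pid,
                        "visit_month": month,
                        "rule_id": rule.rule_id,
                        "reason": f"insufficient data: {ab.reason}",
                    }
                )
    mrncs.sort(key=MRNC.sort_key)
    return EvaluationReport(mrncs=mrncs, abstentions=abstentions)


def deduplicate_strict(mrncs: Iterable[MRNC]) -> list[MRNC]:
    """Collapse strict duplicates between tools.

    At most one MRNC is retained per (patient, visit, dedup_key, trigger
    drugs); retention prefers the source tool highest in
    :data:`TOOL_PRIORITY`, then the lexicographically smallest rule_id.
    Idempotent; never increases counts.
    """
    rank = {t: i for i, t in enumerate(TOOL_PRIORITY)}
    best: dict[tuple, MRNC] = {}
    for m in mrncs:
        key = (m.patient_id, m.visit_month, m.dedup_key, m.trigger_atc_codes)
        cur = best.get(key)
        if cur is None or (rank[m.source_tool], m.rule_id) < (rank[cur.source_tool], cur.rule_id):
            best[key] = m
    out = list(best.values())
    out.sort(key=MRNC.sort_key)
    return out


def flag_pip(mrncs_dedup: Iterable[MRNC], cohort: Cohort,
             mrncs_raw: Optional[Iterable[MRNC]] = None) -> list[PIPFlag]:
    """One PIPFlag per scheduled (patient, visit), zero-MRNC visits included."""
    dedup_counts: dict[tuple[str, int], int] = {}
    for m in mrncs_dedup:
        k = (m.patient_id, m.visit_month)
        dedup_counts[k] = dedup_counts.get(k, 0) + 1
    raw_counts: dict[tuple[str, int], int] = {}
    if mrncs_raw is not None:
        for m in mrncs_raw:
            k = (m.patient_id, m.visit_month)
            raw_counts[k] = raw_counts.get(k, 0) + 1
    else:
        raw_counts = dedup_counts
    return [
        PIPFlag(
            patient_id=pid,
            visit_month=month,
            n_mrnc_raw=raw_counts.get((pid, month), 0),
            n_mrnc_dedup=dedup_counts.get((pid, month), 0),
        )
        for pid, month in cohort.patient_visits()
    ]


def tool_prevalence(mrncs_raw: Iterable[MRNC], cohort: Cohort, at_visit: int) -> pd.DataFrame:
    """Per-tool patient prevalence at one visit, BEFORE deduplication.

    For each source tool: the number and percentage of patients with at
    least one raw MRNC from that tool at the given visit.
    """
    patients_by_tool: dict[str, set[str]] = {t: set() for t in TOOL_PRIORITY}
    for m in mrncs_raw:
        if m.visit_month == at_visit:
            patients_by_tool[m.source_tool].add(m.patient_id)
    n = cohort.n_patients
    rows = [
        {
            "source_tool": tool,
            "n_patients": len(pids),
            "percent": 100.0 * len(pids) / n if n else 0.0,
        }
        for tool, pids in patients_by_tool.items()
    ]
    return pd.DataFrame(rows, columns=["source_tool", "n_patients", "percent"])


def mrnc_distribution(mrncs: Iterable[MRNC], cohort: Cohort, at_visit: int,
                      max_bin: int = 6) -> pd.DataFrame:
    """Histogram of percent of patients by MRNC count at one visit.

    Bins are 0, 1, ..., max_bin-1 and ``>=max_bin``; percentages sum to 100.
    """
    counts: dict[str, int] = {pid: 0 for pid in cohort.patients}
    for m in mrncs:
        if m.visit_month == at_visit:
            counts[m.patient_id] += 1
    n = cohort.n_patients
    bins = {str(k): 0 for k in range(max_bin)}
    bins[f">={max_bin}"] = 0
    for c in counts.values():
        key = str(c) if c < max_bin else f">={max_bin}"
        bins[key] += 1
    return pd.DataFrame(
        [
            {"n_mrnc": k, "n_patients": v, "percent": 100.0 * v / n if n else 0.0}
            for k, v in bins.items()
        ],
        columns=["n_mrnc", "n_patients", "percent"],
    )


def mrnc_table(mrncs: Iterable[MRNC]) -> pd.DataFrame:
    """MRNC stream as a flat DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "visit_month": m.visit_month,
                "rule_id": m.rule_id,
                "source_tool": m.source_tool,
                "dedup_key": m.dedup_key,
                "trigger_atc_codes": ";".join(sorted(m.trigger_atc_codes)),
                "detail": m.detail,
            }
            for m in mrncs
        ],
        columns=[
            "patient_id", "visit_month", "rule_id", "source_tool",
            "dedup_key", "trigger_atc_codes", "detail",
        ],
    )


def pip_table(flags: Iterable[PIPFlag]) -> pd.DataFrame:
    """PIP flags as a flat DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "visit_month": f.visit_month,
                "n_mrnc_raw": f.n_mrnc_raw,
                "n_mrnc_dedup": f.n_mrnc_dedup,
                "pip": int(f.pip),
            }
            for f in flags
        ],
        columns=["patient_id", "visit_month", "n_mrnc_raw", "n_mrnc_dedup", "pip"],
    )
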