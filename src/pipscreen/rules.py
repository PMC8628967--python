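"""Declarative explicit-criteria rules and the demonstration rulebank.

Each rule encodes one explicit prescribing criterion from one of five
families of tools: the EU(7)-PIM list (context-free drug lists), STOPP v2
(misuse conditional on clinical context), START v2 (prescribing omissions),
the French AMI iatrogenicity indicators, market withdrawals, and SmPC
contraindications (drug-drug pairs).  A rule's trigger is a boolean
expression tree over typed atoms evaluated against a ``PatientState``:

=====================  =====================================================
atom                   true when ...
=====================  =====================================================
drug_active            >=1 active prescription falls under the ATC set
                       (optional dose / duration constraints)
drug_absent            no active prescription falls under the ATC set
co_prescribed_count    count of active prescriptions in the ATC set
                       (minus an exclusion set) satisfies the comparator
condition_present      a coded comorbidity is present (optional recency
                       window in months since onset)
condition_absent       no such comorbidity (optional recency window:
                       "no onset within the last N months")
measure                a clinical snapshot value satisfies the comparator;
                       ABSTAINS when the value is missing
dose / duration        standalone filters narrowing the prescriptions
                       matched by drug atoms earlier in the same ``all``
procedure_done         a recorded procedure label is present
=====================  =====================================================

Combinators are ``all`` / ``any`` / ``not``.  Evaluation is pure; a rule
reading a missing clinical value abstains (never fires) rather than erring.

Rule files are YAML; the packaged demonstration rulebank covers every atom
and the restricted codings of STOPP A1 (two sub-criteria), STOPP B6 and the
START G1/G2 prostatism omission, and deliberately omits STOPP K1/K2/K4 and
START C3.  Full source lists (282 EU(7)-PIM entries, 47 STOPP, 24 START,
thousands of SmPC pairs) are loaded from external rule files in the same
schema; the packaged bank is a curated demonstration, not the licensed text.
"""

from __future__ import annotations

import importlib.resources
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import pandas as pd
import yaml

from .atc import atc_matches, is_valid_atc
from .cohort import CONDITION_VOCABULARY, PatientState, Prescription

__all__ = [
    "Abstain",
    "RuleSchemaError",
    "Predicate",
    "Rule",
    "RuleBank",
    "Diagnostic",
    "load_rulebank",
    "save_rulebank",
    "builtin_rulebank",
    "validate_rulebank",
    "TOOLS",
    "TOOL_PRIORITY",
]

TOOLS = ("EU7_PIM", "STOPP", "START", "AMI", "WITHDRAWAL", "CONTRAINDICATION")
#: Retention priority when collapsing strict duplicates (highest first).
TOOL_PRIORITY = ("STOPP", "START", "EU7_PIM", "AMI", "WITHDRAWAL", "CONTRAINDICATION")
RULE_KINDS = ("list_match", "conditional", "omission", "interaction")

_CMP: dict[str, Callable[[float, float], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
}


class Abstain(Exception):
    """Internal signal: a predicate read a missing clinical value."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class RuleSchemaError(ValueError):
    """Rule file violates the documented schema."""


def _cmp(name: str) -> Callable[[float, float], bool]:
    if name not in _CMP:
        raise RuleSchemaError(f"unknown comparator {name!r}")
    return _CMP[name]


@dataclass(frozen=True)
class EvalResult:
    value: bool
    #: prescriptions supporting a true drug atom (drives per-drug MRNCs)
    support: tuple[Prescription, ...] = ()


class Predicate:
    """Base class; subclasses implement ``evaluate(state) -> EvalResult``."""

    def evaluate(self, state: PatientState) -> EvalResult:  # pragma: no cover
        raise NotImplementedError

    def to_obj(self) -> dict:  # pragma: no cover
        raise NotImplementedError

    def walk(self):
        yield self


def _check_atc_set(codes: Sequence[str], where: str) -> tuple[str, ...]:
    if not codes:
        raise RuleSchemaError(f"{where}: atc set must be non-empty")
    for c in codes:
        if not is_valid_atc(c):
            raise RuleSchemaError(f"{where}: malformed ATC code {c!r}")
    return tuple(codes)


@dataclass(frozen=True)
class DoseSpec:
    cmp: str
    value: float
    unit: str = "mg"

    def satisfied_by(self, rx: Prescription) -> bool:
        if rx.dose_value is None:
            return False  # unknown dose never satisfies a dose constraint
        if self.unit and rx.dose_unit.lower() != self.unit.lower():
            return False
        return _cmp(self.cmp)(rx.dose_value, self.value)


@dataclass(frozen=True)
class DurationSpec:
    cmp: str
    months: float

    def satisfied_by(self, rx: Prescription, state: PatientState) -> bool:
        return _cmp(self.cmp)(rx.duration_months_at(state.visit_date), self.months)


@dataclass(frozen=True)
class DrugActive(Predicate):
    atc: tuple[str, ...]
    dose: Optional[DoseSpec] = None
    duration: Optional[DurationSpec] = None

    def evaluate(self, state: PatientState) -> EvalResult:
        hits = [rx for rx in state.active if atc_matches(rx.atc_code, self.atc)]
        if self.dose is not None:
            hits = [rx for rx in hits if self.dose.satisfied_by(rx)]
        if self.duration is not None:
            hits = [rx for rx in hits if self.duration.satisfied_by(rx, state)]
        return EvalResult(bool(hits), tuple(hits))

    def to_obj(self) -> dict:
        spec: dict = {"atc": list(self.atc)}
        if self.dose:
            spec["dose"] = {"cmp": self.dose.cmp, "value": self.dose.value, "unit": self.dose.unit}
        if self.duration:
            spec["duration"] = {"cmp": self.duration.cmp, "months": self.duration.months}
        return {"drug_active": spec}


@dataclass(frozen=True)
class DrugAbsent(Predicate):
    atc: tuple[str, ...]

    def evaluate(self, state: PatientState) -> EvalResult:
        return EvalResult(not any(atc_matches(rx.atc_code, self.atc) for rx in state.active))

    def to_obj(self) -> dict:
        return {"drug_absent": {"atc": list(self.atc)}}


@dataclass(frozen=True)
class CoPrescribedCount(Predicate):
    atc: tuple[str, ...]
    cmp: str
    count: int
    exclude_atc: tuple[str, ...] = ()

    def evaluate(self, state: PatientState) -> EvalResult:
        hits = [
            rx
            for rx in state.active
            if atc_matches(rx.atc_code, self.atc)
            and not (self.exclude_atc and atc_matches(rx.atc_code, self.exclude_atc))
        ]
        return EvalResult(_cmp(self.cmp)(len(hits), self.count))

    def to_obj(self) -> dict:
        spec: dict = {"atc": list(self.atc), "cmp": self.cmp, "count": self.count}
        if self.exclude_atc:
            spec["exclude_atc"] = list(self.exclude_atc)
        return {"co_prescribed_count": spec}


@dataclass(frozen=True)
class ConditionPresent(Predicate):
    conditions: tuple[str, ...]
    within_months: Optional[float] = None

    def evaluate(self, state: PatientState) -> EvalResult:
        for c in self.conditions:
            if c in state.conditions:
                if self.within_months is None or state.conditions[c] <= self.within_months:
                    return EvalResult(True)
        return EvalResult(False)

    def to_obj(self) -> dict:
        spec: dict = {"conditions": list(self.conditions)}
        if self.within_months is not None:
            spec["within_months"] = self.within_months
        return {"condition_present": spec}


@dataclass(frozen=True)
class ConditionAbsent(Predicate):
    conditions: tuple[str, ...]
    within_months: Optional[float] = None

    def evaluate(self, state: PatientState) -> EvalResult:
        for c in self.conditions:
            if c in state.conditions:
                if self.within_months is None or state.conditions[c] <= self.within_months:
                    return EvalResult(False)
        return EvalResult(True)

    def to_obj(self) -> dict:
        spec: dict = {"conditions": list(self.conditions)}
        if self.within_months is not None:
            spec["within_months"] = self.within_months
        return {"condition_absent": spec}


@dataclass(frozen=True)
class Measure(Predicate):
    measure_field: str
    cmp: str
    value: float

    def evaluate(self, state: PatientState) -> EvalResult:
        if state.snapshot is None:
            raise Abstain(f"no clinical snapshot for {self.measure_field}")
        v = state.snapshot.measure(self.measure_field)
        if v is None:
            raise Abstain(f"clinical value {self.measure_field} missing")
        return EvalResult(_cmp(self.cmp)(v, self.value))

    def to_obj(self) -> dict:
        return {"measure": {"field": self.measure_field, "cmp": self.cmp, "value": self.value}}


@dataclass(frozen=True)
class DoseFilter(Predicate):
    """Standalone dose atom: filters sibling drug matches in an ``all``."""

    spec: DoseSpec

    def evaluate(self, state: PatientState) -> EvalResult:  # only via And
        raise RuleSchemaError("standalone dose atom outside an 'all' with a drug atom")

    def to_obj(self) -> dict:
        return {"dose": {"cmp": self.spec.cmp, "value": self.spec.value, "unit": self.spec.unit}}


@dataclass(frozen=True)
class DurationFilter(Predicate):
    """Standalone duration atom: filters sibling drug matches in an ``all``."""

    spec: DurationSpec

    def evaluate(self, state: PatientState) -> EvalResult:
        raise RuleSchemaError("standalone duration atom outside an 'all' with a drug atom")

    def to_obj(self) -> dict:
        return {"duration": {"cmp": self.spec.cmp, "months": self.spec.months}}


@dataclass(frozen=True)
class ProcedureDone(Predicate):
    label: str

    def evaluate(self, state: PatientState) -> EvalResult:
        return EvalResult(self.label in state.conditions)

    def to_obj(self) -> dict:
        return {"procedure_done": {"label": self.label}}


@dataclass(frozen=True)
class And(Predicate):
    """Conjunction with Kleene semantics: False AND Unknown = False.

    An abstaining child (missing clinical value) only propagates when no
    other child is definitively false — a rule that cannot fire anyway is
    false, not uncodable.
    """

    children: tuple[Predicate, ...]

    def evaluate(self, state: PatientState) -> EvalResult:
        support: list[Prescription] = []
        value = True
        abstain: Optional[Abstain] = None
        for child in self.children:
            if isinstance(child, DoseFilter):
                support = [rx for rx in support if child.spec.satisfied_by(rx)]
                value = value and bool(support)
                continue
            if isinstance(child, DurationFilter):
                support = [rx for rx in support if child.spec.satisfied_by(rx, state)]
                value = value and bool(support)
                continue
            try:
                res = child.evaluate(state)
            except Abstain as ab:
                abstain = ab
                continue
            value = value and res.value
            support.extend(rx for rx in res.support if rx not in support)
        if abstain is not None and value:
            raise abstain
        return EvalResult(value, tuple(support) if value else ())

    def to_obj(self) -> dict:
        return {"all": [c.to_obj() for c in self.children]}

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class Or(Predicate):
    """Disjunction with Kleene semantics: True OR Unknown = True."""

    children: tuple[Predicate, ...]

    def evaluate(self, state: PatientState) -> EvalResult:
        support: list[Prescription] = []
        value = False
        abstain: Optional[Abstain] = None
        for child in self.children:
            try:
                res = child.evaluate(state)
            except Abstain as ab:
                abstain = ab
                continue
            if res.value:
                value = True
                support.extend(rx for rx in res.support if rx not in support)
        if abstain is not None and not value:
            raise abstain
        return EvalResult(value, tuple(support))

    def to_obj(self) -> dict:
        return {"any": [c.to_obj() for c in self.children]}

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class Not(Predicate):
    child: Predicate

    def evaluate(self, state: PatientState) -> EvalResult:
        return EvalResult(not self.child.evaluate(state).value)

    def to_obj(self) -> dict:
        return {"not": self.child.to_obj()}

    def walk(self):
        yield self
        yield from self.child.walk()


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ATOM_NAMES = {
    "drug_active",
    "drug_absent",
    "co_prescribed_count",
    "condition_present",
    "condition_absent",
    "measure",
    "dose",
    "duration",
    "procedure_done",
    "all",
    "any",
    "not",
}


def parse_predicate(obj: dict, where: str = "trigger") -> Predicate:
    """Parse the YAML/dict form of a predicate tree."""
    if not isinstance(obj, dict) or len(obj) != 1:
        raise RuleSchemaError(f"{where}: predicate node must be a single-key mapping")
    (name, spec), = obj.items()
    if name not in _ATOM_NAMES:
        raise RuleSchemaError(f"{where}: unknown atom {name!r}")
    if name == "all":
        return And(tuple(parse_predicate(c, where) for c in spec))
    if name == "any":
        return Or(tuple(parse_predicate(c, where) for c in spec))
    if name == "not":
        return Not(parse_predicate(spec, where))
    if name == "drug_active":
        dose = DoseSpec(**spec["dose"]) if "dose" in spec else None
        duration = DurationSpec(**spec["duration"]) if "duration" in spec else None
        if dose:
            _cmp(dose.cmp)
        if duration:
            _cmp(duration.cmp)
        return DrugActive(_check_atc_set(spec["atc"], where), dose, duration)
    if name == "drug_absent":
        return DrugAbsent(_check_atc_set(spec["atc"], where))
    if name == "co_prescribed_count":
        _cmp(spec["cmp"])
        return CoPrescribedCount(
            _check_atc_set(spec["atc"], where),
            spec["cmp"],
            int(spec["count"]),
            tuple(spec.get("exclude_atc", ())),
        )
    if name == "condition_present":
        return ConditionPresent(tuple(spec["conditions"]), spec.get("within_months"))
    if name == "condition_absent":
        return ConditionAbsent(tuple(spec["conditions"]), spec.get("within_months"))
    if name == "measure":
        _cmp(spec["cmp"])
        return Measure(spec["field"], spec["cmp"], float(spec["value"]))
    if name == "dose":
        d = DoseSpec(**spec)
        _cmp(d.cmp)
        return DoseFilter(d)
    if name == "duration":
        d = DurationSpec(**spec)
        _cmp(d.cmp)
        return DurationFilter(d)
    if name == "procedure_done":
        return ProcedureDone(spec["label"])
    raise AssertionError(name)


# ---------------------------------------------------------------------------
# Rules and rulebank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    rule_id: str
    source_tool: str
    rule_kind: str
    trigger: Predicate
    dedup_key: str
    description: str = ""
    citation: str = ""

    def __post_init__(self) -> None:
        if self.source_tool not in TOOLS:
            raise RuleSchemaError(f"{self.rule_id}: unknown source tool {self.source_tool!r}")
        if self.rule_kind not in RULE_KINDS:
            raise RuleSchemaError(f"{self.rule_id}: unknown rule kind {self.rule_kind!r}")
        if not self.dedup_key:
            raise RuleSchemaError(f"{self.rule_id}: missing dedup_key")
        if self.rule_kind == "omission" and self.source_tool not in ("START", "AMI"):
            raise RuleSchemaError(
                f"{self.rule_id}: omission rules must come from START or AMI"
            )
        if self.rule_kind == "interaction":
            drug_atoms = [a for a in self.trigger.walk() if isinstance(a, DrugActive)]
            if len(drug_atoms) < 2:
                raise RuleSchemaError(
                    f"{self.rule_id}: interaction rules need >=2 drug_active atoms"
                )
            a, b = set(drug_atoms[0].atc), set(drug_atoms[1].atc)
            if a & b:
                raise RuleSchemaError(
                    f"{self.rule_id}: interaction atc sets must be disjoint"
                )

    def drug_atoms(self) -> list[DrugActive]:
        return [a for a in self.trigger.walk() if isinstance(a, DrugActive)]


@dataclass
class Diagnostic:
    severity: str  # "error" | "warning" | "info"
    rule_id: str
    message: str


@dataclass
class RuleBank:
    rules: list[Rule]
    atc_catalogue: dict[str, dict] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rules:
            if r.rule_id in seen:
                raise RuleSchemaError(f"duplicate rule_id {r.rule_id!r}")
            seen.add(r.rule_id)

    def __len__(self) -> int:
        return len(self.rules)

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def counts_by_tool(self) -> dict[str, int]:
        counts = {t: 0 for t in TOOLS}
        for r in self.rules:
            counts[r.source_tool] += 1
        return counts

    @property
    def metadata(self) -> dict:
        return {"version": self.version, "n_rules": len(self.rules),
                "counts_by_tool": self.counts_by_tool}

    def rule_ids(self) -> list[str]:
        return [r.rule_id for r in self.rules]


def _rule_from_obj(obj: dict) -> Rule:
    try:
        trigger = parse_predicate(obj["trigger"], where=str(obj.get("id", "?")))
        return Rule(
            rule_id=obj["id"],
            source_tool=obj["tool"],
            rule_kind=obj["kind"],
            trigger=trigger,
            dedup_key=obj["dedup_key"],
            description=obj.get("description", ""),
            citation=obj.get("citation", ""),
        )
    except KeyError as exc:
        raise RuleSchemaError(f"rule {obj.get('id', '?')}: missing field {exc}") from exc


def load_rulebank(path: str | Path, atc_catalogue: Optional[dict] = None) -> RuleBank:
    """Load a YAML rule file into a validated :class:`RuleBank`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise RuleSchemaError("rule file must be a mapping with a 'rules' list")
    rules = [_rule_from_obj(o) for o in doc["rules"]]
    return RuleBank(
        rules=rules,
        atc_catalogue=atc_catalogue or {},
        version=str(doc.get("version", "unversioned")),
    )


def save_rulebank(bank: RuleBank, path: str | Path) -> None:
    """Serialize a rulebank back to the YAML schema (round-trip stable)."""
    doc = {
        "version": bank.version,
        "rules": [
            {
                "id": r.rule_id,
                "tool": r.source_tool,
                "kind": r.rule_kind,
                "dedup_key": r.dedup_key,
                "description": r.description,
                "citation": r.citation,
                "trigger": r.trigger.to_obj(),
            }
            for r in bank.rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def _load_catalogue() -> dict[str, dict]:
    src = importlib.resources.files("pipscreen.data") / "atc_catalogue.csv"
    with importlib.resources.as_file(src) as p:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    return {
        row["code"]: {
            "label": row["label"],
            "eu7_pim": row["eu7_pim"] == "1",
            "withdrawn": row["withdrawn"] == "1",
        }
        for _, row in df.iterrows()
    }


def builtin_rulebank() -> RuleBank:
    """The packaged demonstration rulebank (with its ATC catalogue)."""
    src = importlib.resources.files("pipscreen.data") / "builtin_rules.yaml"
    with importlib.resources.as_file(src) as p:
        bank = load_rulebank(p, atc_catalogue=_load_catalogue())
    return bank


def validate_rulebank(
    bank: RuleBank, vocabulary: frozenset[str] = CONDITION_VOCABULARY
) -> list[Diagnostic]:
    """Machine-readable diagnostics for a rulebank (never raises).

    Reports condition labels outside the vocabulary (unreachable
    predicates), ATC references missing from the catalogue (warnings), and
    distinct rules sharing a dedup_key (declared strict redundancy, info).
    """
    out: list[Diagnostic] = []
    for r in bank.rules:
        for node in r.trigger.walk():
            if isinstance(node, (ConditionPresent, ConditionAbsent)):
                for c in node.conditions:
                    if c not in vocabulary:
                        out.append(
                            Diagnostic("error", r.rule_id,
                                       f"condition {c!r} not in vocabulary")
                        )
            if isinstance(node, ProcedureDone) and node.label not in vocabulary:
                out.append(
                    Diagnostic("error", r.rule_id,
                               f"procedure label {node.label!r} not in vocabulary")
                )
            if bank.atc_catalogue and isinstance(node, DrugActive):
                for code in node.atc:
                    known = any(k.startswith(code) or code.startswith(k)
                                for k in bank.atc_catalogue)
                    if not known:
                        out.append(
                            Diagnostic("warning", r.rule_id,
                                       f"ATC reference {code!r} not in catalogue")
                        )
    by_key: dict[str, list[Rule]] = {}
    for r in bank.rules:
        by_key.setdefault(r.dedup_key, []).append(r)
    for key, rs in by_key.items():
        tools = {r.source_tool for r in rs}
        if len(tools) > 1:
            out.append(
                Diagnostic(
                    "info",
                    ",".join(sorted(r.rule_id for r in rs)),
                    f"declared strict redundancy across tools on dedup_key {key!r}",
                )
            )
    return out
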