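"""Independent oracles used by the test suite.

These deliberately re-derive results through naive, separate code paths:
a brute-force rule evaluator (plain loops over prescriptions/conditions,
no shared evaluation machinery), an exhaustive fixed-margin enumeration
for the two-sided Fisher p-value, and a Monte-Carlo sampler of the
fixed-margin (permutation) null for the chi-square test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2_contingency, multivariate_hypergeom

from pipscreen import rules as R


# ---------------------------------------------------------------------------
# Brute-force rule evaluation
# ---------------------------------------------------------------------------

class _NaiveAbstain(Exception):
    pass


def _matches(code, prefixes):
    return any(code.startswith(p) for p in prefixes)


def _dose_ok(rx, spec):
    if rx.dose_value is None:
        return False
    if spec.unit and rx.dose_unit.lower() != spec.unit.lower():
        return False
    return _cmp_op(spec.cmp, rx.dose_value, spec.value)


def _cmp_op(name, a, b):
    return {
        "<": a < b, "<=": a <= b, "=": a == b, "==": a == b,
        ">=": a >= b, ">": a > b,
    }[name]


def _naive_eval(node, active, conds, snap, visit_date):
    """Returns (truth, supporting prescriptions)."""
    if isinstance(node, R.And):
        # Kleene: False AND Unknown = False; abstain only if possibly true
        ok = True
        abstained = None
        support = []
        for child in node.children:
            if isinstance(child, R.DoseFilter):
                support = [rx for rx in support if _dose_ok(rx, child.spec)]
                ok = ok and len(support) > 0
            elif isinstance(child, R.DurationFilter):
                support = [
                    rx for rx in support
                    if _cmp_op(child.spec.cmp,
                               (visit_date - rx.start_date).days / 30.4375,
                               child.spec.months)
                ]
                ok = ok and len(support) > 0
            else:
                try:
                    v, s = _naive_eval(child, active, conds, snap, visit_date)
                except _NaiveAbstain as ab:
                    abstained = ab
                    continue
                ok = ok and v
                for rx in s:
                    if rx not in support:
                        support.append(rx)
        if abstained is not None and ok:
            raise abstained
        return ok, (support if ok else [])
    if isinstance(node, R.Or):
        # Kleene: True OR Unknown = True
        support = []
        ok = False
        abstained = None
        for child in node.children:
            try:
                v, s = _naive_eval(child, active, conds, snap, visit_date)
            except _NaiveAbstain as ab:
                abstained = ab
                continue
            if v:
                ok = True
                for rx in s:
                    if rx not in support:
                        support.append(rx)
        if abstained is not None and not ok:
            raise abstained
        return ok, support
    if isinstance(node, R.Not):
        v, _ = _naive_eval(node.child, active, conds, snap, visit_date)
        return (not v), []
    if isinstance(node, R.DrugActive):
        hits = [rx for rx in active if _matches(rx.atc_code, node.atc)]
        if node.dose is not None:
            hits = [rx for rx in hits if _dose_ok(rx, node.dose)]
        if node.duration is not None:
            hits = [
                rx for rx in hits
                if _cmp_op(node.duration.cmp,
                           (visit_date - rx.start_date).days / 30.4375,
                           node.duration.months)
            ]
        return len(hits) > 0, hits
    if isinstance(node, R.DrugAbsent):
        return all(not _matches(rx.atc_code, node.atc) for rx in active), []
    if isinstance(node, R.CoPrescribedCount):
        n = 0
        for rx in active:
            if _matches(rx.atc_code, node.atc):
                if node.exclude_atc and _matches(rx.atc_code, node.exclude_atc):
                    continue
                n += 1
        return _cmp_op(node.cmp, n, node.count), []
    if isinstance(node, R.ConditionPresent):
        for c in node.conditions:
            if c in conds and (node.within_months is None
                               or conds[c] <= node.within_months):
                return True, []
        return False, []
    if isinstance(node, R.ConditionAbsent):
        for c in node.conditions:
            if c in conds and (node.within_months is None
                               or conds[c] <= node.within_months):
                return False, []
        return True, []
    if isinstance(node, R.Measure):
        if snap is None:
            raise _NaiveAbstain(node.measure_field)
        v = snap.measure(node.measure_field)
        if v is None:
            raise _NaiveAbstain(node.measure_field)
        return _cmp_op(node.cmp, v, node.value), []
    if isinstance(node, R.ProcedureDone):
        return node.label in conds, []
    raise AssertionError(type(node))


def brute_force_mrncs(cohort, bank):
    """Set of (patient_id, visit_month, rule_id, frozenset of trigger codes)."""
    out = set()
    for pid in sorted(cohort.patients):
        patient = cohort.patients[pid]
        for month in patient.visit_months:
            vd = patient.visit_date(month)
            active = [
                rx for rx in cohort.prescriptions[pid]
                if rx.start_date <= vd and (rx.end_date is None or rx.end_date >= vd)
            ]
            conds = {}
            for cm in cohort.comorbidities[pid]:
                if cm.onset_date <= vd:
                    elapsed = (vd - cm.onset_date).days / 30.4375
                    conds[cm.condition] = min(conds.get(cm.condition, elapsed), elapsed)
            months = [m for m in cohort.snapshots[pid] if m <= month]
            snap = cohort.snapshots[pid][max(months)] if months else None
            for rule in bank.rules:
                try:
                    ok, support = _naive_eval(rule.trigger, active, conds, snap, vd)
                except _NaiveAbstain:
                    continue
                if not ok:
                    continue
                if rule.rule_kind == "omission":
                    out.add((pid, month, rule.rule_id, frozenset()))
                elif rule.rule_kind == "interaction":
                    atoms = [a for a in rule.trigger.walk()
                             if isinstance(a, R.DrugActive)]
                    _, sa = _naive_eval(atoms[0], active, conds, snap, vd)
                    _, sb = _naive_eval(atoms[1], active, conds, snap, vd)
                    for ra in sa:
                        for rb in sb:
                            out.add((pid, month, rule.rule_id,
                                     frozenset((ra.atc_code, rb.atc_code))))
                else:
                    for rx in support:
                        out.add((pid, month, rule.rule_id,
                                 frozenset((rx.atc_code,))))
    return out


# ---------------------------------------------------------------------------
# Exact Fisher by full enumeration
# ---------------------------------------------------------------------------

def fisher_enum_p(table) -> float:
    """Two-sided Fisher p via exhaustive enumeration of fixed-margin tables.

    Sums P(table) over all tables with the observed margins whose point
    hypergeometric probability is <= that of the observed table
    (minimum-likelihood rule).
    """
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# Permutation-null Monte Carlo for the chi-square test
# ---------------------------------------------------------------------------

def chi2_permutation_p(table, n_mc: int = 200_000, seed: int = 0) -> tuple[float, float]:
    """MC estimate of the fixed-margin (permutation) null p for a 2xC table.

    Tables are sampled directly from the multivariate hypergeometric
    distribution, which is exactly the conditional distribution of a
    contingency table given its margins under independence.  Returns
    (p_estimate, MC standard error).
    """
    t = np.asarray(table, dtype=int)
    assert t.shape[0] == 2, "2xC tables only"
    colsums = t.sum(axis=0)
    n1 = int(t.sum(axis=1)[0])
    n = int(t.sum())
    obs = chi2_contingency(t, correction=False)[0]
    rng = np.random.default_rng(seed)
    row1 = multivariate_hypergeom.rvs(m=colsums, n=n1, size=n_mc, random_state=rng)
    row2 = colsums[None, :] - row1
    E = np.outer(t.sum(axis=1), colsums) / n
    stats = ((row1 - E[0]) ** 2 / E[0] + (row2 - E[1]) ** 2 / E[1]).sum(axis=1)
    p = float((stats >= obs - 1e-12).mean())
    se = math.sqrt(max(p * (1 - p), 1e-12) / n_mc)
    return p, se
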