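"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as plain, direct predicates and
normal-equation algebra, independent of the package's own code paths, so
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

from vnaflow.core import Analyte, InjectionRecord, MethodConstants, Role
from vnaflow.qa import QARuleConfig
from vnaflow.westgard import Action, RuleName, Scope, WestgardRuleSet


def wls_line_oracle(x, y, w):
    """Weighted least-squares line by explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    intercept, slope = np.linalg.solve(A, b)
    return float(intercept), float(slope)


def repeatability_oracle(a: float, b: float, constants: MethodConstants) -> bool:
    m = (a + b) / 2.0
    if m == 0.0:
        return a == 0.0 and b == 0.0
    limit = 20.0 if m < constants.repeatability_cut_pg_ml else 10.0
    return abs(a - b) / m * 100.0 <= limit


def make_record(
    analyte: Analyte,
    sample_id: str = "S1",
    well: str = "A3",
    injection_index: int = 1,
    role: Role = Role.UNKNOWN,
    quant_area: float = 50_000.0,
    istd_area: float = 200_000.0,
    confirm_area: float | None = None,
    rt_offset: float = 0.0,
    rt_istd_offset: float = 0.0,
    calibrant_amount_ratio: float | None = None,
) -> InjectionRecord:
    """Record with every QA rule passing unless an offset/area says otherwise."""
    if confirm_area is None:
        confirm_area = analyte.expected_ion_ratio * quant_area
    return InjectionRecord(
        sample_id=sample_id,
        well=well,
        injection_index=injection_index,
        role=role,
        analyte=analyte.name,
        quant_area=quant_area,
        confirm_area=confirm_area,
        istd_area=istd_area,
        rt_quant_min=analyte.expected_rt_min + rt_offset,
        rt_istd_min=analyte.expected_rt_istd_min + rt_istd_offset,
        calibrant_amount_ratio=calibrant_amount_ratio,
    )


def qa_flags_oracle(
    record: InjectionRecord,
    quantifiable: bool,
    analyte: Analyte,
    cfg: QARuleConfig,
    blank_raw_concs: list[float],
    predecessor_max_conc: float | None,
    threshold: float,
) -> dict[str, bool]:
    """Plain-predicate re-evaluation of the per-sample rule list."""
    tol = cfg.ion_ratio_tolerance_pct / 100.0
    exp = analyte.expected_ion_ratio
    if record.quant_area > 0:
        obs = record.confirm_area / record.quant_area
        ion_ok = exp * (1 - tol) <= obs <= exp * (1 + tol)
    else:
        ion_ok = False
    limit = cfg.blank_limit_for(analyte)
    return {
        "rt_quant": abs(record.rt_quant_min - analyte.expected_rt_min)
        <= cfg.rt_tolerance_min,
        "rt_istd": abs(record.rt_istd_min - analyte.expected_rt_istd_min)
        <= cfg.rt_tolerance_min,
        "ion_ratio": ion_ok,
        "istd_area": record.istd_area >= cfg.istd_area_min,
        "blank_limit": all(c <= limit for c in blank_raw_concs),
        "carryover_follow": predecessor_max_conc is None
        or predecessor_max_conc <= threshold,
        "unquantifiable": quantifiable,
    }


def westgard_oracle(
    series: dict[str, list[float]], rules: WestgardRuleSet
) -> tuple[str, set[str]]:
    """Textbook-definition evaluation of the multirule family on z-score
    series (one chronological list per pool, current value last).

    Returns (status, fired rule names). All excursions are strict.
    """
    cur = {p: s[-1] for p, s in series.items()}
    cur_vals = list(cur.values())
    fired: set[str] = set()
    reject = False
    warn = False

    for rule, spec in rules.rules.items():
        within = spec.scope in (Scope.WITHIN_POOL, Scope.BOTH)
        across = spec.scope in (Scope.ACROSS_POOL, Scope.BOTH)
        hit = False
        if rule is RuleName.ONE_2S:
            hit = any(z > 2 or z < -2 for z in cur_vals)
        elif rule is RuleName.ONE_3S:
            hit = any(z > 3 or z < -3 for z in cur_vals)
        elif rule is RuleName.TWO_2S:
            if across and len(cur_vals) >= 2:
                if all(z > 2 for z in cur_vals) or all(z < -2 for z in cur_vals):
                    hit = True
            if within and not hit:
                for s in series.values():
                    if len(s) >= 2:
                        last2 = s[-2:]
                        if all(z > 2 for z in last2) or all(z < -2 for z in last2):
                            hit = True
        elif rule is RuleName.R_4S:
            if len(cur_vals) >= 2:
                hit = max(cur_vals) > 2 and min(cur_vals) < -2
        elif rule is RuleName.FOUR_1S:
            if within:
                for s in series.values():
                    if len(s) >= 4:
                        last4 = s[-4:]
                        if all(z > 1 for z in last4) or all(z < -1 for z in last4):
                            hit = True
            if across and not hit and len(series) >= 2:
                if all(len(s) >= 2 for s in series.values()):
                    comb = [z for s in series.values() for z in s[-2:]]
                    if all(z > 1 for z in comb) or all(z < -1 for z in comb):
                        hit = True
        elif rule is RuleName.TEN_X:
            if within:
                for s in series.values():
                    if len(s) >= 10:
                        last10 = s[-10:]
                        if all(z > 0 for z in last10) or all(z < 0 for z in last10):
                            hit = True
            if across and not hit and len(series) >= 2:
                if all(len(s) >= 5 for s in series.values()):
                    comb = [z for s in series.values() for z in s[-5:]]
                    if all(z > 0 for z in comb) or all(z < 0 for z in comb):
                        hit = True
        if hit:
            fired.add(rule.value)
            if spec.action is Action.REJECT:
                reject = True
            else:
                warn = True
    status = "reject" if reject else ("warn" if warn else "accept")
    return status, fired
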