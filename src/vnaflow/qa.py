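"""Per-sample QA rules and batch-level run rejection.

Every unknown is evaluated individually against the method's QA rule list:
retention times of the quant-ion and ISTD peaks, confirmation-ion ratio,
minimum ISTD area, the batch blank-limit check, and the carryover-follow
rule (a sample injected immediately after any injection above 200 pg/mL must
be reinjected and pass tiered repeatability criteria). Runs are rejected
outright when either DCM blank exceeds the established per-analyte blank
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .core import (
    Analyte,
    AnalytePanel,
    ConfigError,
    InjectionRecord,
    MethodConstants,
    OrderingError,
    Role,
)
from .quantify import QuantResult


class RuleId(str, Enum):
    RT_QUANT = "rt_quant"
    RT_ISTD = "rt_istd"
    ION_RATIO = "ion_ratio"
    ISTD_AREA = "istd_area"
    BLANK_LIMIT = "blank_limit"
    CARRYOVER_FOLLOW = "carryover_follow"
    REPEAT_FAIL = "repeat_fail"
    UNQUANTIFIABLE = "unquantifiable"


#: Rules evaluated for every (sample, analyte); REPEAT_FAIL is emitted only
#: during reinjection resolution.
SAMPLE_RULES = (
    RuleId.RT_QUANT,
    RuleId.RT_ISTD,
    RuleId.ION_RATIO,
    RuleId.ISTD_AREA,
    RuleId.BLANK_LIMIT,
    RuleId.CARRYOVER_FOLLOW,
    RuleId.UNQUANTIFIABLE,
)


@dataclass(frozen=True)
class QAFlag:
    rule_id: RuleId
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class QARuleConfig:
    """Tolerances for the per-sample rules.

    RT tolerance, ion-ratio tolerance and the ISTD-area floor are
    laboratory-set method parameters; the shipped defaults are documented
    working values (0.1 min, +-20 % relative, 50k counts). ``blank_limits``
    overrides the panel's per-analyte limits when given. ``check_leading_acn``
    additionally holds the batch-opening ACN solvent blank to the same blank
    limits as the DCM blanks.
    """

    rt_tolerance_min: float = 0.1
    ion_ratio_tolerance_pct: float = 20.0
    istd_area_min: float = 50_000.0
    blank_limits: Optional[Mapping[str, float]] = None
    check_leading_acn: bool = True

    def __post_init__(self) -> None:
        if not self.rt_tolerance_min > 0:
            raise ConfigError("rt_tolerance_min must be > 0")
        if not self.ion_ratio_tolerance_pct > 0:
            raise ConfigError("ion_ratio_tolerance_pct must be > 0")
        if self.istd_area_min < 0:
            raise ConfigError("istd_area_min must be >= 0")

    def blank_limit_for(self, analyte: Analyte) -> float:
        if self.blank_limits and analyte.name in self.blank_limits:
            return float(self.blank_limits[analyte.name])
        return analyte.blank_limit_pg_ml


def check_retention_times(
    record: InjectionRecord, analyte: Analyte, cfg: QARuleConfig
) -> tuple[QAFlag, QAFlag]:
    """RT check for the quant-ion peak and the ISTD peak, separately."""
    flags = []
    for rule, observed, expected in (
        (RuleId.RT_QUANT, record.rt_quant_min, analyte.expected_rt_min),
        (RuleId.RT_ISTD, record.rt_istd_min, analyte.expected_rt_istd_min),
    ):
        dev = observed - expected
        ok = abs(dev) <= cfg.rt_tolerance_min
        flags.append(
            QAFlag(
                rule,
                ok,
                f"observed {observed:.3f} min, expected {expected:.3f} min, "
                f"deviation {dev:+.3f} min (tol {cfg.rt_tolerance_min:.3f})",
            )
        )
    return flags[0], flags[1]


def check_ion_ratio(
    record: InjectionRecord, analyte: Analyte, cfg: QARuleConfig
) -> QAFlag:
    """Confirmation/quant ion-area ratio within a relative window (closed
    interval) of the expected ratio."""
    if record.quant_area == 0:
        return QAFlag(RuleId.ION_RATIO, False, "no quant peak")
    observed = record.confirm_area / record.quant_area
    tol = cfg.ion_ratio_tolerance_pct / 100.0
    lo, hi = analyte.expected_ion_ratio * (1 - tol), analyte.expected_ion_ratio * (1 + tol)
    ok = lo <= observed <= hi
    return QAFlag(
        RuleId.ION_RATIO,
        ok,
        f"observed {observed:.3f}, window [{lo:.3f}, {hi:.3f}]",
    )


def check_istd_area(record: InjectionRecord, cfg: QARuleConfig) -> QAFlag:
    ok = record.istd_area >= cfg.istd_area_min
    return QAFlag(
        RuleId.ISTD_AREA,
        ok,
        f"area {record.istd_area:.0f}, minimum {cfg.istd_area_min:.0f}",
    )


@dataclass(frozen=True)
class RunBlankVerdict:
    """Run-level accept/reject based on the DCM (and optionally the leading
    ACN) blanks. ``offenders`` lists (blank sample_id, analyte) pairs whose
    raw concentration strictly exceeds the blank limit."""

    accepted: bool
    offenders: tuple[tuple[str, str], ...] = ()
    reason: str = ""


def check_run_blanks(
    blank_results: Sequence[QuantResult],
    panel: AnalytePanel,
    cfg: QARuleConfig,
) -> RunBlankVerdict:
    """Reject the run if any DCM blank result exceeds its analyte's blank
    limit (strict '>': a blank exactly at the limit is accepted)."""
    dcm = [r for r in blank_results if r.role is Role.DCM_BLANK]
    per_analyte: dict[str, int] = {}
    for r in dcm:
        per_analyte[r.analyte] = per_analyte.get(r.analyte, 0) + 1
    for analyte in panel.names:
        if per_analyte.get(analyte, 0) != 2:
            return RunBlankVerdict(
                False, (), f"missing blank: expected 2 DCM blanks for {analyte}"
            )
    offenders = []
    for r in dcm:
        a = panel.get(r.analyte)
        if a is None:
            continue
        if not r.quantifiable:
            return RunBlankVerdict(False, (), f"missing blank: {r.sample_id}/{r.analyte} unquantifiable")
        if r.raw_conc_pg_ml > cfg.blank_limit_for(a):
            offenders.append((r.sample_id, r.analyte))
    if cfg.check_leading_acn:
        acn = [r for r in blank_results if r.role is Role.ACN_BLANK]
        if acn:
            lead_idx = min(r.injection_index for r in acn)
            for r in acn:
                if r.injection_index != lead_idx:
                    continue  # post-standard purge blanks are not held to blank limits
                a = panel.get(r.analyte)
                if a is not None and r.quantifiable and r.raw_conc_pg_ml > cfg.blank_limit_for(a):
                    offenders.append((r.sample_id, r.analyte))
    accepted = not offenders
    return RunBlankVerdict(
        accepted,
        tuple(offenders),
        "" if accepted else "blank limit exceeded: "
        + ", ".join(f"{s}/{an}" for s, an in offenders),
    )


def flag_carryover_follow(
    results: Sequence[QuantResult],
    constants: MethodConstants,
) -> dict[tuple[str, str], QAFlag]:
    """Carryover-precaution flags, keyed by (sample_id, analyte).

    Results must be ordered by injection index. An unknown whose immediately
    preceding injection carried any analyte above the flag threshold
    (strictly > 200 pg/mL by default, on blank-subtracted values) is flagged
    for reinjection; all of its analytes are flagged since the whole vial is
    reinjected. The first injection of a batch is never flagged.
    """
    indices = [r.injection_index for r in results]
    if indices != sorted(indices):
        raise OrderingError("results must be sorted by injection_index")

    by_injection: dict[int, list[QuantResult]] = {}
    for r in results:
        by_injection.setdefault(r.injection_index, []).append(r)
    order = sorted(by_injection)

    flags: dict[tuple[str, str], QAFlag] = {}
    prev_idx: Optional[int] = None
    for idx in order:
        group = by_injection[idx]
        if all(r.role is not Role.UNKNOWN for r in group):
            prev_idx = idx
            continue
        fail = False
        detail = "no high-concentration predecessor"
        if prev_idx is not None:
            prev = by_injection[prev_idx]
            concs = [
                r.blank_sub_conc_pg_ml
                for r in prev
                if r.quantifiable and r.blank_sub_conc_pg_ml is not None
            ]
            if concs:
                peak = max(concs)
                if peak > constants.carryover_flag_threshold_pg_ml:
                    fail = True
                    detail = (
                        f"predecessor injection {prev_idx} at {peak:.1f} pg/mL "
                        f"> {constants.carryover_flag_threshold_pg_ml:.0f} pg/mL; reinject"
                    )
        for r in group:
            flags[(r.sample_id, r.analyte)] = QAFlag(
                RuleId.CARRYOVER_FOLLOW, not fail, detail
            )
        prev_idx = idx
    return flags


@dataclass(frozen=True)
class RepeatabilityResult:
    passed: bool
    pct_difference: float
    threshold_pct: float


def check_repeatability(
    conc_a: float, conc_b: float, constants: MethodConstants
) -> RepeatabilityResult:
    """Tiered duplicate-injection agreement.

    The relative difference |a-b| / mean(a,b) x 100 must be within 20 % when
    the mean is below 50 pg/mL and within 10 % at or above 50 pg/mL. Two
    exact zeros pass trivially.
    """
    m = (conc_a + conc_b) / 2.0
    if m == 0.0:
        if conc_a == conc_b == 0.0:
            return RepeatabilityResult(True, 0.0, constants.repeatability_low_pct)
        return RepeatabilityResult(False, float("inf"), constants.repeatability_low_pct)
    threshold = (
        constants.repeatability_low_pct
        if m < constants.repeatability_cut_pg_ml
        else constants.repeatability_high_pct
    )
    pct = abs(conc_a - conc_b) / m * 100.0
    return RepeatabilityResult(pct <= threshold, pct, threshold)


class Disposition(str, Enum):
    REPORT = "report"
    REINJECT = "reinject"
    REJECT = "reject"
    REPEAT = "repeat"  # re-prepare: reinjection failed repeatability


@dataclass(frozen=True)
class SampleAnalyteReport:
    sample_id: str
    analyte: str
    flags: tuple[QAFlag, ...]
    reportable: bool
    disposition: Disposition

    def flag(self, rule: RuleId) -> QAFlag:
        for f in self.flags:
            if f.rule_id is rule:
                return f
        raise KeyError(rule)

    @property
    def failing_rules(self) -> tuple[RuleId, ...]:
        return tuple(f.rule_id for f in self.flags if not f.passed)


@dataclass(frozen=True)
class SampleContext:
    """Batch-level inputs to per-sample evaluation: the run-blank verdict and
    the carryover-follow flags computed over the injection sequence."""

    blank_verdict: RunBlankVerdict
    carryover_flags: Mapping[tuple[str, str], QAFlag] = field(default_factory=dict)


def evaluate_sample(
    record: InjectionRecord,
    result: QuantResult,
    analyte: Analyte,
    cfg: QARuleConfig,
    context: SampleContext,
) -> SampleAnalyteReport:
    """Evaluate the full rule list for one (sample, analyte).

    Emits exactly one flag per rule in :data:`SAMPLE_RULES`. The sample is
    reportable iff every rule passes; a failing carryover-follow rule alone
    yields a ``reinject`` disposition (the value may still be reported if a
    reinjection passes repeatability), any other failure yields ``reject``.
    """
    rt_q, rt_i = check_retention_times(record, analyte, cfg)
    flags = [
        rt_q,
        rt_i,
        check_ion_ratio(record, analyte, cfg),
        check_istd_area(record, cfg),
        QAFlag(
            RuleId.BLANK_LIMIT,
            context.blank_verdict.accepted,
            context.blank_verdict.reason or "batch blanks within limits",
        ),
        context.carryover_flags.get(
            (record.sample_id, record.analyte),
            QAFlag(RuleId.CARRYOVER_FOLLOW, True, "no high-concentration predecessor"),
        ),
        QAFlag(
            RuleId.UNQUANTIFIABLE,
            result.quantifiable,
            "" if result.quantifiable else "internal standard area is zero",
        ),
    ]
    failing = [f.rule_id for f in flags if not f.passed]
    reportable = not failing
    if not failing:
        disposition = Disposition.REPORT
    elif failing == [RuleId.CARRYOVER_FOLLOW]:
        disposition = Disposition.REINJECT
    else:
        disposition = Disposition.REJECT
    return SampleAnalyteReport(
        sample_id=record.sample_id,
        analyte=record.analyte,
        flags=tuple(flags),
        reportable=reportable,
        disposition=disposition,
    )


@dataclass(frozen=True)
class BatchQAReport:
    batch_id: str
    blank_verdict: RunBlankVerdict
    sample_reports: tuple[SampleAnalyteReport, ...]

    def for_sample(self, sample_id: str) -> list[SampleAnalyteReport]:
        return [r for r in self.sample_reports if r.sample_id == sample_id]


def evaluate_batch_qa(
    batch_id: str,
    records: Sequence[InjectionRecord],
    results: Sequence[QuantResult],
    panel: AnalytePanel,
    cfg: QARuleConfig,
    constants: MethodConstants,
) -> BatchQAReport:
    """Run the full QA pass over a quantitated batch.

    Evaluates the run-blank verdict, computes carryover-follow flags over the
    injection sequence, and produces one report per unknown (sample, analyte).
    """
    ordered = sorted(results, key=lambda r: r.injection_index)
    blank_results = [
        r for r in ordered if r.role in (Role.DCM_BLANK, Role.ACN_BLANK)
    ]
    verdict = check_run_blanks(blank_results, panel, cfg)
    carry = flag_carryover_follow(ordered, constants)
    context = SampleContext(blank_verdict=verdict, carryover_flags=carry)

    rec_by_key = {
        (r.sample_id, r.analyte, r.injection_index): r for r in records
    }
    reports: list[SampleAnalyteReport] = []
    for res in ordered:
        if res.role is not Role.UNKNOWN:
            continue
        rec = rec_by_key.get((res.sample_id, res.analyte, res.injection_index))
        analyte = panel.get(res.analyte)
        if rec is None or analyte is None:
            continue
        reports.append(evaluate_sample(rec, res, analyte, cfg, context))
    return BatchQAReport(batch_id, verdict, tuple(reports))


@dataclass(frozen=True)
class ReinjectionResolution:
    """Outcome of comparing an original injection against its reinjection."""

    sample_id: str
    analyte: str
    passed: bool
    flag: QAFlag
    reported_conc_pg_ml: Optional[float]
    disposition: Disposition


def resolve_reinjection(
    original: QuantResult,
    reinjection: QuantResult,
    constants: MethodConstants,
) -> ReinjectionResolution:
    """Apply the repeatability criteria to an original/reinjection pair.

    A pair passing repeatability reports the reinjection value (carryover
    excluded); a failing pair sends the sample back for re-preparation
    (``repeat``). Both concentrations are the blank-subtracted values.
    """
    a = original.blank_sub_conc_pg_ml
    b = reinjection.blank_sub_conc_pg_ml
    if a is None or b is None:
        return ReinjectionResolution(
            original.sample_id,
            original.analyte,
            False,
            QAFlag(RuleId.REPEAT_FAIL, False, "missing concentration for repeatability"),
            None,
            Disposition.REPEAT,
        )
    rep = check_repeatability(a, b, constants)
    detail = (
        f"|{a:.2f} - {b:.2f}| / mean = {rep.pct_difference:.2f}% "
        f"(limit {rep.threshold_pct:.0f}%)"
    )
    if rep.passed:
        return ReinjectionResolution(
            original.sample_id,
            original.analyte,
            True,
            QAFlag(RuleId.REPEAT_FAIL, True, detail),
            b,
            Disposition.REPORT,
        )
    return ReinjectionResolution(
        original.sample_id,
        original.analyte,
        False,
        QAFlag(RuleId.REPEAT_FAIL, False, detail),
        None,
        Disposition.REPEAT,
    )
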