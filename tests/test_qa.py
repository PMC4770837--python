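"""Per-sample QA rules, run-blank rejection, carryover and repeatability."""

import pytest
from hypothesis import given, strategies as st

from vnaflow.core import Analyte, MethodConstants, OrderingError, Role
from vnaflow.qa import (
    Disposition,
    QAFlag,
    QARuleConfig,
    RuleId,
    SampleContext,
    RunBlankVerdict,
    check_ion_ratio,
    check_istd_area,
    check_repeatability,
    check_retention_times,
    check_run_blanks,
    evaluate_sample,
    flag_carryover_follow,
    resolve_reinjection,
)
from vnaflow.quantify import QuantResult

from oracles import make_record, repeatability_oracle

CFG = QARuleConfig(istd_area_min=5000.0)
RT_ANALYTE = Analyte("NDMA", "NDMA-d6", 8.50, 0.50, 13.0, 6.5, True)


def _result(analyte="NDMA", sample_id="S1", well="A3", idx=1, role=Role.UNKNOWN,
            raw=50.0, sub=None, quantifiable=True):
    return QuantResult(
        sample_id=sample_id, well=well, analyte=analyte, injection_index=idx,
        role=role, quantifiable=quantifiable,
        response_ratio=None if not quantifiable else raw / 250.0,
        raw_conc_pg_ml=None if not quantifiable else raw,
        blank_sub_conc_pg_ml=(raw if sub is None else sub) if quantifiable else None,
    )


class TestRetentionTimes:
    def test_within_tolerance_passes(self):
        rec = make_record(RT_ANALYTE, rt_offset=0.05)
        q, i = check_retention_times(rec, RT_ANALYTE, CFG)
        assert q.passed and i.passed

    def test_beyond_tolerance_fails_with_deviation_detail(self):
        rec = make_record(RT_ANALYTE, rt_offset=0.20)
        q, _ = check_retention_times(rec, RT_ANALYTE, CFG)
        assert not q.passed
        assert "+0.200" in q.detail

    def test_exact_match_passes(self):
        rec = make_record(RT_ANALYTE)
        q, i = check_retention_times(rec, RT_ANALYTE, CFG)
        assert q.passed and i.passed


class TestIonRatio:
    def test_within_twenty_percent_window(self):
        rec = make_record(RT_ANALYTE, quant_area=1e5, confirm_area=0.55e5)
        assert check_ion_ratio(rec, RT_ANALYTE, CFG).passed

    def test_outside_window_fails(self):
        rec = make_record(RT_ANALYTE, quant_area=1e5, confirm_area=0.65e5)
        assert not check_ion_ratio(rec, RT_ANALYTE, CFG).passed

    def test_window_boundary_is_closed(self):
        rec = make_record(RT_ANALYTE, quant_area=1e5, confirm_area=0.40e5)
        assert check_ion_ratio(rec, RT_ANALYTE, CFG).passed

    def test_missing_quant_peak_fails(self):
        rec = make_record(RT_ANALYTE, quant_area=0.0, confirm_area=0.0)
        flag = check_ion_ratio(rec, RT_ANALYTE, CFG)
        assert not flag.passed and "no quant peak" in flag.detail


class TestIstdArea:
    @pytest.mark.parametrize(
        "area,ok", [(5000.0, True), (0.0, False), (1e6, True), (4999.0, False)]
    )
    def test_minimum_area_boundary(self, area, ok):
        rec = make_record(RT_ANALYTE, istd_area=area)
        assert check_istd_area(rec, CFG).passed is ok


class TestRunBlanks:
    def _blanks(self, panel, ndma_concs=(5.0, 5.0), other=2.0):
        out = []
        for i, (sid, well) in enumerate([("DCM_BLANK_1", "A1"), ("DCM_BLANK_2", "F8")]):
            for a in panel.names:
                raw = ndma_concs[i] if a == "NDMA" else other
                out.append(_result(a, sid, well, i + 1, Role.DCM_BLANK, raw=raw))
        return out

    def test_all_below_limits_accepts(self, panel):
        verdict = check_run_blanks(self._blanks(panel), panel, CFG)
        assert verdict.accepted and not verdict.offenders

    def test_exceeding_blank_rejects_citing_analyte(self, panel):
        verdict = check_run_blanks(self._blanks(panel, (5.0, 20.0)), panel, CFG)
        assert not verdict.accepted
        assert ("DCM_BLANK_2", "NDMA") in verdict.offenders

    def test_exactly_at_limit_accepts(self, panel):
        limit = panel["NDMA"].blank_limit_pg_ml
        verdict = check_run_blanks(self._blanks(panel, (limit, limit)), panel, CFG)
        assert verdict.accepted  # the rule is a strict "exceeds"

    def test_missing_blank_rejects_with_reason(self, panel):
        blanks = [b for b in self._blanks(panel) if b.sample_id != "DCM_BLANK_2"]
        verdict = check_run_blanks(blanks, panel, CFG)
        assert not verdict.accepted and "missing blank" in verdict.reason

    def test_leading_acn_blank_held_to_limits_when_enabled(self, panel):
        blanks = self._blanks(panel)
        blanks.append(_result("NMEA", "ACN_LEAD", "ACN1", 1, Role.ACN_BLANK, raw=50.0))
        verdict = check_run_blanks(blanks, panel, CFG)
        assert not verdict.accepted
        off = check_run_blanks(
            blanks, panel, QARuleConfig(istd_area_min=5000.0, check_leading_acn=False)
        )
        assert off.accepted


class TestCarryoverFollow:
    def _seq(self, pred_conc, pred_role=Role.UNKNOWN):
        return [
            _result("NDMA", "P", "A3", 10, pred_role, sub=pred_conc),
            _result("NDMA", "S", "A4", 11, Role.UNKNOWN, sub=40.0),
        ]

    def test_predecessor_above_threshold_flags(self, constants):
        flags = flag_carryover_follow(self._seq(250.0), constants)
        assert not flags[("S", "NDMA")].passed

    def test_predecessor_below_threshold_does_not_flag(self, constants):
        flags = flag_carryover_follow(self._seq(150.0), constants)
        assert flags[("S", "NDMA")].passed

    def test_threshold_is_strict(self, constants):
        flags = flag_carryover_follow(self._seq(200.0), constants)
        assert flags[("S", "NDMA")].passed

    def test_first_injection_never_flagged(self, constants):
        flags = flag_carryover_follow(
            [_result("NDMA", "S", "A3", 1, Role.UNKNOWN, sub=40.0)], constants
        )
        assert flags[("S", "NDMA")].passed

    def test_any_analyte_of_predecessor_can_trigger(self, constants):
        seq = [
            _result("NDMA", "P", "A3", 10, Role.UNKNOWN, sub=10.0),
            _result("NPIP", "P", "A3", 10, Role.UNKNOWN, sub=300.0),
            _result("NDMA", "S", "A4", 11, Role.UNKNOWN, sub=40.0),
        ]
        flags = flag_carryover_follow(seq, constants)
        assert not flags[("S", "NDMA")].passed

    def test_unsorted_results_rejected(self, constants):
        with pytest.raises(OrderingError):
            flag_carryover_follow(self._seq(250.0)[::-1], constants)


class TestRepeatability:
    def test_low_tier_worked_pair_passes(self, constants):
        res = check_repeatability(40.0, 46.0, constants)
        assert res.passed
        assert res.pct_difference == pytest.approx(abs(40 - 46) / 43 * 100)
        assert res.threshold_pct == 20.0

    def test_high_tier_worked_pair_fails(self, constants):
        res = check_repeatability(100.0, 115.0, constants)
        assert not res.passed
        assert res.threshold_pct == 10.0
        assert res.pct_difference == pytest.approx(15 / 107.5 * 100)

    def test_double_zero_passes(self, constants):
        assert check_repeatability(0.0, 0.0, constants).passed

    @given(st.floats(min_value=1e-3, max_value=1e4, allow_nan=False))
    def test_identical_injections_always_pass(self, x):
        assert check_repeatability(x, x, MethodConstants()).passed

    @given(
        st.floats(min_value=0.0, max_value=300.0),
        st.floats(min_value=0.0, max_value=300.0),
    )
    def test_matches_direct_formula_oracle(self, a, b):
        constants = MethodConstants()
        assert check_repeatability(a, b, constants).passed == repeatability_oracle(
            a, b, constants
        )


class TestEvaluateSample:
    def _context(self, blank_ok=True, carry_flags=None):
        return SampleContext(
            RunBlankVerdict(blank_ok, (), "" if blank_ok else "blank limit exceeded"),
            carry_flags or {},
        )

    def test_all_rules_pass_is_reportable(self, panel):
        a = panel["NDMA"]
        rec = make_record(a, istd_area=2e5)
        rep = evaluate_sample(rec, _result(), a, CFG, self._context())
        assert rep.reportable and rep.disposition is Disposition.REPORT
        assert len(rep.flags) == 7  # one flag per rule, none skipped

    def test_single_ion_ratio_failure_blocks_reporting(self, panel):
        a = panel["NDMA"]
        rec = make_record(a, quant_area=1e5, confirm_area=1e5)
        rep = evaluate_sample(rec, _result(), a, CFG, self._context())
        assert not rep.reportable
        assert rep.failing_rules == (RuleId.ION_RATIO,)
        assert rep.disposition is Disposition.REJECT

    def test_carryover_only_failure_means_reinject(self, panel):
        a = panel["NDMA"]
        rec = make_record(a)
        carry = {("S1", "NDMA"): QAFlag(RuleId.CARRYOVER_FOLLOW, False, "reinject")}
        rep = evaluate_sample(rec, _result(), a, CFG, self._context(carry_flags=carry))
        assert rep.disposition is Disposition.REINJECT


class TestReinjection:
    def test_reinjection_passing_repeatability_reports_reinjection_value(self, constants):
        res = resolve_reinjection(
            _result(sub=40.0), _result(idx=2, sub=46.0), constants
        )
        assert res.passed
        assert res.reported_conc_pg_ml == 46.0
        assert res.disposition is Disposition.REPORT

    def test_reinjection_failing_repeatability_repeats_sample(self, constants):
        res = resolve_reinjection(
            _result(sub=100.0), _result(idx=2, sub=115.0), constants
        )
        assert not res.passed
        assert res.reported_conc_pg_ml is None
        assert res.disposition is Disposition.REPEAT
        assert res.flag.rule_id is RuleId.REPEAT_FAIL
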