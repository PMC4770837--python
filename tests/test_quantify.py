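"""Calibration fitting, back-calculation, and blank subtraction."""

import numpy as np
import pytest

from vnaflow.core import MethodConstants, Role
from vnaflow.quantify import (
    CalibrationCurve,
    CalibrationError,
    QuantResult,
    Weighting,
    blank_subtract,
    fit_calibration,
    quantify_batch,
    quantitate,
    response_ratio,
)
from vnaflow.simulate import generate_batch

from oracles import make_record, wls_line_oracle


def _cal_records(panel, xs, ys):
    a = panel["NDMA"]
    return [
        make_record(
            a,
            sample_id=f"CAL{i}",
            well=f"CAL{i}",
            injection_index=i + 1,
            role=Role.CALIBRANT,
            quant_area=y * 200_000.0,
            istd_area=200_000.0,
            calibrant_amount_ratio=x,
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


class TestResponseRatio:
    def test_simple_ratio(self, panel):
        rec = make_record(panel["NDMA"], quant_area=5000.0, istd_area=10000.0)
        assert response_ratio(rec) == 0.5

    def test_zero_quant_area_gives_zero(self, panel):
        rec = make_record(panel["NDMA"], quant_area=0.0, confirm_area=0.0)
        assert response_ratio(rec) == 0.0

    def test_zero_istd_is_unquantifiable_not_an_exception(self, panel):
        rec = make_record(panel["NDMA"], istd_area=0.0)
        assert response_ratio(rec) is None


class TestFitCalibration:
    @pytest.mark.parametrize("weighting", list(Weighting))
    def test_exact_line_recovered_under_any_weighting(self, panel, weighting):
        xs = [0.004, 0.2, 0.4, 1.0]
        ys = [0.5 * x for x in xs]
        curve = fit_calibration(_cal_records(panel, xs, ys), weighting)
        assert curve.slope == pytest.approx(0.5, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert all(abs(r) < 1e-8 for r in curve.level_residuals.values())

    @pytest.mark.parametrize("weighting", list(Weighting))
    def test_noisy_fit_matches_normal_equations_oracle(self, panel, weighting):
        rng = np.random.default_rng(42)
        xs = np.geomspace(0.01, 2.0, 8)
        ys = 0.8 * xs * (1 + rng.normal(0, 0.03, xs.size)) + 0.002
        curve = fit_calibration(_cal_records(panel, xs, ys), weighting)
        if weighting is Weighting.NONE:
            w = np.ones_like(xs)
        elif weighting is Weighting.ONE_OVER_X:
            w = 1 / xs
        else:
            w = 1 / xs**2
        b0, b1 = wls_line_oracle(xs, ys, w)
        assert curve.intercept == pytest.approx(b0, abs=1e-12)
        assert curve.slope == pytest.approx(b1, abs=1e-12)

    def test_fewer_than_three_levels_is_an_error(self, panel):
        with pytest.raises(CalibrationError, match="3 distinct"):
            fit_calibration(_cal_records(panel, [0.1, 0.5], [0.1, 0.5]))

    def test_negative_slope_rejected_with_diagnostic(self, panel):
        xs = [0.1, 0.5, 1.0]
        ys = [1.0, 0.5, 0.1]
        with pytest.raises(CalibrationError, match="non-positive slope"):
            fit_calibration(_cal_records(panel, xs, ys))

    def test_weighted_schemes_require_positive_amount_ratios(self, panel):
        recs = _cal_records(panel, [0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        with pytest.raises(CalibrationError, match="positive"):
            fit_calibration(recs, Weighting.ONE_OVER_X)

    def test_noise_free_simulation_recovers_generating_line(
        self, noiseless_sim, layout, panel
    ):
        batch = generate_batch(noiseless_sim, layout)
        cal = [r for r in batch.records_for("NDEA") if r.role is Role.CALIBRANT]
        curve = fit_calibration(cal)
        assert curve.slope == pytest.approx(1.0, rel=1e-9)
        assert abs(curve.intercept) < 1e-9
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)


class TestQuantitate:
    def _curve(self, slope=1.0, intercept=0.0):
        return CalibrationCurve(
            analyte="NDMA", slope=slope, intercept=intercept,
            weighting=Weighting.NONE, r_squared=1.0, level_residuals={}, n_points=4,
        )

    def test_textbook_arithmetic(self, panel, constants):
        rec = make_record(panel["NDMA"], quant_area=0.2 * 2e5, istd_area=2e5)
        res = quantitate(rec, self._curve(), constants)
        assert res.raw_conc_pg_ml == pytest.approx(50.0)  # 0.2 * 500 / 2

    def test_response_at_intercept_gives_zero(self, panel, constants):
        rec = make_record(
            panel["NDMA"], quant_area=0.05 * 2e5, istd_area=2e5, confirm_area=1.0
        )
        res = quantitate(rec, self._curve(intercept=0.05), constants)
        assert res.raw_conc_pg_ml == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula_on_random_inputs(self, panel, constants):
        rng = np.random.default_rng(3)
        for _ in range(50):
            slope = rng.uniform(0.2, 2.0)
            intercept = rng.uniform(-0.02, 0.02)
            ratio = rng.uniform(0.01, 1.5)
            rec = make_record(panel["NDMA"], quant_area=ratio * 2e5, istd_area=2e5)
            res = quantitate(rec, self._curve(slope, intercept), constants)
            expected = (res.response_ratio - intercept) / slope * (500.0 / 2.0)
            assert res.raw_conc_pg_ml == expected

    def test_unquantifiable_record_flagged_without_conc(self, panel, constants):
        rec = make_record(panel["NDMA"], istd_area=0.0)
        res = quantitate(rec, self._curve(), constants)
        assert not res.quantifiable
        assert res.raw_conc_pg_ml is None


def _qr(analyte, sample_id, well, idx, role, raw):
    return QuantResult(
        sample_id=sample_id, well=well, analyte=analyte, injection_index=idx,
        role=role, quantifiable=True, response_ratio=raw / 250.0,
        raw_conc_pg_ml=raw,
    )


class TestBlankSubtract:
    def test_mean_of_two_blanks_subtracted(self, panel):
        results = [
            _qr("NDMA", "B1", "A1", 1, Role.DCM_BLANK, 1.8),
            _qr("NDMA", "S1", "A3", 2, Role.UNKNOWN, 52.0),
            _qr("NDMA", "B2", "F8", 3, Role.DCM_BLANK, 2.2),
        ]
        out = blank_subtract(results, panel)
        by_id = {r.sample_id: r for r in out}
        assert by_id["S1"].blank_sub_conc_pg_ml == pytest.approx(50.0)
        # blanks retain raw values for the run-rejection check
        assert by_id["B1"].blank_sub_conc_pg_ml == 1.8
        assert by_id["B2"].blank_sub_conc_pg_ml == 2.2

    def test_zero_blanks_are_identity(self, panel):
        results = [
            _qr("NMEA", "B1", "A1", 1, Role.DCM_BLANK, 0.0),
            _qr("NMEA", "S1", "A3", 2, Role.UNKNOWN, 12.5),
            _qr("NMEA", "B2", "F8", 3, Role.DCM_BLANK, 0.0),
        ]
        out = blank_subtract(results, panel)
        s1 = next(r for r in out if r.sample_id == "S1")
        assert s1.blank_sub_conc_pg_ml == 12.5

    def test_missing_blank_fails_the_batch(self, panel):
        from vnaflow.core import BatchError

        results = [
            _qr("NDMA", "B1", "A1", 1, Role.DCM_BLANK, 1.8),
            _qr("NDMA", "S1", "A3", 2, Role.UNKNOWN, 52.0),
        ]
        with pytest.raises(BatchError, match="2 DCM blank"):
            blank_subtract(results, panel)

    def test_negative_corrected_values_kept_and_flagged_below_lod(self, panel):
        results = [
            _qr("NDMA", "B1", "A1", 1, Role.DCM_BLANK, 10.0),
            _qr("NDMA", "S1", "A3", 2, Role.UNKNOWN, 4.0),
            _qr("NDMA", "B2", "F8", 3, Role.DCM_BLANK, 10.0),
        ]
        out = blank_subtract(results, panel)
        s1 = next(r for r in out if r.sample_id == "S1")
        assert s1.blank_sub_conc_pg_ml == pytest.approx(-6.0)
        assert s1.below_lod

    def test_conservation_raw_equals_sub_plus_mean(self, sim, layout, panel):
        batch = generate_batch(sim, layout)
        _, results = quantify_batch(batch)
        blank_mean = {}
        for r in results:
            if r.role is Role.DCM_BLANK:
                blank_mean.setdefault(r.analyte, []).append(r.raw_conc_pg_ml)
        blank_mean = {a: np.mean(v) for a, v in blank_mean.items()}
        for r in results:
            if r.role is not Role.DCM_BLANK and r.quantifiable:
                assert r.blank_sub_conc_pg_ml == r.raw_conc_pg_ml - blank_mean[r.analyte]
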