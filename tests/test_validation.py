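"""Detection limits, precision and spike-recovery statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vnaflow.quantify import CalibrationCurve, Weighting
from vnaflow.validation import (
    ValidationError,
    accuracy_summary,
    c4_correction,
    estimate_lod_3s0,
    estimate_lod_clsi,
    lod_3s0_from_sds,
    precision_summary,
    solution_accuracy_check,
)


class TestLod3S0:
    def test_exactly_linear_sd_profile(self):
        est = lod_3s0_from_sds([0.0, 2.5, 5.0, 7.5], [2.0, 2.1, 2.2, 2.3])
        assert est.s0 == pytest.approx(2.0, abs=1e-12)
        assert est.lod == pytest.approx(6.0, abs=1e-12)
        assert est.lod == 3 * est.s0

    def test_flat_sd_profile_gives_three_s(self):
        est = lod_3s0_from_sds([0.0, 2.5, 5.0, 7.5], [1.7] * 4)
        assert est.lod == pytest.approx(3 * 1.7)

    def test_decreasing_profile_advises_clsi(self):
        with pytest.raises(ValidationError, match="CLSI"):
            lod_3s0_from_sds([0.0, 2.5, 5.0, 7.5], [0.1, 0.2, 3.0, 6.0])

    def test_needs_three_pools_with_replicates(self):
        with pytest.raises(ValidationError, match=">= 3 pools"):
            estimate_lod_3s0({0.0: [1, 2], 2.5: [2, 3]})
        with pytest.raises(ValidationError, match=">= 2 values"):
            estimate_lod_3s0({0.0: [1.0], 2.5: [2, 3], 5.0: [3, 4]})

    def test_raw_value_path_reduces_to_sd_path(self):
        rng = np.random.default_rng(4)
        pools = {c: rng.normal(c, 2.0 + 0.02 * c, 60) for c in (0.0, 2.5, 5.0, 7.5)}
        est = estimate_lod_3s0(pools, bias_correct=False)
        sds = [np.std(pools[c], ddof=1) for c in (0.0, 2.5, 5.0, 7.5)]
        ref = lod_3s0_from_sds([0.0, 2.5, 5.0, 7.5], sds)
        assert est.lod == pytest.approx(ref.lod, rel=1e-12)

    def test_bias_correction_scales_by_c4(self):
        rng = np.random.default_rng(4)
        pools = {c: rng.normal(c, 2.0, 10) for c in (0.0, 2.5, 5.0, 7.5)}
        plain = estimate_lod_3s0(pools, bias_correct=False)
        corrected = estimate_lod_3s0(pools, bias_correct=True)
        assert corrected.lod == pytest.approx(plain.lod / c4_correction(10), rel=1e-12)


class TestLodClsi:
    def test_hand_arithmetic(self):
        # blanks: mean 1.0, sd 0.5; low pool sd 1.0
        est = estimate_lod_clsi([0.5, 1.0, 1.5], [1.0, 2.0, 3.0])
        assert est.lob == pytest.approx(1.0 + 1.645 * 0.5)
        assert est.lod == pytest.approx(1.8225 + 1.645 * 1.0)

    def test_zero_blanks_reduce_to_low_pool_term(self):
        est = estimate_lod_clsi([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert est.lob == 0.0
        assert est.lod == pytest.approx(1.645 * 1.0)

    def test_degenerate_quantile_returns_blank_mean(self):
        est = estimate_lod_clsi([1.0, 1.5], [1.0, 2.0], beta_quantile=0.0)
        assert est.lod == pytest.approx(1.25)

    def test_pooled_low_pools_by_degrees_of_freedom(self):
        est = estimate_lod_clsi(
            [0.0, 0.0, 0.0], {2.5: [1.0, 2.0, 3.0], 5.0: [4.0, 6.0, 8.0]}
        )
        pooled = np.sqrt((1.0**2 * 2 + 2.0**2 * 2) / 4)
        assert est.lod == pytest.approx(1.645 * pooled)

    def test_insufficient_data(self):
        with pytest.raises(ValidationError):
            estimate_lod_clsi([1.0], [1.0, 2.0])


class TestPrecision:
    def test_single_run_cv(self):
        summ = precision_summary({1: [48.0, 50.0, 52.0], 2: [50.0, 50.5, 49.5]})
        assert summ.intra_run_cv_pct[0] == pytest.approx(4.0)

    def test_identical_run_means_give_zero_inter_cv(self):
        summ = precision_summary({1: [49.0, 51.0], 2: [48.0, 52.0], 3: [50.0, 50.0]})
        assert summ.inter_run_cv_pct == pytest.approx(0.0)

    @given(
        st.floats(min_value=0.125, max_value=8.0),
    )
    def test_scale_invariance(self, k):
        runs = {1: [48.0, 50.0, 52.0], 2: [55.0, 54.0, 53.0], 3: [47.0, 49.0, 50.0]}
        base = precision_summary(runs)
        scaled = precision_summary({r: [k * v for v in vals] for r, vals in runs.items()})
        assert scaled.intra_run_cv_pct == pytest.approx(base.intra_run_cv_pct, rel=1e-9)
        assert scaled.inter_run_cv_pct == pytest.approx(base.inter_run_cv_pct, rel=1e-9)

    def test_zero_mean_is_undefined(self):
        with pytest.raises(ValidationError, match="zero mean"):
            precision_summary({1: [1.0, -1.0], 2: [2.0, 3.0]})

    def test_needs_replicates_and_runs(self):
        with pytest.raises(ValidationError, match=">= 2 runs"):
            precision_summary({1: [1.0, 2.0]})
        with pytest.raises(ValidationError, match=">= 2 replicates"):
            precision_summary({1: [1.0], 2: [1.0, 2.0]})


class TestAccuracy:
    def test_zero_baseline(self):
        out = accuracy_summary({100.0: [95.0, 95.0, 95.0]}, [])
        assert out[100.0].mean_recovery_pct == pytest.approx(95.0)

    def test_baseline_subtracted(self):
        out = accuracy_summary({100.0: [110.0, 110.0]}, [10.0, 10.0, 10.0])
        assert out[100.0].mean_recovery_pct == pytest.approx(100.0)

    def test_zero_nominal_rejected(self):
        with pytest.raises(ValidationError, match="non-zero"):
            accuracy_summary({0.0: [1.0, 2.0]}, [])

    def test_zero_noise_recovery_is_exactly_hundred(self, noiseless_sim):
        from vnaflow.simulate import generate_validation_study

        df = generate_validation_study("accuracy_matrix_3x3x3", noiseless_sim)
        for analyte, grp in df.groupby("analyte"):
            spiked = {
                float(s): g["measured_conc_pg_ml"].tolist()
                for s, g in grp[grp.spike_pg_ml > 0].groupby("spike_pg_ml")
            }
            baseline = grp[grp.spike_pg_ml == 0]["measured_conc_pg_ml"].tolist()
            for level in accuracy_summary(spiked, baseline, analyte).values():
                assert level.mean_recovery_pct == pytest.approx(100.0, abs=1e-9)


class TestSolutionAccuracy:
    CURVE = CalibrationCurve(
        analyte="NDMA", slope=1.0, intercept=0.0, weighting=Weighting.NONE,
        r_squared=1.0, level_residuals={}, n_points=8,
    )

    def test_matching_second_source_is_hundred_percent(self):
        levels = {0.4: [0.4] * 3, 20.0: [20.0] * 3, 40.0: [40.0] * 3}
        out = solution_accuracy_check(levels, self.CURVE)
        assert all(v.accuracy_pct == pytest.approx(100.0) for v in out.values())
        assert all(v.passed for v in out.values())

    def test_biased_second_source(self):
        out = solution_accuracy_check({0.4: [0.42] * 3}, self.CURVE)
        assert out[0.4].accuracy_pct == pytest.approx(105.0)

    def test_back_calculation_matches_direct_formula(self):
        curve = CalibrationCurve(
            analyte="NDMA", slope=0.8, intercept=0.01, weighting=Weighting.NONE,
            r_squared=1.0, level_residuals={}, n_points=8,
        )
        ratios = [0.33, 0.35, 0.34]
        out = solution_accuracy_check({0.4: ratios}, curve)
        expected = np.mean([(r - 0.01) / 0.8 / 0.4 * 100 for r in ratios])
        assert out[0.4].accuracy_pct == pytest.approx(expected, rel=1e-12)

    def test_missing_level_is_an_error(self):
        with pytest.raises(ValidationError, match="no replicate"):
            solution_accuracy_check({0.4: []}, self.CURVE)


def test_c4_correction_known_values():
    assert c4_correction(2) == pytest.approx(np.sqrt(2 / np.pi))
    assert c4_correction(60) == pytest.approx(1 - 1 / (4 * 59), abs=1e-4)
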