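"""Calibration fitting, LOD/LOQ rules and QC precision statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucagon_idms.quant import (
    CalibrationStandard,
    area_ratio,
    evaluate_lod,
    evaluate_loq,
    expected_infusate_conc,
    fit_calibration,
    inverse_predict,
    qc_precision,
)

FF_LADDER = (1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0)


def make_standards(concs, slope=0.02, intercept=0.0, noise=None, rng=None):
    out = []
    for c in concs:
        ratio = slope * c + intercept
        if noise is not None:
            ratio *= 1.0 + noise * rng.standard_normal()
        out.append(
            CalibrationStandard("FF", c, (ratio * 1e5,), (1e5,))
        )
    return out


class TestAreaRatio:
    @pytest.mark.parametrize(
        "a, b, expected", [(100, 100, 1.0), (50, 100, 0.5)]
    )
    def test_ratio(self, a, b, expected):
        assert area_ratio(a, b) == expected

    def test_zero_is_area_signals_failed_enrichment(self):
        with pytest.raises(ValueError, match="enrichment"):
            area_ratio(10, 0)


class TestFitCalibration:
    def test_noiseless_line_recovered_exactly(self):
        curve = fit_calibration(make_standards(FF_LADDER))
        assert curve.slope == pytest.approx(0.02, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-10)
        assert curve.r == pytest.approx(1.0, abs=1e-12)

    def test_low_noise_ladder_has_high_r(self):
        rng = np.random.default_rng(7)
        curve = fit_calibration(
            make_standards(FF_LADDER, noise=0.05, rng=rng)
        )
        assert curve.r > 0.99

    def test_weighting_changes_fit_on_heteroscedastic_data(self):
        rng = np.random.default_rng(11)
        standards = make_standards(FF_LADDER, noise=0.08, rng=rng)
        ols = fit_calibration(standards, weighting="none")
        wls = fit_calibration(standards, weighting="1/x2")
        assert ols.slope != wls.slope

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_calibration(make_standards((1.0, 2.0)))

    @given(
        slope=st.floats(1e-4, 10.0),
        intercept=st.floats(-0.5, 0.5),
        conc=st.floats(0.1, 500.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_inverse_predict_round_trip(self, slope, intercept, conc):
        """predict then invert recovers the concentration on any line."""
        curve = fit_calibration(
            make_standards((1.0, 10.0, 100.0), slope=slope, intercept=intercept)
        )
        ratio = curve.predict_ratio(conc)
        est = inverse_predict(curve, ratio)
        assert est.pg_ml == pytest.approx(conc, rel=1e-6, abs=1e-9)


class TestInversePredict:
    def test_known_curve(self):
        from glucagon_idms.quant import CalibrationCurve

        curve = CalibrationCurve("FF", 0.02, 0.0, 1.0, "none")
        assert inverse_predict(curve, 1.0).pg_ml == pytest.approx(50.0)
        assert inverse_predict(curve, 0.0).pg_ml == pytest.approx(0.0)

    def test_below_zero_flagged_not_clipped(self):
        from glucagon_idms.quant import CalibrationCurve

        curve = CalibrationCurve("FF", 0.02, 0.1, 1.0, "none")
        est = inverse_predict(curve, 0.05)
        assert est.pg_ml < 0
        assert est.below_zero


class TestLOD:
    def test_level_above_blank_and_snr_passes(self):
        result = evaluate_lod(
            levels={1.0: [0.2, 0.2, 0.2]},
            blank_replicates=[0.09, 0.10, 0.11],
            snr_values={1.0: [5.0, 6.0, 5.5]},
        )
        assert result.lod_pg_ml == 1.0

    def test_level_within_3sd_of_blank_fails(self):
        result = evaluate_lod(
            levels={1.0: [0.12, 0.12, 0.12]},
            blank_replicates=[0.09, 0.10, 0.11],
            snr_values={1.0: [5.0, 6.0, 5.5]},
        )
        assert result.lod_pg_ml is None

    def test_low_snr_fails_despite_signal(self):
        result = evaluate_lod(
            levels={1.0: [0.5, 0.5, 0.5]},
            blank_replicates=[0.09, 0.10, 0.11],
            snr_values={1.0: [2.0, 5.0, 5.0]},
        )
        assert not result.per_level.passes.iloc[0]

    def test_lod_is_lowest_passing_level_of_ladder(self):
        # Noise floor constructed so only levels >= 1.56 clear S/N 3.
        levels = {c: [0.02 * c] * 3 for c in (0.78, 1.56, 3.125, 6.25)}
        snr = {c: [c / 0.52] * 3 for c in levels}
        result = evaluate_lod(levels, [0.001, 0.0012, 0.0011], snr)
        assert result.lod_pg_ml == 1.56

    def test_missing_blanks_rejected(self):
        with pytest.raises(ValueError):
            evaluate_lod({1.0: [0.2]}, [0.1], {1.0: [5.0]})


class TestLOQ:
    def test_perfect_replicates_pass(self):
        result = evaluate_loq({10.0: (10.0, 10.0, 10.0)})
        assert result.loq_pg_ml == 10.0

    def test_high_cv_fails(self):
        # CV(5,10,15) = 50% > 25%
        result = evaluate_loq({10.0: (5.0, 10.0, 15.0)})
        assert result.loq_pg_ml is None
        assert result.per_level.cv_pct.iloc[0] == pytest.approx(50.0)

    def test_accuracy_failure(self):
        # mean 13 at nominal 10 -> RE 30% > 25%
        result = evaluate_loq({10.0: (13.0, 13.0, 13.0)})
        assert result.loq_pg_ml is None
        assert result.per_level.re_pct.iloc[0] == pytest.approx(30.0)

    def test_loq_monotone_under_added_noise(self):
        """Inflating every level's spread never lowers the LOQ."""
        rng = np.random.default_rng(3)
        base = {
            c: c * (1.0 + 0.05 * rng.standard_normal(3))
            for c in (1.56, 6.25, 25.0)
        }
        loq_low = evaluate_loq(base).loq_pg_ml
        inflated = {
            c: np.mean(v) + (v - np.mean(v)) * 8.0 for c, v in base.items()
        }
        loq_high = evaluate_loq(inflated).loq_pg_ml
        assert loq_low is not None
        assert loq_high is None or loq_high >= loq_low


class TestQCPrecision:
    def test_identical_values_zero_cv(self):
        qc = qc_precision({1: (10.0, 10.0), 2: (10.0, 10.0)}, "FF", 10.0)
        assert qc.intra_day_cv_pct == 0.0
        assert qc.inter_day_cv_pct == 0.0

    def test_between_day_shift_hand_value(self):
        # SD(10,10,20,20)/mean(15) = 5.7735/15 = 38.49%
        qc = qc_precision({1: (10.0, 10.0), 2: (20.0, 20.0)}, "FF", 15.0)
        assert qc.intra_day_cv_pct == 0.0
        assert qc.inter_day_cv_pct == pytest.approx(38.49, abs=0.01)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            qc_precision({1: (10.0, 11.0)}, "FF", 10.0)

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, scale):
        """CVs are unchanged when all measurements are rescaled."""
        base = {1: (9.0, 11.0, 10.0), 2: (12.0, 13.0, 11.0)}
        scaled = {d: tuple(v * scale for v in vals) for d, vals in base.items()}
        qc1 = qc_precision(base, "FF", 10.0)
        qc2 = qc_precision(scaled, "FF", 10.0 * scale)
        assert qc2.intra_day_cv_pct == pytest.approx(qc1.intra_day_cv_pct, rel=1e-9)
        assert qc2.inter_day_cv_pct == pytest.approx(qc1.inter_day_cv_pct, rel=1e-9)

    def test_anova_estimator_zero_when_day_means_equal(self):
        """With identical day means all spread is within-day: the
        variance-components between-day CV is floored at zero while the
        total CV still sees the replicate scatter."""
        batches = {1: (9.0, 11.0), 2: (9.0, 11.0), 3: (9.0, 11.0)}
        total = qc_precision(batches, "FF", 10.0).inter_day_cv_pct
        anova = qc_precision(
            batches, "FF", 10.0, inter_day_estimator="anova"
        ).inter_day_cv_pct
        assert anova == 0.0
        assert total > 0.0


class TestInfusateConc:
    def test_dilution_a(self):
        assert expected_infusate_conc(0.0465, 100) == pytest.approx(465.0)

    def test_dilution_ratio(self):
        a = expected_infusate_conc(0.0465, 500)
        b = expected_infusate_conc(0.0465, 2000)
        assert a / b == pytest.approx(4.0)

    def test_identity_dilution(self):
        assert expected_infusate_conc(0.05, 1) == pytest.approx(5.0e4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_infusate_conc(-1.0, 100)
        with pytest.raises(ValueError):
            expected_infusate_conc(0.05, 0.5)
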