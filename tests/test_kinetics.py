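"""Steele non-steady-state turnover and volume-of-distribution fitting."""

import numpy as np
import pytest

from glucagon_idms.kinetics import (
    InfusionProtocol,
    InfusionSegment,
    PlasmaTimeSeries,
    compute_ttr,
    endogenous_conc,
    fit_volume_of_distribution,
    rate_of_appearance,
    rate_of_disappearance,
)


class TestTTR:
    def test_bounds_and_simple_values(self):
        assert compute_ttr([5.0], [100.0])[0] == pytest.approx(0.05)
        assert compute_ttr([100.0], [100.0])[0] == pytest.approx(1.0)

    def test_tracee_denominator_mode(self):
        ttr = compute_ttr([5.0], [100.0], c_ffla=[5.0], denominator="tracee")
        assert ttr[0] == pytest.approx(5.0 / 90.0)

    def test_nonpositive_total_is_nan(self):
        ttr = compute_ttr([5.0, 5.0], [100.0, 0.0])
        assert np.isnan(ttr[1]) and not np.isnan(ttr[0])


class TestEndogenous:
    def test_subtraction_and_flags(self):
        series = PlasmaTimeSeries(
            time_min=[0.0, 1.0, 2.0],
            c_ff_pg_ml=[5.0, 6.0, 0.0],
            c_ffla_pg_ml=[5.0, 6.0, 0.0],
            c_total_pg_ml=[100.0, 10.0, 80.0],
        )
        c_endo, flags = endogenous_conc(series)
        assert c_endo == pytest.approx([90.0, -2.0, 80.0])
        assert flags.tolist() == [False, True, False]

    def test_missing_channel_rejected(self):
        series = PlasmaTimeSeries(time_min=[0.0, 1.0], c_ff_pg_ml=[1.0, 1.0])
        with pytest.raises(ValueError):
            endogenous_conc(series)


class TestRateOfAppearance:
    def test_steady_state_collapse(
        self, steady_state_series, dual_infusion_protocol
    ):
        """Constant TTR and C: Ra = F_FF/TTR - F_FF - F_FFLA exactly."""
        result = rate_of_appearance(
            dual_infusion_protocol, steady_state_series, vd_ml_kg=40.0
        )
        assert result.ra_pg_kg_min == pytest.approx(
            np.full(5, 1.0 / 0.05 - 2.0), abs=1e-9
        )

    def test_hand_computed_transient_interval(self):
        # TTR 0.05 -> 0.06 over 10 min, C = 100, Vd = 40, F_FF = 1:
        # Ra = 1/0.055 - 1 - 40*100*0.001/0.055 = -55.545...
        series = PlasmaTimeSeries(
            time_min=[0.0, 10.0],
            c_ff_pg_ml=[5.0, 6.0],
            c_ffla_pg_ml=[0.0, 0.0],
            c_total_pg_ml=[100.0, 100.0],
        )
        protocol = InfusionProtocol(
            f_ff=(InfusionSegment(0.0, 20.0, 1.0),), tbw_kg=70.0
        )
        result = rate_of_appearance(protocol, series, vd_ml_kg=40.0)
        expected = 1.0 / 0.055 - 1.0 - 40.0 * 100.0 * 0.001 / 0.055
        assert result.ra_pg_kg_min[0] == pytest.approx(expected, abs=1e-9)
        assert result.flags[0] == "negative_ra"

    def test_zero_tracer_with_nonzero_ttr_rejected(self, steady_state_series):
        protocol = InfusionProtocol(tbw_kg=70.0)  # no bolus, no infusion
        with pytest.raises(ValueError, match="inconsistent"):
            rate_of_appearance(protocol, steady_state_series, vd_ml_kg=40.0)

    def test_tracer_scale_invariance(self, steady_state_series):
        """Scaling the FF infusion and its steady-state plasma level
        together (total rising by the added tracer) leaves Ra unchanged:
        the estimate always returns the endogenous appearance rate."""
        base_protocol = InfusionProtocol(
            f_ff=(InfusionSegment(0.0, 100.0, 1.0),), tbw_kg=70.0
        )
        ra1 = rate_of_appearance(
            base_protocol, steady_state_series, vd_ml_kg=40.0
        ).ra_pg_kg_min
        scale = 3.0
        c_ff = steady_state_series.c_ff_pg_ml * scale
        scaled_series = PlasmaTimeSeries(
            time_min=steady_state_series.time_min,
            c_ff_pg_ml=c_ff,
            c_ffla_pg_ml=steady_state_series.c_ffla_pg_ml,
            # tracee pool is untouched; total gains the extra tracer mass
            c_total_pg_ml=steady_state_series.c_total_pg_ml
            + (scale - 1.0) * steady_state_series.c_ff_pg_ml,
        )
        scaled_protocol = InfusionProtocol(
            f_ff=(InfusionSegment(0.0, 100.0, scale),), tbw_kg=70.0
        )
        ra3 = rate_of_appearance(
            scaled_protocol, scaled_series, vd_ml_kg=40.0
        ).ra_pg_kg_min
        assert ra3 == pytest.approx(ra1, abs=1e-9)

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PlasmaTimeSeries(
                time_min=[0.0, 10.0, 5.0],
                c_ff_pg_ml=[5.0, 5.0, 5.0],
            )


class TestRateOfDisappearance:
    def test_steady_state_identity(
        self, steady_state_series, dual_infusion_protocol
    ):
        """At steady state Rd = F_FF/TTR exactly (Ra + F_FF + F_FFLA)."""
        ra = rate_of_appearance(
            dual_infusion_protocol, steady_state_series, vd_ml_kg=40.0
        )
        rd = rate_of_disappearance(
            ra, dual_infusion_protocol, steady_state_series, vd_ml_kg=40.0
        )
        assert rd.rd_pg_kg_min == pytest.approx(np.full(5, 20.0), abs=1e-9)

    def test_falling_concentration_hand_value(self):
        # C 100 -> 90 over 10 min, Vd 40: volume term adds +40 pg/kg/min.
        series = PlasmaTimeSeries(
            time_min=[0.0, 10.0],
            c_ff_pg_ml=[5.0, 4.5],  # constant TTR 0.05
            c_ffla_pg_ml=[0.0, 0.0],
            c_total_pg_ml=[100.0, 90.0],
        )
        protocol = InfusionProtocol(
            f_ff=(InfusionSegment(0.0, 20.0, 1.0),),
            f_ffla=(InfusionSegment(0.0, 20.0, 1.0),),
            tbw_kg=70.0,
        )
        ra = rate_of_appearance(protocol, series, vd_ml_kg=40.0)
        rd = rate_of_disappearance(ra, protocol, series, vd_ml_kg=40.0)
        assert rd.rd_pg_kg_min[0] == pytest.approx(
            ra.ra_pg_kg_min[0] + 2.0 + 40.0, abs=1e-9
        )

    def test_grid_mismatch_rejected(
        self, steady_state_series, dual_infusion_protocol
    ):
        ra = rate_of_appearance(
            dual_infusion_protocol, steady_state_series, vd_ml_kg=40.0
        )
        other = PlasmaTimeSeries(
            time_min=[0.0, 7.0, 30.0],
            c_ff_pg_ml=[5.0] * 3,
            c_ffla_pg_ml=[5.0] * 3,
            c_total_pg_ml=[100.0] * 3,
        )
        with pytest.raises(ValueError, match="grid"):
            rate_of_disappearance(
                ra, dual_infusion_protocol, other, vd_ml_kg=40.0
            )


class TestVdFit:
    def test_noiseless_exact_inversion(self):
        t = np.linspace(0, 30, 12)
        c = 2500.0 * np.exp(-0.1 * t)
        fit = fit_volume_of_distribution(7.0e6, t, c, tbw_kg=70.0)
        assert fit.c0_pg_ml == pytest.approx(2500.0, rel=1e-6)
        assert fit.k_elim_per_min == pytest.approx(0.1, rel=1e-6)
        assert fit.vd_ml_kg == pytest.approx(40.0, rel=1e-6)
        assert fit.half_life_min == pytest.approx(np.log(2) / 0.1, rel=1e-6)

    def test_noisy_recovery_near_truth(self):
        rng = np.random.default_rng(42)
        t = np.linspace(1, 50, 12)
        vds = []
        for _ in range(50):
            c = 250.0 * np.exp(-0.05 * t) * (
                1.0 + 0.10 * np.maximum(rng.standard_normal(12), -3)
            )
            fit = fit_volume_of_distribution(7.0e5, t, c, tbw_kg=70.0)
            vds.append(fit.vd_ml_kg)
        true_vd = 7.0e5 / 250.0 / 70.0
        assert abs(np.median(vds) - true_vd) / true_vd < 0.05

    def test_increasing_concentrations_fail(self):
        t = np.linspace(0, 30, 6)
        with pytest.raises(RuntimeError, match="decay"):
            fit_volume_of_distribution(1e6, t, 100.0 + 5.0 * t, tbw_kg=70.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_volume_of_distribution(1e6, [0, 1], [100, 90], tbw_kg=70.0)


class TestProtocol:
    def test_round_trip_json(self):
        protocol = InfusionProtocol(
            f_ff=(InfusionSegment(0.0, 100.0, 1.5),),
            f_ffla=(InfusionSegment(10.0, 200.0, 2.5),),
            bolus_pg=7.0e5,
            tbw_kg=82.0,
        )
        back = InfusionProtocol.from_json(protocol.to_json())
        assert back == protocol

    def test_missing_tbw_rejected(self):
        with pytest.raises(ValueError, match="tbw"):
            InfusionProtocol.from_json(
                '{"bolus_pg": 0, "f_ff": [], "f_ffla": []}'
            )

    def test_piecewise_rates(self):
        protocol = InfusionProtocol(
            f_ff=(
                InfusionSegment(0.0, 60.0, 2.0),
                InfusionSegment(60.0, 120.0, 1.0),
            ),
            tbw_kg=70.0,
        )
        assert protocol.f_ff_at([30.0, 60.0, 119.0, 120.0]) == pytest.approx(
            [2.0, 1.0, 1.0, 0.0]
        )
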