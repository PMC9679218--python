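"""Headspace/DIC accounting, calibration, units, withdrawal correction."""

import numpy as np
import pytest

from isofate.isotope import delta_to_atom_fraction
from isofate.mineralization import (
    CalibrationCurve,
    CalibrationError,
    RateEstimate,
    convert_rate,
    dic_bottle_umol,
    dic_excess_mg,
    gas_excess_mg,
    headspace_co2_umol,
    mineralization_rate,
    umol_to_ppm,
    withdrawal_corrected_total,
)
from isofate.recovery import recover_scenario
from isofate.simulate import get_scenario, simulate_gas_arrays


class TestCalibration:
    def test_line_through_standards(self):
        curve = CalibrationCurve.from_standards([1.0, 3.0], [10.0, 30.0])
        assert curve.predict(10.0) == pytest.approx(1.0)
        assert curve.predict(20.0) == pytest.approx(2.0)  # midway -> 2 umol

    def test_zero_intercept_zero_area(self):
        curve = CalibrationCurve(slope=0.5)
        assert curve.predict(0.0) == 0.0
        fitted = CalibrationCurve.from_standards([0.0, 4.0], [0.0, 8.0])
        assert fitted.predict(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_four_point_least_squares(self):
        amounts = np.array([1.0, 2.0, 4.0, 8.0])
        curve = CalibrationCurve.from_standards(amounts, amounts * 7.0)
        assert curve.predict(21.0) == pytest.approx(3.0)

    def test_negative_prediction_clamps(self):
        curve = CalibrationCurve(slope=1.0, intercept=-5.0)
        assert curve.predict(1.0) == 0.0

    def test_single_standard_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationCurve.from_standards([1.0], [1.0])


class TestHeadspacePool:
    def test_ideal_gas_reference_value(self):
        # 10,000 ppm in 240 mL at 18 C, 1 atm: n = 0.01 * 0.240 / (R * 291.15)
        n = headspace_co2_umol(10_000, 240.0, 18.0)
        assert n == pytest.approx(0.01 * 0.240 / (0.0820574 * 291.15) * 1e6, rel=1e-6)
        assert n == pytest.approx(100.4, abs=0.2)

    def test_zero_ppm_and_linearity(self):
        assert headspace_co2_umol(0.0, 240.0, 18.0) == 0.0
        assert headspace_co2_umol(500, 480.0, 18.0) == pytest.approx(
            2 * headspace_co2_umol(500, 240.0, 18.0)
        )

    def test_round_trip_with_ppm(self):
        assert umol_to_ppm(
            headspace_co2_umol(1234.0, 240.0, 17.5), 240.0, 17.5
        ) == pytest.approx(1234.0)

    def test_bad_geometry(self):
        with pytest.raises(ValueError):
            headspace_co2_umol(100, -1.0, 18.0)


class TestDicScaleup:
    def test_bottle_factor(self):
        # 1 umol in a 5 mL subsample of 300 mL water -> 60 umol in the bottle
        assert dic_bottle_umol(1.0, 5.0, 300.0) == pytest.approx(60.0)

    def test_identity_when_subsample_is_whole(self):
        assert dic_bottle_umol(7.0, 300.0, 300.0) == pytest.approx(7.0)

    def test_zero_subsample_rejected(self):
        with pytest.raises(ValueError):
            dic_bottle_umol(1.0, 0.0, 300.0)


class TestWithdrawalCorrection:
    def test_exact_recovery_of_simulated_withdrawals(self):
        # respire 0.1 mg into the headspace each week; 5/240 removed weekly
        w = 5.0 / 240.0
        pool, series = 0.0, []
        for _ in range(6):
            pool += 0.1
            series.append(pool)  # measured before withdrawal
            pool *= 1.0 - w
        total = withdrawal_corrected_total(np.array(series), 5.0, 240.0)
        assert total == pytest.approx(0.6, rel=1e-12)

    def test_uncorrected_underestimates(self):
        cfg = get_scenario("humic_leaf", sigma_delta=1e-6, co2_cv=1e-9, replicate_rate_cv=0.0)
        rng = np.random.default_rng(0)
        gas = simulate_gas_arrays(cfg, 1, rng)
        pool = headspace_co2_umol(gas["treatment_ppm"], cfg.headspace_ml, cfg.temperature_c)
        ctrl = gas["control_delta"].mean(axis=1, keepdims=True)
        kw = dict(withdrawn_ml=cfg.gas_sample_ml, headspace_ml=cfg.headspace_ml)
        corrected = gas_excess_mg(pool, gas["treatment_delta"], ctrl, cfg.x_source, **kw)
        raw = gas_excess_mg(
            pool, gas["treatment_delta"], ctrl, cfg.x_source, correct_withdrawals=False, **kw
        )
        truth_gas = gas["truth_mineralized_mg"] * cfg.f_gas
        assert np.all(corrected >= 0.99 * truth_gas)
        assert np.all(corrected <= 1.01 * truth_gas)
        assert np.all(raw < truth_gas)


class TestRateUnits:
    def test_forced_arithmetic_examples(self):
        from isofate.mineralization import MONTH_DAYS

        # 0.4 mg of 4 mg over one month -> 10 %/month -> 100 permil/month
        r = mineralization_rate(0.4, 4.0, MONTH_DAYS, unit="%/month")
        assert r.mean == pytest.approx(10.0)
        assert r.to("permil/month").mean == pytest.approx(100.0)

    def test_normalization_from_six_weeks(self):
        from isofate.mineralization import MONTH_DAYS

        r = mineralization_rate(0.84, 4.0, 42.0, unit="%/month")
        assert r.mean == pytest.approx(100 * 0.84 / 4 * MONTH_DAYS / 42)

    def test_unit_round_trip_closed(self):
        v = 9.0
        there = convert_rate(v, "%/month", "permil/year")
        assert convert_rate(there, "permil/year", "%/month") == pytest.approx(v, rel=1e-14)
        assert there == pytest.approx(9.0 * 10 * 12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mineralization_rate(0.1, 0.0, 30.0)
        with pytest.raises(ValueError):
            mineralization_rate(0.1, 4.0, 0.0)
        with pytest.raises(ValueError):
            convert_rate(1.0, "%/month", "furlong/fortnight")

    def test_below_detection_flag(self):
        assert RateEstimate([0.1, -0.2, 0.05]).below_detection
        assert not RateEstimate([5.0, 5.1, 4.9]).below_detection


def test_known_respired_mass_recovered():
    """A bottle built with known substrate-C respired returns that mass."""
    cfg = get_scenario("humic_leaf", replicate_rate_cv=0.0)
    rng = np.random.default_rng(5)
    gas = simulate_gas_arrays(cfg, 50, rng)
    pool = headspace_co2_umol(gas["treatment_ppm"], cfg.headspace_ml, cfg.temperature_c)
    x = delta_to_atom_fraction(gas["control_delta"])
    ctrl = gas["control_delta"].mean(axis=1, keepdims=True)
    excess = gas_excess_mg(
        pool, gas["treatment_delta"], ctrl, cfg.x_source,
        withdrawn_ml=cfg.gas_sample_ml, headspace_ml=cfg.headspace_ml,
    ) + dic_excess_mg(
        gas["treatment_dic_umol"], gas["treatment_dic_delta"],
        gas["control_dic_delta"].mean(axis=1, keepdims=True), cfg.x_source,
        subsample_ml=cfg.dic_subsample_ml, water_volume_ml=cfg.water_volume_ml,
    )
    truth = gas["truth_mineralized_mg"]
    assert excess.mean() == pytest.approx(truth.mean(), rel=0.02)


def test_control_equality_null_is_unbiased():
    """Treatment == control within noise -> mean rate 0 within 3 SE."""
    rec = recover_scenario(get_scenario("null"), n_experiments=200, seed=123)
    assert abs(rec.mineralization_grand_mean) <= 3 * rec.mineralization_se
    assert abs(rec.assimilation_grand_mean) <= 3 * rec.assimilation_se
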