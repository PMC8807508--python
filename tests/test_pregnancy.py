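import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gestpbpk.pregnancy import (
    MW_ALBUMIN,
    PlasmaBindingModel,
    TABLE_TRIMESTER,
    UGT1A4_CUBIC,
    cyp1a2_activity_change,
    cyp3a4_activity,
    fit_ugt1a4_cubic,
    fmo3_activity,
    fraction_unbound,
    pregnant_compound_params,
    ugt1a4_activity_change,
)
from gestpbpk.synthetic import generate_lamotrigine_points


@pytest.fixture(scope="module")
def binding():
    return PlasmaBindingModel.calibrate(0.07, calibration_FW=0.0)


class TestFractionUnbound:
    def test_calibration_identity(self, binding):
        assert fraction_unbound(0.0, binding) == pytest.approx(0.07, abs=1e-9)

    @pytest.mark.parametrize("fw,expected", [(6, 0.075), (20, 0.085),
                                             (34, 0.091)])
    def test_trimester_values(self, binding, fw, expected):
        assert fraction_unbound(fw, binding) == pytest.approx(expected,
                                                              abs=5e-4)

    @given(st.floats(min_value=0.0, max_value=60.0),
           st.floats(min_value=0.1, max_value=10.0))
    def test_strictly_increasing_and_bounded(self, binding, fw, step):
        lo, hi = fraction_unbound(fw, binding), fraction_unbound(fw + step,
                                                                 binding)
        asymptote = 1.0 / (1.0 + binding.KA * 31.7 / MW_ALBUMIN * 1e6)
        assert lo < hi < asymptote


class TestActivityTrajectories:
    def test_cyp1a2_decline(self):
        assert cyp1a2_activity_change(0.0) == 0.0
        assert cyp1a2_activity_change(20.0) == pytest.approx(-43.76)
        assert cyp1a2_activity_change(34.0) == pytest.approx(-60.54, abs=5e-3)

    def test_ugt1a4_induction_scales_clearance(self):
        assert ugt1a4_activity_change(0.0) == 0.0
        assert 20.06 * (1 + ugt1a4_activity_change(6.0) / 100) == \
            pytest.approx(28.24, abs=0.01)
        assert 20.06 * (1 + ugt1a4_activity_change(20.0) / 100) == \
            pytest.approx(35.04, abs=0.02)

    def test_cyp3a4_induction(self):
        assert cyp3a4_activity(0.0) == pytest.approx(1.00736)
        assert 0.82 * cyp3a4_activity(20.0) == pytest.approx(1.28, abs=0.01)
        assert 0.82 * cyp3a4_activity(34.0) == pytest.approx(1.64, abs=0.01)

    def test_fmo3_step(self):
        assert 4.05 * fmo3_activity(6.0) == pytest.approx(4.05)
        assert 4.05 * fmo3_activity(20.0) == pytest.approx(4.05)
        assert 4.05 * fmo3_activity(34.0) == pytest.approx(7.11)
        assert fmo3_activity(34.0, mode="literature") == pytest.approx(1.58)


class TestPregnantParameters:
    def test_canonical_third_trimester(self, olz):
        cp = pregnant_compound_params(olz, 34.0, mode="table2_canonical")
        assert cp.fu == 0.091
        assert cp.CLint == TABLE_TRIMESTER[34]["CLint"]

    def test_cyp2c8_never_changes(self, olz):
        for fw in (6.0, 20.0, 34.0):
            for mode in ("table2_canonical", "equation_generated"):
                cp = pregnant_compound_params(olz, fw, mode=mode)
                assert cp.CLint["CYP2C8"] == pytest.approx(2.14)

    def test_week_zero_is_baseline_except_cyp3a4(self, olz):
        for mode in ("table2_canonical", "equation_generated"):
            cp = pregnant_compound_params(olz, 0.0, mode=mode)
            assert cp.fu == pytest.approx(0.07, abs=1e-9)
            assert cp.CLint["CYP3A4"] == pytest.approx(0.82 * 1.00736)
            for enz in ("CYP1A2", "CYP2C8", "FMO3", "UGT1A4"):
                assert cp.CLint[enz] == pytest.approx(olz.CLint[enz])

    def test_canonical_fallback_warns_and_matches_equations(self, olz,
                                                            caplog):
        with caplog.at_level(logging.WARNING, logger="gestpbpk.pregnancy"):
            fallback = pregnant_compound_params(olz, 10.0,
                                                mode="table2_canonical")
        assert any("falling back" in r.message for r in caplog.records)
        equation = pregnant_compound_params(olz, 10.0,
                                            mode="equation_generated")
        assert fallback.CLint == equation.CLint

    def test_equation_mode_continuous(self, olz):
        grid = np.linspace(0.0, 38.0, 77)
        prev = None
        for fw in grid:
            cp = pregnant_compound_params(olz, fw, mode="equation_generated")
            vec = np.array([cp.fu] + sorted(cp.CLint.values()))
            if prev is not None and fw != 27.0:
                # FMO3 carries one documented step at the trimester-3 onset
                assert np.all(np.abs(vec - prev) < 2.0)
            prev = vec

    def test_total_intrinsic_clearance_change_below_20pct(self, olz):
        base = olz.total_CLint
        for fw in (6.0, 20.0, 34.0):
            cp = pregnant_compound_params(olz, fw, mode="table2_canonical")
            assert abs(cp.total_CLint - base) / base < 0.20


class TestCubicFit:
    def test_exact_recovery_from_noise_free_points(self):
        points = generate_lamotrigine_points(UGT1A4_CUBIC, noise_sd=0.0,
                                             seed=1)
        a = fit_ugt1a4_cubic(points)
        assert np.allclose(a, UGT1A4_CUBIC, atol=1e-6)

    def test_noisy_recovery_within_ci(self):
        # parameter-recovery study: 200 replicates, study-size weights
        devs = []
        for rep in range(200):
            pts = generate_lamotrigine_points(UGT1A4_CUBIC, noise_sd=8.0,
                                              seed=1000 + rep)
            devs.append(fit_ugt1a4_cubic(pts))
        mean = np.mean(devs, axis=0)
        se = np.std(devs, axis=0, ddof=1) / np.sqrt(len(devs))
        for est, true, s in zip(mean, UGT1A4_CUBIC, se):
            assert abs(est - true) < 4.0 * s + 1e-9

    def test_weights_change_the_fit(self):
        pts = generate_lamotrigine_points(UGT1A4_CUBIC, noise_sd=12.0, seed=7)
        unweighted = [(fw, y, 1.0) for fw, y, _ in pts]
        assert not np.allclose(fit_ugt1a4_cubic(pts),
                               fit_ugt1a4_cubic(unweighted))

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_ugt1a4_cubic([(5, 40, 7), (6, 45, 11), (7, 50, 53)])
        with pytest.raises(Exception):
            fit_ugt1a4_cubic([(5, 40, 7)] * 6)
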