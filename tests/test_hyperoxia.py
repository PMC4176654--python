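"""Gas-exchange model, York regression, and the Method III inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import veinphase as vp
from veinphase import BloodGasParams, MultiEchoSeries
from veinphase.models import HyperoxiaPhaseContrast
from veinphase.york import york_fit


class TestSeveringhaus:
    @pytest.mark.parametrize(
        "pao2, expected", [(110.0, 0.9829), (430.0, 0.9997), (500.0, 0.9998)]
    )
    def test_reference_values(self, pao2, expected):
        assert vp.severinghaus_sao2(pao2) == pytest.approx(expected, abs=5e-5)

    def test_saturates_towards_unity(self):
        assert vp.severinghaus_sao2(1e6) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing(self):
        pao2 = np.linspace(10, 600, 200)
        sao2 = vp.severinghaus_sao2(pao2)
        assert np.all(np.diff(sao2) > 0)
        assert np.all((sao2 > 0) & (sao2 < 1))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            vp.severinghaus_sao2(0.0)


class TestDeltaYh:
    def test_printed_protocol_value(self):
        blood = BloodGasParams(pao2_no=110.0, pao2_ho=430.0)
        assert vp.delta_yh(blood) == pytest.approx(0.066, abs=5e-4)

    def test_targeted_protocol_value(self):
        blood = BloodGasParams(pao2_no=110.0, pao2_ho=500.0)
        assert vp.delta_yh(blood) == pytest.approx(0.077, abs=5e-4)

    def test_no_challenge_no_change(self):
        assert vp.delta_yh(BloodGasParams(pao2_ho=110.0, pao2_no=110.0)) == 0.0

    def test_increasing_in_hyperoxic_po2_decreasing_in_hb(self):
        base = BloodGasParams()
        assert vp.delta_yh(base.replace(pao2_ho=600.0)) > vp.delta_yh(base)
        assert vp.delta_yh(base.replace(hb=17.0)) < vp.delta_yh(base)


class TestYorkFit:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = york_fit(x, 2 * x + 1, 1e-9, 1e-9)
        assert fit.slope_a == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept_k == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_reduces_to_weighted_ols_without_x_errors(self, rng):
        x = rng.uniform(-1, 1, 40)
        y = 1.7 * x + 0.3 + rng.normal(0, 0.1, 40)
        sy = rng.uniform(0.05, 0.3, 40)
        fit = york_fit(x, y, 1e-14, sy)
        # independent weighted-OLS closed form
        w = 1.0 / sy ** 2
        xb = (w @ x) / w.sum()
        yb = (w @ y) / w.sum()
        slope_wls = (w * (x - xb)) @ (y - yb) / ((w * (x - xb)) @ (x - xb))
        assert fit.slope_a == pytest.approx(slope_wls, abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(-2, 2, 30)
        y = -0.8 * x + 0.1 + rng.normal(0, 0.2, 30)
        sy = rng.uniform(0.1, 0.4, 30)
        fit = york_fit(x, y, 1e-14, sy)
        wls = sm.WLS(y, sm.add_constant(x), weights=1 / sy ** 2).fit()
        assert fit.slope_a == pytest.approx(wls.params[1], abs=1e-8)
        assert fit.intercept_k == pytest.approx(wls.params[0], abs=1e-8)

    def test_slope_invariant_to_constant_y_offset(self, rng):
        x = rng.uniform(-1, 1, 25)
        y = 0.8 * x + rng.normal(0, 0.05, 25)
        f1 = york_fit(x, y, 0.05, 0.05)
        f2 = york_fit(x, y + 3.21, 0.05, 0.05)
        assert f2.slope_a == pytest.approx(f1.slope_a, abs=1e-10)
        assert f2.intercept_k == pytest.approx(f1.intercept_k + 3.21, abs=1e-10)

    def test_axis_swap_gives_reciprocal_slope(self, rng):
        x = rng.uniform(0, 2, 30)
        y = 0.7 * x + rng.normal(0, 0.1, 30)
        sx = rng.uniform(0.05, 0.15, 30)
        sy = rng.uniform(0.05, 0.15, 30)
        f_xy = york_fit(x, y, sx, sy)
        f_yx = york_fit(y, x, sy, sx)
        assert f_xy.slope_a == pytest.approx(1.0 / f_yx.slope_a, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="x-variance"):
            york_fit([1.0, 1.0, 1.0], [1, 2, 3], 0.1, 0.1)
        with pytest.raises(ValueError, match="positive"):
            york_fit([1, 2, 3], [1, 2, 3], 0.0, 0.1)
        with pytest.raises(ValueError, match="3 points"):
            york_fit([1, 2], [1, 2], 0.1, 0.1)


class TestMethod3Inversion:
    def test_zero_saturation_limit(self):
        dyh = 0.066
        a = 1 - dyh / (1 - 0.0)
        assert vp.yv_from_slope(a, dyh) == pytest.approx(0.0, abs=1e-12)

    def test_forward_compose_then_invert(self):
        a = (1 - 0.66 - 0.066) / (1 - 0.66)
        assert a == pytest.approx(0.8059, abs=1e-4)
        assert vp.yv_from_slope(a, 0.066) == pytest.approx(0.66, abs=1e-12)

    @given(
        yv=st.floats(0.05, 0.9),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=100, deadline=None)
    def test_inversion_is_exact_for_all_feasible_pairs(self, yv, frac):
        dyh = frac * (1 - yv)
        a = vp.slope_from_yv(yv, dyh)
        assert vp.yv_from_slope(a, dyh) == pytest.approx(yv, abs=1e-10)


class TestFitVeins:
    def test_noiseless_phantom_round_trip(self, small_vein_bundle):
        spec, b = small_vein_bundle
        model = HyperoxiaPhaseContrast(
            b["phase_no"], b["phase_ho"], b["brain_mask"], spec.acq,
            blood=spec.blood,
            multi_echo=MultiEchoSeries(b["magnitudes"], b["tes"]),
            snr=1e6, filter_d=None, dyh=spec.dyh_true,
        )
        res = model.fit()
        assert len(res.veins) == 1
        assert res.veins.yv.iloc[0] == pytest.approx(spec.yv_true, abs=1e-6)
        assert res.veins.a.iloc[0] == pytest.approx(
            vp.slope_from_yv(spec.yv_true, spec.dyh_true), abs=1e-6
        )

    def test_degenerate_challenge_flags_all_veins_invalid(self, small_vein_bundle):
        spec, b = small_vein_bundle
        # identical phases: the fitted slope is exactly 1 -> invalid
        model = HyperoxiaPhaseContrast(
            b["phase_no"], b["phase_no"].copy(), b["brain_mask"], spec.acq,
            blood=spec.blood,
            multi_echo=MultiEchoSeries(b["magnitudes"], b["tes"]),
            snr=1e6, filter_d=None, dyh=0.066,
        )
        with pytest.warns(UserWarning, match="no valid veins"):
            res = model.fit()
        assert len(res.veins) == 1
        assert not res.veins.valid.any()
        assert np.isnan(res.mode)

    def test_small_rois_skipped(self, small_vein_bundle):
        spec, b = small_vein_bundle
        model = HyperoxiaPhaseContrast(
            b["phase_no"], b["phase_ho"], b["brain_mask"], spec.acq,
            blood=spec.blood,
            multi_echo=MultiEchoSeries(b["magnitudes"], b["tes"]),
            snr=1e6, filter_d=None, dyh=spec.dyh_true, min_points=10 ** 6,
        )
        with pytest.warns(UserWarning, match="no valid veins"):
            res = model.fit()
        assert len(res.veins) == 0


class TestWeightedMode:
    def test_voxel_weighting_moves_the_mode(self):
        yv = [0.505, 0.515, 0.705]
        assert vp.weighted_mode(yv, weights=[1, 1, 1]) == pytest.approx(0.51, abs=0.011)
        assert vp.weighted_mode(yv, weights=[1, 1, 10]) == pytest.approx(0.71, abs=0.011)

    def test_nan_values_ignored(self):
        assert vp.weighted_mode([0.605, np.nan, 0.605]) == pytest.approx(0.61, abs=0.011)
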