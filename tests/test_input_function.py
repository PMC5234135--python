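import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspoquant.errors import ModelError, ValidationError
from tspoquant.input_function import (
    BloodCurve,
    BloodPlasmaRatioModel,
    DispersionModel,
    ParentFractionModel,
    build_plasma_input,
    construct_input_function,
    dispersion_convolve,
    dispersion_correct,
    fit_blood_to_plasma,
    fit_hill_parent_fraction,
    merge_blood_samples,
)
from tspoquant.synthetic_data import simulate_input_function


def _smooth_test_curve(end_min=22.5, dt=1 / 60):
    """FEPPA-like bolus: linear rise then bi-exponential washout."""
    t = np.arange(0, end_min, dt)
    rise = np.clip(t / 0.6, 0, 1)
    decay = 0.75 * np.exp(-3.0 * np.clip(t - 0.6, 0, None)) + 0.25 * np.exp(
        -0.1 * np.clip(t - 0.6, 0, None)
    )
    return BloodCurve(t, 100.0 * np.where(t < 0.6, rise, decay))


class TestDispersion:
    def test_tau_zero_is_identity(self):
        c = _smooth_test_curve()
        out = dispersion_correct(c, DispersionModel(tau_s=0.0))
        np.testing.assert_array_equal(out.activity, c.activity)

    def test_step_recovery(self):
        t = np.arange(0, 22.5, 1 / 60)
        step = np.where(t >= 2.0, 10.0, 0.0)
        smeared = dispersion_convolve(BloodCurve(t, step), 16.0)
        rec = dispersion_correct(smeared, DispersionModel(16.0, smoothing_fwhm_s=0.0))
        rms = np.sqrt(np.mean((rec.activity - step) ** 2))
        assert rms < 0.01 * 10.0

    @pytest.mark.parametrize("tau_s", [4.0, 16.0, 30.0])
    def test_convolve_deconvolve_round_trip(self, tau_s):
        c = _smooth_test_curve()
        m = dispersion_convolve(c, tau_s)
        rec = dispersion_correct(m, DispersionModel(tau_s))
        back = dispersion_convolve(rec, tau_s)
        rms = np.sqrt(np.mean((back.activity - m.activity) ** 2))
        assert rms < 0.005 * m.activity.max()

    def test_rl_agrees_with_analytic_inverse(self):
        c = _smooth_test_curve()
        m = dispersion_convolve(c, 16.0)
        rl = dispersion_correct(m, DispersionModel(16.0, smoothing_fwhm_s=0.0))
        an = dispersion_correct(m, DispersionModel(16.0), method="analytic")
        # both recover the truth; compare away from the discretized peak
        sel = c.time > 2.0
        np.testing.assert_allclose(rl.activity[sel], an.activity[sel], rtol=0.02, atol=0.05)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValidationError):
            DispersionModel(tau_s=-1.0)


class TestBloodToPlasmaFit:
    def test_noise_free_recovery(self):
        t = np.linspace(1, 120, 12)
        truth = BloodPlasmaRatioModel(0.10, 0.05, 0.72, 0.001)
        fit = fit_blood_to_plasma(t, truth(t))
        grid = np.linspace(0.5, 125, 200)
        np.testing.assert_allclose(fit(grid), truth(grid), rtol=1e-4)

    def test_constant_ratio_predicts_constant(self):
        t = np.array([2.5, 7.0, 30.0, 90.0])
        fit = fit_blood_to_plasma(t, np.full(4, 1.2))
        np.testing.assert_allclose(fit(np.linspace(0, 120, 50)), 1.2, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_blood_to_plasma([1, 2, 3], [1.0, 1.0, 1.0])


class TestHillFit:
    def test_all_ones_means_no_metabolism(self):
        fit = fit_hill_parent_fraction([2.5, 7, 30, 90], [1.0, 1.0, 1.0, 1.0])
        assert fit.a == 0.0
        np.testing.assert_allclose(fit(np.linspace(0, 125, 20)), 1.0)

    def test_noise_free_recovery_of_prediction(self):
        truth = ParentFractionModel(0.9, 2.0, 400.0)
        t = np.array([2.5, 7, 12, 15, 30, 45, 60, 90, 120], float)
        fit = fit_hill_parent_fraction(t, truth(t))
        grid = np.linspace(0.0, 125.0, 251)
        np.testing.assert_allclose(fit(grid), truth(grid), atol=1e-3)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValidationError):
            fit_hill_parent_fraction([1, 2, 3, 4], [1.0, 0.9, 1.3, 0.5])

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.2, 6.0),
        st.floats(1.0, 5000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_hill_model_is_monotone_and_bounded(self, a, b, c):
        model = ParentFractionModel(a, b, c)
        t = np.linspace(0, 130, 500)
        f = model(t)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(np.diff(f) <= 1e-12)
        assert np.isclose(model(0.0), 1.0)


class TestMerge:
    def test_auto_only_within_support_and_error_beyond(self):
        auto = _smooth_test_curve()
        manual = BloodCurve(np.array([30.0, 45.0]), np.array([5.0, 3.0]), "manual")
        grid = np.arange(0, 20.0, 1 / 60)
        merged = merge_blood_samples(auto, manual, grid=grid, scale_to_manual=False)
        sel = grid > 1.0
        np.testing.assert_allclose(
            merged.activity[sel], np.interp(grid[sel], auto.time, auto.activity), rtol=0.02
        )
        with pytest.raises(ValidationError):
            merge_blood_samples(
                auto,
                BloodCurve(np.array([5.0]), np.array([50.0]), "manual"),
                grid=np.arange(0, 120, 1.0),
            )

    def test_scaling_matches_manual_at_overlap(self):
        auto = _smooth_test_curve()
        t_m = np.array([2.5, 30.0, 60.0, 90.0, 120.0])
        manual_act = 2.0 * np.interp(t_m, auto.time, auto.activity)  # sampler off by 2x
        manual = BloodCurve(t_m, manual_act, "manual")
        merged = merge_blood_samples(auto, manual)
        assert np.isclose(
            np.interp(2.5, merged.time, merged.activity), manual_act[0], rtol=0.02
        )

    def test_synthetic_schedule_reconstruction_within_5pct(self):
        truth, obs = simulate_input_function(seed=4)
        corrected = dispersion_correct(obs["auto"], DispersionModel(16.0))
        manual = BloodCurve(
            obs["manual"]["time_min"].to_numpy(),
            obs["manual"]["activity_kBq_ml"].to_numpy(),
            "manual",
        )
        merged = merge_blood_samples(corrected, manual)
        sel = (merged.time >= 1.0) & (merged.time <= 120.0)
        wb_true = truth.blood_at(merged.time[sel])
        rel = np.abs(merged.activity[sel] - wb_true) / wb_true
        assert rel.max() < 0.05


class TestBuildPlasmaInput:
    def test_identity_when_ratio_and_fraction_are_one(self):
        blood = _smooth_test_curve()
        pif = build_plasma_input(
            blood,
            BloodPlasmaRatioModel(1.0, 0.0, 0.0, 0.0),
            ParentFractionModel(0.0, 1.0, 1.0),
            grid=blood.time,
        )
        np.testing.assert_allclose(pif.cp, blood.activity, rtol=1e-12)

    def test_constant_half_parent_fraction_scales(self):
        blood = _smooth_test_curve()
        r = BloodPlasmaRatioModel(1.0, 0.0, 0.0, 0.0)
        full = build_plasma_input(blood, r, ParentFractionModel(0.0, 1.0, 1.0), blood.time)
        # a -> 0.5 with c -> 0 gives fp ~ 0.5 for t > 0
        half = build_plasma_input(blood, r, ParentFractionModel(0.5, 1.0, 1e-9), blood.time)
        np.testing.assert_allclose(half.cp[1:], 0.5 * full.cp[1:], rtol=1e-6)

    def test_nonpositive_ratio_rejected(self):
        blood = _smooth_test_curve()
        with pytest.raises(ModelError):
            build_plasma_input(
                blood,
                BloodPlasmaRatioModel(0.0, 0.0, 0.0, 0.0),
                ParentFractionModel(0.0, 1.0, 1.0),
                blood.time,
            )

    def test_metabolite_correction_only_removes_signal(self):
        truth, obs = simulate_input_function(seed=7)
        pif = construct_input_function(obs["auto"], obs["manual"])
        r = pif.components["b2p"](pif.time)
        assert np.all(pif.cp <= pif.whole_blood / r + 1e-9)

    def test_full_chain_recovers_parent_plasma_within_5pct(self):
        truth, obs = simulate_input_function(seed=1)
        pif = construct_input_function(obs["auto"], obs["manual"])
        sel = pif.time >= 1.0
        cp_true = truth.cp_at(pif.time[sel])
        rel = np.abs(pif.cp[sel] - cp_true) / np.maximum(cp_true, 1e-12)
        assert rel.max() < 0.05
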