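import numpy as np
import pandas as pd
import pytest

import serialbias as sb
from serialbias.dogcurve import DOG_NORM_C, dog, dog_basis, fit_dog_curve
from serialbias.dogmodel import DoGModel, add_derived_columns


class TestCurve:
    def test_odd_function(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-90, 90, 50)
        assert np.allclose(dog(-x, 1.5, 0.05), -dog(x, 1.5, 0.05))
        assert dog(0.0, 3.0, 0.1) == 0.0

    def test_peak_height_equals_alpha(self):
        # maximizing x*exp(-(wx)^2) gives x* = 1/(w*sqrt(2)); the
        # normalization makes the peak value equal alpha exactly
        for alpha, w in [(2.0, 0.05), (-1.3, 0.02), (0.7, 0.2)]:
            xpk = 1.0 / (w * np.sqrt(2.0))
            assert dog(xpk, alpha, w) == pytest.approx(alpha, rel=1e-12)
            xs = np.linspace(-90, 90, 20001)
            assert np.max(np.abs(dog(xs, alpha, w))) <= abs(alpha) + 1e-9

    def test_single_level_fit_recovers_parameters(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-60, 60, 4000)
        y = dog(x, 1.5, 0.06) + rng.normal(0, 1.0, 4000)
        a, w = fit_dog_curve(x, y)
        assert a == pytest.approx(1.5, abs=0.15)
        assert w == pytest.approx(0.06, abs=0.01)


class TestMultilevel:
    def test_recovery_and_width_band(self, exp1_behavior):
        res = DoGModel.from_dataframe(exp1_behavior).fit()
        assert res.alpha0 == pytest.approx(2.0, abs=1.96 * res.se_alpha0 + 0.2)
        # generating with w = 0.05; estimates should land in the empirical
        # band reported for behavioral fits (0.039 +- 0.018 around this scale)
        assert 0.02 <= res.w <= 0.09

    def test_negating_errors_negates_amplitude(self, exp1_behavior):
        res = DoGModel.from_dataframe(exp1_behavior).fit()
        flipped = exp1_behavior.copy()
        flipped["error"] = -flipped["error"]
        res2 = DoGModel(flipped["error"], flipped["delta_S"], flipped["subject"]).fit()
        assert res2.alpha0 == pytest.approx(-res.alpha0, abs=1e-6)
        assert res2.w == pytest.approx(res.w, abs=1e-6)

    def test_matches_statsmodels_mixedlm_at_fixed_width(self, exp1_behavior):
        """Dual-route check: at the profiled optimum w, the closed-form GLS
        must agree with statsmodels MixedLM on the linearized model."""
        import statsmodels.formula.api as smf

        res = DoGModel.from_dataframe(exp1_behavior).fit()
        df = exp1_behavior.dropna(subset=["error", "delta_S"]).copy()
        df["f"] = dog_basis(df["delta_S"].to_numpy(), res.w)
        m = smf.mixedlm("error ~ f - 1", df, groups=df["subject"],
                        re_formula="~ f - 1")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = m.fit(reml=False)
        assert res.alpha0 == pytest.approx(float(sm_fit.fe_params.iloc[0]), abs=1e-3)
        assert res.loglik == pytest.approx(float(sm_fit.llf), abs=0.05)

    def test_profile_equals_linear_mixed_fit_within_tolerance(self, exp1_behavior):
        # given w fixed, the model is linear in alpha: the profiled inner
        # solution must be the exact GLS optimum (gradient ~ 0)
        model = DoGModel.from_dataframe(exp1_behavior)
        res = model.fit()
        nll0 = model._neg_profile_ll(res.w, (res.sigma_u / res.sigma_e) ** 2 or 1e-12)[0]
        for dw in (-1e-4, 1e-4):
            assert model._neg_profile_ll(res.w + dw,
                                         (res.sigma_u / res.sigma_e) ** 2 or 1e-12)[0] >= nll0 - 1e-6


@pytest.fixture(scope="module")
def exp3_behavior():
    _, t = sb.generate_design("exp3", n_subjects=12, n_trials=500, seed=41)
    gt = sb.GroundTruth(alpha_true_per_subject=1.76, alpha_after_catch=-0.82,
                        w_true=0.05, sigma_noise=8.0)
    b = add_derived_columns(sb.generate_behavior(t, gt, seed=42))
    # condition: whether the previous trial was a response or a catch
    prev_catch = (b.groupby("subject")["condition"]
                   .shift(1).astype(str) == "catch")
    b["prev_response"] = (~prev_catch).astype(int)
    return b.dropna(subset=["error", "delta_S"])


class TestConditional:

    def test_opposite_amplitudes_recovered(self, exp3_behavior):
        fit = sb.ConditionalDoGModel(exp3_behavior["error"], exp3_behavior["delta_S"],
                                     exp3_behavior["subject"],
                                     exp3_behavior["prev_response"]).fit()
        # condition 1 = after response (attractive), 0 = after catch (repulsive)
        assert fit.k0 > 0 > fit.alpha0
        assert fit.p_diff < 1e-3
        assert fit.k0 == pytest.approx(1.76, abs=3 * fit.se_k0 + 0.1)
        assert fit.alpha0 == pytest.approx(-0.82, abs=3 * fit.se_alpha0 + 0.1)

    def test_z_test_matches_hand_computation(self, exp3_behavior):
        fit = sb.ConditionalDoGModel(exp3_behavior["error"], exp3_behavior["delta_S"],
                                     exp3_behavior["subject"],
                                     exp3_behavior["prev_response"]).fit()
        z = (fit.alpha0 - fit.k0) / np.sqrt(fit.se_alpha0 ** 2 + fit.se_k0 ** 2)
        assert fit.z_diff == pytest.approx(z, rel=1e-12)

    def test_identical_conditions_no_difference(self, null_behavior):
        df = null_behavior.dropna(subset=["error", "delta_S"]).copy()
        rng = np.random.default_rng(43)
        cond = rng.integers(0, 2, len(df))
        fit = sb.ConditionalDoGModel(df["error"], df["delta_S"], df["subject"], cond).fit()
        assert abs(fit.z_diff) < 3.0


class TestControls:
    def test_shuffle_null_p_matches_rank_computation(self, exp1_behavior):
        obs, draws, p = sb.shuffle_null_amplitude(exp1_behavior, "delta_S",
                                                  n=30, seed=1)
        hi = (1 + np.sum(draws >= obs)) / 31
        lo = (1 + np.sum(draws <= obs)) / 31
        assert p == pytest.approx(min(1.0, 2 * min(hi, lo)))

    def test_shuffle_destroys_true_dependence(self, exp1_behavior):
        obs, draws, p = sb.shuffle_null_amplitude(exp1_behavior, "delta_S",
                                                  n=30, seed=2)
        assert obs > 1.0
        assert abs(np.mean(draws)) < 0.5

    def test_future_control_nonsignificant_for_causal_generator(self, exp1_behavior):
        res = sb.future_trial_control(exp1_behavior, "delta_S")
        assert abs(res.alpha0) < 3 * res.se_alpha0 + 0.3

    def test_future_predictor_excludes_last_trial(self, exp1_behavior):
        fut = add_derived_columns(exp1_behavior.drop(
            columns=["error", "delta_S", "delta_R"]), future=True)
        last = fut.groupby("subject").tail(1)
        assert last["delta_S"].isna().all()


class TestRunningAverage:
    def test_constant_error_flat_curve_zero_se(self):
        df = pd.DataFrame({
            "subject": np.repeat([1, 2, 3], 100),
            "delta_S": np.tile(np.linspace(-80, 80, 100), 3),
            "error": 2.5,
        })
        curve = sb.running_average_curve(df)
        ok = curve.dropna(subset=["mean"])
        assert np.allclose(ok["mean"], 2.5)
        assert np.allclose(ok["se"], 0.0, atol=1e-12)

    def test_window_centers_step_one_degree(self):
        df = pd.DataFrame({"subject": [1] * 50, "delta_S": np.linspace(-80, 80, 50),
                           "error": 0.0})
        curve = sb.running_average_curve(df, window=15, overlap=14)
        steps = np.diff(curve["center"])
        assert np.allclose(steps, 1.0)

    def test_jackknife_matches_closed_form_three_subjects(self):
        # all three subjects contribute constant errors a, b, c in one window
        df = pd.DataFrame({"subject": [1, 2, 3], "delta_S": [0.0, 0.0, 0.0],
                           "error": [1.0, 2.0, 4.0]})
        curve = sb.running_average_curve(df, window=15, overlap=14)
        row = curve.iloc[(curve["center"] - 0).abs().idxmin()]
        vals = np.array([1.0, 2.0, 4.0])
        loo = np.array([(2 + 4) / 2, (1 + 4) / 2, (1 + 2) / 2])
        se = np.sqrt(2 / 3 * np.sum((loo - loo.mean()) ** 2))
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["se"] == pytest.approx(se, rel=1e-9)
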