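import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serialbias as sb
from serialbias.preprocessing import (chance_performance_test, clean_errors,
                                      demean_errors, filter_trials,
                                      grubbs_critical_value, grubbs_filter,
                                      residualize_orientation_bias,
                                      residualize_size_bias)


def _rt_table(rts, subject=1):
    n = len(rts)
    return pd.DataFrame({
        "subject": subject, "trial": np.arange(1, n + 1),
        "stimulus": np.linspace(0, 170, n) % 180,
        "response": np.linspace(0, 170, n) % 180,
        "rt_ms": rts,
    })


class TestFilterTrials:
    def test_fast_trial_and_successor_removed(self):
        t = _rt_table([2000.0] * 5 + [150.0] + [2000.0] * 5)
        out, rep = filter_trials(t)
        assert rep.n_removed_rt == 2
        assert 6 not in out["trial"].values and 7 not in out["trial"].values

    def test_clean_rts_untouched(self):
        t = _rt_table([2000.0] * 30)
        out, rep = filter_trials(t)
        assert len(out) == 30 and rep.n_removed_rt == 0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        rts = rng.lognormal(np.log(2000), 0.4, 200)
        rts[[10, 50]] = 100.0
        rts[120] = 60000.0
        t = _rt_table(rts)
        out, rep = filter_trials(t)

        # independent two-pass scan (single iteration to fixed point)
        kept = rts.copy()
        keep_idx = np.arange(200)
        while True:
            mu, sd = kept.mean(), kept.std(ddof=1)
            bad = (kept < 200) | (np.abs((kept - mu) / sd) > 3.5)
            bad_next = np.zeros_like(bad)
            bad_next[1:] = bad[:-1]
            drop = bad | bad_next
            if not drop.any():
                break
            keep_idx = keep_idx[~drop]
            kept = kept[~drop]
        assert np.array_equal(out["trial"].to_numpy(), keep_idx + 1)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rts = rng.lognormal(np.log(2000), 0.5, 300)
        rts[rng.choice(300, 5, replace=False)] = 120.0
        t = _rt_table(rts)
        once, _ = filter_trials(t)
        twice, rep = filter_trials(once)
        assert rep.n_removed_rt == 0
        assert len(twice) == len(once)

    def test_empty_after_filter_raises(self):
        t = _rt_table([100.0, 150.0, 120.0])
        with pytest.raises(ValueError):
            filter_trials(t)


class TestGrubbs:
    def test_known_outlier_removed(self):
        # G = 1.50 for {1,2,3,100} exceeds the n=4 critical value ~1.48
        kept = grubbs_filter([1.0, 2.0, 3.0, 100.0])
        assert list(kept) == [0, 1, 2]
        assert grubbs_critical_value(4) == pytest.approx(1.481, abs=0.01)

    def test_null_rarely_removes_points(self):
        rng = np.random.default_rng(2)
        removals = []
        for _ in range(200):
            x = rng.normal(0, 1, 60)
            removals.append(60 - len(grubbs_filter(x)))
        assert np.mean(np.array(removals) <= 1) >= 0.95

    def test_constant_data_untouched(self):
        assert len(grubbs_filter(np.full(10, 3.3))) == 10

    def test_short_series_pass_through_with_warning(self):
        with pytest.warns(UserWarning):
            kept = grubbs_filter([1.0, 2.0])
        assert len(kept) == 2


class TestCleanPipeline:
    def test_demeaning_removes_chronic_bias(self, exp1_behavior):
        out = demean_errors(exp1_behavior)
        means = out.groupby("subject")["error"].mean()
        assert np.allclose(means, 0.0, atol=1e-9)

    def test_fraction_removed_small_for_clean_generator(self, exp1_behavior):
        # uncontaminated log-normal RTs: only tail trials (and their
        # successors) go; the Grubbs stage finds next to nothing
        _, rep = clean_errors(exp1_behavior)
        assert 0.0 <= rep.fraction_removed < 0.06
        assert rep.n_removed_grubbs <= 0.005 * rep.n_total


@pytest.fixture(scope="module")
def biased_behavior():
    _, t = sb.generate_design("exp2", n_subjects=8, n_trials=400, seed=51)
    gt = sb.GroundTruth(alpha_true_per_subject=2.0, w_true=0.05,
                        sigma_noise=7.0,
                        bias_sinusoid=((4.0, 2.0, 0.3), (2.0, 5.0, 1.1),
                                       (1.0, 9.0, -0.5)))
    return sb.add_derived_columns(sb.generate_behavior(t, gt, seed=52))


class TestOrientationResidualization:

    def test_bias_from_same_family_removed(self, biased_behavior):
        pre_rms = biased_behavior.groupby("subject")["error"].std().mean()
        out, fits = residualize_orientation_bias(biased_behavior)
        post_rms = out.groupby("subject")["error"].std().mean()
        assert post_rms < pre_rms
        # the injected sinusoid amplitude (~4 deg rms) should be mostly gone
        assert post_rms < pre_rms - 0.5

    def test_zero_bias_data_nearly_unchanged(self, exp1_behavior):
        out, _ = residualize_orientation_bias(exp1_behavior)
        rms_change = np.nanstd(out["error"] - exp1_behavior["error"])
        assert rms_change < 2.0

    def test_refit_after_residualization_finds_nothing(self, biased_behavior):
        out, _ = residualize_orientation_bias(biased_behavior)
        _, fits2 = residualize_orientation_bias(out)
        rms2 = np.mean([f["rms"] for f in fits2.values() if np.isfinite(f["rms"])])
        resid_sd = out.groupby("subject")["error"].std().mean()
        assert rms2 == pytest.approx(resid_sd, rel=0.2)

    def test_spurious_delta_r_dependence_removed(self):
        # strong orientation bias, no true serial dependence: the shuffled
        # null detects a spurious delta-R amplitude before residualization
        # and none after
        _, t = sb.generate_design("exp2", n_subjects=6, n_trials=350, seed=61)
        gt = sb.GroundTruth(alpha_true_per_subject=0.0, w_true=0.05,
                            sigma_noise=5.0,
                            bias_sinusoid=((8.0, 2.0, 0.4), (4.0, 4.5, 1.0),
                                           (2.0, 8.0, 0.0)))
        b = sb.add_derived_columns(sb.generate_behavior(t, gt, seed=62))
        obs_pre, draws_pre, _ = sb.shuffle_null_amplitude(b, "delta_R", n=25, seed=63)
        assert np.mean(draws_pre) > 0.3  # spurious attraction in the null
        resid, _ = residualize_orientation_bias(b)
        obs_post, draws_post, _ = sb.shuffle_null_amplitude(resid, "delta_R",
                                                            n=25, seed=64)
        assert abs(np.mean(draws_post)) < 0.3


class TestSizeResidualization:
    def test_miscalibrated_slope_corrected(self):
        _, t = sb.generate_design("exp7", n_subjects=6, n_trials=300, seed=71)
        gt = sb.SizeGroundTruth(bias_slope=1.2, sigma_noise=0.2)
        b = sb.generate_size_behavior(t, gt, seed=72)
        out, fits = residualize_size_bias(b)
        slope = np.polyfit(out["stimulus"], out["response"], 1)[0]
        assert 0.97 <= slope <= 1.03

    def test_residuals_uncorrelated_with_size(self):
        rng = np.random.default_rng(73)
        n = 5000
        size = rng.uniform(0.5, 5.0, n)
        err = 0.3 * size + rng.normal(0, 0.3, n)
        t = pd.DataFrame({"subject": 1, "trial": np.arange(1, n + 1),
                          "stimulus": size, "response": size + err})
        out, _ = residualize_size_bias(t)
        r = np.corrcoef(out["stimulus"], out["error"])[0, 1]
        assert abs(r) < 0.05


class TestChancePerformance:
    def test_perfect_responses_minimal_p(self):
        t = pd.DataFrame({"subject": 1, "trial": np.arange(1, 51),
                          "stimulus": np.linspace(0.5, 5, 50),
                          "response": np.linspace(0.5, 5, 50)})
        p = chance_performance_test(t, n_perm=500, seed=0)
        assert p[1] <= 1 / 500 + 1e-9

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for k in range(60):
            t = pd.DataFrame({"subject": 1, "trial": np.arange(1, 41),
                              "stimulus": rng.uniform(0.5, 5, 40),
                              "response": rng.uniform(0.5, 5, 40)})
            ps.append(chance_performance_test(t, n_perm=200, seed=k)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_accurate_generator_subjects_beat_chance(self):
        _, t = sb.generate_design("exp7", n_subjects=4, n_trials=200, seed=81)
        b = sb.generate_size_behavior(t, sb.SizeGroundTruth(sigma_noise=0.1), seed=82)
        ps = chance_performance_test(b, n_perm=2000, seed=83)
        assert all(p < 0.001 for p in ps.values())
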