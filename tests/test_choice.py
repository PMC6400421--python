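import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serialbias as sb
from serialbias.choice import (baseline_delta_dprime, compute_sdt, criterion,
                               delta_p_vertical, dprime, fit_dprime_model,
                               fit_linear_mixed)


def _dual_task_table(seed=0, n_subjects=10, trials_per_cell=24,
                     dev_slope=0.05, snr_effect=0.0, congruent_shift=0.0):
    """Yes/No vertical-judgment trials with a known psychometric structure.

    P(say vertical) follows a normal-CDF psychometric curve whose
    sensitivity grows with |deviation| at ``dev_slope`` per degree, plus an
    optional SNR-dependent boost in the congruent condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subj_d0 = 0.8 + rng.normal(0, 0.1)
        for dev in (2, 5, 15, 40):
            for snr in (0.0, 25.0, 75.0):
                for cong in (True, False):
                    d = subj_d0 + dev_slope * dev
                    if cong:
                        d += snr_effect * snr + congruent_shift
                    for sign in (+1, -1):  # toward vertical / horizontal
                        p_yes = stats.norm.cdf((d / 2) * sign)
                        for _ in range(trials_per_cell // 2):
                            rows.append({
                                "subject": s + 1, "deviation": dev, "snr": snr,
                                "congruent": cong,
                                "signed_deviation": sign * dev,
                                "is_signal": sign > 0,
                                "said_yes": rng.random() < p_yes,
                            })
    return pd.DataFrame(rows)


class TestSDT:
    def test_dprime_from_rates(self):
        assert dprime(0.8, 0.2) == pytest.approx(2 * stats.norm.ppf(0.8), rel=1e-12)
        assert dprime(0.8, 0.2) == pytest.approx(1.683, abs=0.001)
        assert dprime(0.5, 0.5) == 0.0

    def test_antisymmetry_under_swap(self):
        assert dprime(0.9, 0.3) == pytest.approx(-dprime(0.3, 0.9))

    def test_extreme_rate_correction(self):
        df = pd.DataFrame({
            "subject": 1, "deviation": 5, "snr": 0.0, "congruent": True,
            "is_signal": [True] * 20 + [False] * 20,
            "said_yes": [True] * 20 + [False] * 20,
        })
        sdt = compute_sdt(df)
        cell = sdt.table.iloc[0]
        assert cell["hit_rate"] == pytest.approx(1 - 1 / 40)  # 0.975
        assert cell["fa_rate"] == pytest.approx(1 / 40)

    def test_incomplete_cells_flagged(self):
        df = pd.DataFrame({
            "subject": 1, "deviation": 5, "snr": 0.0, "congruent": True,
            "is_signal": [True] * 10, "said_yes": [True] * 10,
        })
        sdt = compute_sdt(df)
        assert sdt.table["incomplete"].all()


@pytest.fixture(scope="module")
def sdt():
    return compute_sdt(_dual_task_table(seed=1, snr_effect=0.004,
                                        trials_per_cell=60))


class TestDprimeModel:

    def test_deviation_slope_recovered(self, sdt):
        fit = fit_dprime_model(sdt, congruent=False)
        assert fit.params["deviation"] == pytest.approx(
            0.05, abs=3 * fit.bse["deviation"] + 0.01)

    def test_null_snr_effect_in_incongruent(self, sdt):
        fit = fit_dprime_model(sdt, congruent=False)
        assert fit.pvalues["snr"] > 0.01

    def test_snr_effect_detected_in_congruent(self, sdt):
        fit = fit_dprime_model(sdt, congruent=True)
        assert fit.params["snr"] > 0
        assert fit.pvalues["snr"] < 0.05


class TestBaselineDelta:
    def test_identical_conditions_no_shift(self):
        sdt = compute_sdt(_dual_task_table(seed=2, trials_per_cell=60))
        out = baseline_delta_dprime(sdt)
        assert np.allclose(out["mean"], 0.0, atol=0.15)

    def test_sign_pattern_attract_then_repel(self):
        # attraction after decision-only (0% SNR) lowers d', repulsion after
        # strong stimuli raises it
        sdt = compute_sdt(_dual_task_table(seed=3, snr_effect=0.006,
                                           congruent_shift=-0.25))
        out = baseline_delta_dprime(sdt).set_index("snr")
        assert out.loc[0.0, "mean"] < 0 < out.loc[75.0, "mean"]
        assert out.attrs["paired_p"] < 0.05

    def test_collapsing_matches_direct_cell_average(self):
        sdt = compute_sdt(_dual_task_table(seed=4))
        out = baseline_delta_dprime(sdt)
        df = sdt.table[~sdt.table["incomplete"]]
        base = df[~df["congruent"].astype(bool)].groupby("subject")["dprime"].mean()
        cong0 = (df[(df["congruent"].astype(bool)) & (df["snr"] == 0.0)]
                 .groupby("subject")["dprime"].mean())
        direct = (cong0 - base).mean()
        assert out.set_index("snr").loc[0.0, "mean"] == pytest.approx(direct, rel=1e-9)


class TestDeltaPVertical:
    def test_identical_conditions_flat_curve(self):
        t = _dual_task_table(seed=5)
        curve, fit = delta_p_vertical(t, snr_levels=(0.0, 75.0))
        assert abs(fit.alpha0) < 0.06 and abs(fit.k0) < 0.06

    def test_opposite_amplitudes_recovered(self):
        # congruent 0% SNR: more "vertical" after horizontal tilts
        # (attraction); congruent 75%: sharpened discrimination (repulsion)
        rng = np.random.default_rng(6)
        rows = []
        for s in range(12):
            for sign in (+1, -1):
                for dev in (2, 5, 15, 40):
                    sd = sign * dev
                    for snr, amp in ((0.0, 0.06), (75.0, -0.06), (25.0, 0.0)):
                        for cong in (True, False):
                            p = 0.5 + 0.01 * sd
                            if cong:
                                p -= amp * np.sign(sd) * np.exp(-(abs(sd) - 5) ** 2 / 200)
                            for _ in range(30):
                                rows.append({"subject": s + 1, "snr": snr,
                                             "congruent": cong,
                                             "signed_deviation": sd,
                                             "said_yes": rng.random() < p})
        t = pd.DataFrame(rows)
        curve, fit = delta_p_vertical(t, snr_levels=(0.0, 75.0))
        assert fit.alpha0 > 0 > fit.k0      # attraction vs repulsion
        assert fit.p_diff < 0.05


class TestLinearMixed:
    def test_reduces_to_ols_without_group_variance(self):
        rng = np.random.default_rng(7)
        n = 600
        x = rng.normal(size=n)
        y = 1.0 + 0.4 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"subject": np.repeat(np.arange(6), 100), "y": y, "x": x})
        fit = fit_linear_mixed(df, "y", ["x"])
        beta = np.polyfit(x, y, 1)
        assert fit.params["x"] == pytest.approx(beta[0], abs=0.02)

    def test_collinear_pair_rejected(self):
        df = pd.DataFrame({"subject": [1, 2], "y": [0, 1],
                           "delta_S": [0, 1], "delta_R": [0, 1]})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_mixed(df, "y", ["delta_S", "delta_R"])

    def test_zero_slope_generator_covers_zero(self):
        rng = np.random.default_rng(8)
        n = 800
        x = rng.normal(size=n)
        y = rng.normal(0, 1, n)
        df = pd.DataFrame({"subject": np.repeat(np.arange(8), 100), "y": y, "x": x})
        fit = fit_linear_mixed(df, "y", ["x"])
        assert abs(fit.params["x"]) < 3 * fit.bse["x"]
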