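"""Deciding between competing one-back predictor models (delta-S vs delta-R).

Four complementary procedures: a permutation test on the difference in fit
rmse, subject-stratified cross-validation of out-of-sample rmse, a
resampled dominance analysis of relative predictor importance in the linear
range, and AIC / likelihood-based comparison for the linear size models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dogmodel import DoGModel, add_derived_columns
from .dogcurve import dog
from .lmm import fit_random_intercept


@dataclass
class ComparisonReport:
    rmse_S: float = np.nan
    rmse_R: float = np.nan
    perm_p: float = np.nan
    cv_win_fraction: float = np.nan
    dominance_share: float = np.nan
    aic_S: float = np.nan
    aic_R: float = np.nan
    lrt_p: float = np.nan
    details: dict = field(default_factory=dict)

    @property
    def rmse_diff(self):
        return self.rmse_S - self.rmse_R

    def to_dict(self):
        return {
            "rmse_S": self.rmse_S, "rmse_R": self.rmse_R,
            "rmse_diff": self.rmse_diff, "perm_p": self.perm_p,
            "cv_win_fraction": self.cv_win_fraction,
            "dominance_share": self.dominance_share,
            "aic_S": self.aic_S, "aic_R": self.aic_R, "lrt_p": self.lrt_p,
        }


def _prepared(table):
    if "delta_S" not in table.columns or "error" not in table.columns:
        table = add_derived_columns(table)
    return table.dropna(subset=["error", "delta_S", "delta_R"]).reset_index(drop=True)


def rmse_permutation_test(table: pd.DataFrame, n: int = 1000,
                          seed: int | None = None,
                          predictors=("delta_S", "delta_R")):
    """Permutation test of rmse(model A) - rmse(model B).

    The observed difference comes from full multilevel DoG fits with each
    predictor.  The null distribution refits both models with each predictor
    column independently permuted within subject, removing any real
    predictor-error relationship while preserving marginals.  Returns
    ``(rmse_diff, perm_p, null_draws)`` with a two-sided exceedance p.
    """
    rng = np.random.default_rng(seed)
    df = _prepared(table)
    pa, pb = predictors
    obs = (DoGModel.from_dataframe(df, pa).fit().rmse
           - DoGModel.from_dataframe(df, pb).fit().rmse)
    null = np.empty(n)
    idx_by_subj = list(df.groupby("subject", sort=False).indices.values())
    xa = df[pa].to_numpy(float)
    xb = df[pb].to_numpy(float)
    for b in range(n):
        sa, sb = xa.copy(), xb.copy()
        for idx in idx_by_subj:
            sa[idx] = sa[rng.permutation(idx)]
            sb[idx] = sb[rng.permutation(idx)]
        fit_a = DoGModel(df["error"], sa, df["subject"]).fit()
        fit_b = DoGModel(df["error"], sb, df["subject"]).fit()
        null[b] = fit_a.rmse - fit_b.rmse
    hi = (1 + np.sum(null >= obs)) / (n + 1)
    lo = (1 + np.sum(null <= obs)) / (n + 1)
    return float(obs), float(min(1.0, 2.0 * min(hi, lo))), null


def cross_validate(table: pd.DataFrame, n: int = 1000, train_frac: float = 0.7,
                   seed: int | None = None, predictors=("delta_S", "delta_R")):
    """Subject-stratified train/test comparison of out-of-sample rmse.

    Each iteration splits every subject's trials ``train_frac``/rest, fits
    both predictor models on the train set, and scores test rmse using the
    fitted subject amplitudes.  Returns ``(win_fraction, diffs)`` where
    ``win_fraction`` is the share of iterations with rmse(A) > rmse(B),
    i.e. model B (delta-R by default) predicting better.
    """
    rng = np.random.default_rng(seed)
    df = _prepared(table)
    if df["subject"].nunique() < 2:
        raise ValueError("cross-validation requires at least 2 subjects")
    pa, pb = predictors
    idx_by_subj = list(df.groupby("subject", sort=False).indices.values())
    diffs = np.empty(n)
    y = df["error"].to_numpy(float)
    subj = df["subject"].to_numpy()
    cols = {p: df[p].to_numpy(float) for p in (pa, pb)}
    for b in range(n):
        train_mask = np.zeros(len(df), bool)
        for idx in idx_by_subj:
            perm = rng.permutation(idx)
            train_mask[perm[: int(round(train_frac * len(idx)))]] = True
        test = ~train_mask
        rmses = {}
        for p in (pa, pb):
            fit = DoGModel(y[train_mask], cols[p][train_mask], subj[train_mask]).fit()
            amp = fit.alpha_subject.reindex(subj[test]).to_numpy()
            pred = dog(cols[p][test], amp, fit.w)
            rmses[p] = np.sqrt(np.mean((y[test] - pred) ** 2))
        diffs[b] = rmses[pa] - rmses[pb]
    return float(np.mean(diffs > 0)), diffs


def dominance_analysis(table: pd.DataFrame, predictors=("delta_S", "delta_R"),
                       range_limit: float = 40.0, n: int = 10_000,
                       subsample: float = 0.75, seed: int | None = None):
    """Resampled two-predictor dominance analysis in the linear range.

    Restricts to trials with both predictors within ``+-range_limit`` (where
    the DoG is approximately linear), then repeatedly subsamples with
    subject stratification and computes general-dominance shares from
    marginal-R2 contributions of random-intercept mixed fits of the single-
    and two-predictor models.  Returns the distribution of
    ``share(B) - share(A)`` and the mean share of B.
    """
    rng = np.random.default_rng(seed)
    df = _prepared(table)
    pa, pb = predictors
    df = df[(df[pa].abs() <= range_limit) & (df[pb].abs() <= range_limit)]
    df = df.reset_index(drop=True)
    idx_by_subj = list(df.groupby("subject", sort=False).indices.values())
    y = df["error"].to_numpy(float)
    subj = df["subject"].to_numpy()
    xa = df[pa].to_numpy(float)
    xb = df[pb].to_numpy(float)
    ones = np.ones(len(df))
    diffs = []
    n_skipped = 0
    for b in range(n):
        take = np.concatenate([rng.permutation(idx)[: max(2, int(round(subsample * len(idx))))]
                               for idx in idx_by_subj])
        try:
            r2_a = fit_random_intercept(y[take], np.c_[ones[take], xa[take]], subj[take]).r2_marginal
            r2_b = fit_random_intercept(y[take], np.c_[ones[take], xb[take]], subj[take]).r2_marginal
            r2_ab = fit_random_intercept(y[take], np.c_[ones[take], xa[take], xb[take]],
                                         subj[take]).r2_marginal
        except np.linalg.LinAlgError:
            n_skipped += 1
            continue
        gd_a = 0.5 * r2_a + 0.5 * (r2_ab - r2_b)
        gd_b = 0.5 * r2_b + 0.5 * (r2_ab - r2_a)
        tot = gd_a + gd_b
        share_b = gd_b / tot if tot > 0 else 0.5
        diffs.append(share_b - (1.0 - share_b))
    diffs = np.asarray(diffs)
    share_b = float(0.5 * (1.0 + np.mean(diffs))) if len(diffs) else np.nan
    return share_b, diffs, n_skipped


def aic_lrt_compare(fit_a, fit_b):
    """AIC and likelihood comparison of two fits on identical data.

    For non-nested models with equal parameter counts the chi-square LRT
    degenerates, so alongside the raw likelihood-ratio statistic a
    Vuong-style standardized statistic is reported: per-observation Gaussian
    log-density differences of the conditional residuals, standardized by
    their sd.  Returns a dict with aic_a, aic_b, lrt, vuong_z, p.
    """
    ra = np.asarray(fit_a.resid, float)
    rb = np.asarray(fit_b.resid, float)
    if len(ra) != len(rb):
        raise ValueError("fits must be computed on identical rows")
    lrt = 2.0 * (fit_b.loglik - fit_a.loglik)
    la = stats.norm.logpdf(ra, scale=max(fit_a.sigma_e, 1e-12))
    lb = stats.norm.logpdf(rb, scale=max(fit_b.sigma_e, 1e-12))
    d = lb - la
    sd = d.std(ddof=1)
    vuong = float(np.sqrt(len(d)) * d.mean() / sd) if sd > 0 else 0.0
    return {
        "aic_a": float(fit_a.aic), "aic_b": float(fit_b.aic),
        "lrt": float(lrt), "vuong_z": vuong,
        "p": float(2.0 * stats.norm.sf(abs(vuong))),
    }
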