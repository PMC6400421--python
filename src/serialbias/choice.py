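"""Signal-detection and linear mixed-effects analyses for forced-choice and
size-adjustment tasks.

The dual-task design presents a near-threshold discrimination followed by a
vertical/horizontal judgment whose tilt deviates from a diagonal by signed
offsets (positive toward vertical).  Responses are recoded as Yes/No
"vertical" to give hit and false-alarm rates per Deviation x SNR x
Congruency cell, corrected for extreme rates, from which d' and the
criterion c follow.  d' cells feed a random-intercept linear model with
Deviation, SNR and their interaction; raw "vertical"-proportion differences
between congruency conditions are fitted with the conditional DoG.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .dogmodel import ConditionalDoGModel


@dataclass
class SDTResult:
    """Per-cell rates and indices; ``table`` has one row per cell."""

    table: pd.DataFrame

    def cells(self, **filters):
        t = self.table
        for k, v in filters.items():
            t = t[t[k] == v]
        return t


def _correct_rate(k, n):
    """Hit/FA rate with the 1/(2N) correction for extreme rates."""
    rate = k / n
    rate = np.where(rate <= 0, 1.0 / (2.0 * n), rate)
    rate = np.where(rate >= 1, 1.0 - 1.0 / (2.0 * n), rate)
    return rate


def dprime(hit_rate, fa_rate):
    return stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate)


def criterion(hit_rate, fa_rate):
    return -0.5 * (stats.norm.ppf(hit_rate) + stats.norm.ppf(fa_rate))


def compute_sdt(table: pd.DataFrame,
                cell_cols=("subject", "deviation", "snr", "congruent")) -> SDTResult:
    """Hit/FA rates, d' and criterion per cell.

    Expects boolean-like columns ``is_signal`` (tilt toward vertical) and
    ``said_yes`` (responded "vertical"), with ``deviation`` the absolute
    off-diagonal tilt.  Cells lacking signal or noise trials are flagged
    ``incomplete`` and excluded from downstream fits.
    """
    rows = []
    for key, grp in table.groupby(list(cell_cols), sort=True):
        sig = grp[grp["is_signal"].astype(bool)]
        noi = grp[~grp["is_signal"].astype(bool)]
        row = dict(zip(cell_cols, key))
        row["n_signal"] = len(sig)
        row["n_noise"] = len(noi)
        if len(sig) == 0 or len(noi) == 0:
            row.update(hit_rate=np.nan, fa_rate=np.nan, dprime=np.nan,
                       criterion=np.nan, incomplete=True)
        else:
            h = float(_correct_rate(sig["said_yes"].sum(), len(sig)))
            f = float(_correct_rate(noi["said_yes"].sum(), len(noi)))
            row.update(hit_rate=h, fa_rate=f, dprime=float(dprime(h, f)),
                       criterion=float(criterion(h, f)), incomplete=False)
        rows.append(row)
    return SDTResult(pd.DataFrame(rows))


@dataclass
class LinearMixedFit:
    """Slim wrapper over a fitted random-intercept MixedLM."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    nobs: int
    resid: np.ndarray
    sigma_e: float
    converged: bool

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def aic(self):
        k = len(self.params) + 2
        return 2.0 * k - 2.0 * self.loglik


def fit_linear_mixed(table: pd.DataFrame, response: str, predictors,
                     group_col: str = "subject") -> LinearMixedFit:
    """Random-intercept linear mixed model via ML.

    Rejects the collinear pair delta_S/delta_R in one model (they are fitted
    separately and compared instead).
    """
    preds = list(predictors)
    if {"delta_S", "delta_R"} <= set(preds):
        raise ValueError("delta_S and delta_R are collinear; fit them in separate models")
    df = table.dropna(subset=[response, *preds, group_col]).copy()
    formula = f"{response} ~ " + " + ".join(preds) if preds else f"{response} ~ 1"
    model = smf.mixedlm(formula, df, groups=df[group_col])
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=False, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            raise RuntimeError("mixed-model fit failed with all optimizers")
        try:
            resid = np.asarray(fit.resid, float)
        except ValueError:
            # singular random-effect covariance (variance ~ 0): fall back to
            # marginal residuals
            resid = np.asarray(df[response], float) - np.asarray(fit.predict(df), float)
    return LinearMixedFit(
        params=fit.fe_params, bse=fit.bse_fe, pvalues=fit.pvalues[fit.fe_params.index],
        loglik=float(fit.llf), nobs=int(fit.nobs),
        resid=resid, sigma_e=float(np.sqrt(fit.scale)),
        converged=bool(fit.converged),
    )


def fit_dprime_model(sdt: SDTResult, congruent: bool) -> LinearMixedFit:
    """Fixed effects of Deviation, SNR and their interaction on d'.

    One congruency condition at a time, random subject intercept.
    """
    df = sdt.table
    df = df[(df["congruent"] == congruent) & ~df["incomplete"]].copy()
    df["dev_x_snr"] = df["deviation"] * df["snr"]
    return fit_linear_mixed(df, "dprime", ["deviation", "snr", "dev_x_snr"])


def baseline_delta_dprime(sdt: SDTResult) -> pd.DataFrame:
    """Congruent d' per SNR relative to the incongruent baseline.

    Baseline = each subject's mean d' over all SNR and Deviation levels in
    the incongruent condition; the congruent condition is collapsed over
    Deviation within each SNR.  Includes a paired t-test across subjects
    between the lowest and highest SNR.
    """
    df = sdt.table[~sdt.table["incomplete"]]
    base = (df[~df["congruent"].astype(bool)]
            .groupby("subject")["dprime"].mean().rename("baseline"))
    cong = (df[df["congruent"].astype(bool)]
            .groupby(["subject", "snr"])["dprime"].mean().rename("dprime").reset_index())
    cong = cong.join(base, on="subject")
    cong["delta_dprime"] = cong["dprime"] - cong["baseline"]
    out = (cong.groupby("snr")["delta_dprime"]
           .agg(["mean", "sem", "count"]).reset_index())
    snrs = sorted(out["snr"])
    lo = cong[cong["snr"] == snrs[0]].set_index("subject")["delta_dprime"]
    hi = cong[cong["snr"] == snrs[-1]].set_index("subject")["delta_dprime"]
    common = lo.index.intersection(hi.index)
    if len(common) > 1:
        t, p = stats.ttest_rel(hi.loc[common], lo.loc[common])
        out.attrs["paired_t"] = float(t)
        out.attrs["paired_p"] = float(p)
    return out


def delta_p_vertical(table: pd.DataFrame, snr_levels=(0.0, 0.75)):
    """Incongruent-minus-congruent proportion of "vertical" per signed tilt,
    fitted with the conditional DoG across the two SNR levels of interest.

    Expects columns subject, signed_deviation, snr, congruent, said_yes.
    Returns ``(curve_frame, ConditionalDoGResults)`` where condition 1 is
    the higher SNR level.
    """
    df = table.copy()
    prop = (df.groupby(["subject", "snr", "congruent", "signed_deviation"])["said_yes"]
            .mean().rename("p_vertical").reset_index())
    inc = prop[~prop["congruent"].astype(bool)].groupby(
        ["subject", "signed_deviation"])["p_vertical"].mean().rename("p_incongruent")
    rows = []
    for snr in snr_levels:
        con = prop[(prop["congruent"].astype(bool)) & (prop["snr"] == snr)]
        con = con.join(inc, on=["subject", "signed_deviation"])
        con = con.assign(delta_p=con["p_incongruent"] - con["p_vertical"], snr=snr)
        rows.append(con)
    curve = pd.concat(rows, ignore_index=True).dropna(subset=["delta_p"])
    cond = (curve["snr"] == snr_levels[1]).astype(int)
    fit = ConditionalDoGModel(curve["delta_p"], curve["signed_deviation"],
                              curve["subject"], cond).fit()
    return curve, fit
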