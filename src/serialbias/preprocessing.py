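"""Data conditioning before model fitting.

Order of operations mirrors standard practice for adjustment tasks: wrap
errors to +-90 deg, drop trials with unrealistic or outlying reaction times
(plus the trial immediately following each, whose history is contaminated),
demean each subject's errors to remove chronic clockwise/counterclockwise
bias, apply an iterative Grubbs outlier test per subject, and residualize
stimulus-dependent response biases (sinusoidal over orientation, linear over
size) so they cannot masquerade as serial dependence on delta-R.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .circular import wrap_delta, wrap_orientation
from .dogmodel import add_derived_columns


@dataclass
class CleaningReport:
    n_removed_rt: int = 0
    n_removed_grubbs: int = 0
    n_total: int = 0
    per_subject_mean_error: dict = field(default_factory=dict)
    residualization: dict = field(default_factory=dict)

    @property
    def fraction_removed(self) -> float:
        if self.n_total == 0:
            return 0.0
        return (self.n_removed_rt + self.n_removed_grubbs) / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_removed_rt": self.n_removed_rt,
            "n_removed_grubbs": self.n_removed_grubbs,
            "n_total": self.n_total,
            "fraction_removed": self.fraction_removed,
            "per_subject_mean_error": self.per_subject_mean_error,
            "residualization": self.residualization,
        }


def filter_trials(table: pd.DataFrame, min_rt_ms: float = 200.0,
                  z_thresh: float = 3.5):
    """Drop trials with RT < 200 ms or |z(RT)| > 3.5 (per subject), and the
    trial immediately following each dropped trial.

    Iterated to a fixed point so the filter is idempotent.  Catch trials
    (NaN RT) are never themselves removed but do count as "following"
    trials.  Raises if a subject would lose all trials.
    """
    if "rt_ms" not in table.columns:
        raise ValueError("rt_ms column required for trial filtering")
    out = table.copy()
    total_removed = 0
    while True:
        drop = np.zeros(len(out), bool)
        rt = out["rt_ms"].to_numpy(float)
        for _, idx in out.groupby("subject", sort=False).indices.items():
            r = rt[idx]
            finite = np.isfinite(r)
            mu = r[finite].mean() if finite.any() else np.nan
            sd = r[finite].std(ddof=1) if finite.sum() > 1 else 0.0
            bad = finite & (r < min_rt_ms)
            if sd > 0:
                bad |= finite & (np.abs((r - mu) / sd) > z_thresh)
            bad_next = np.zeros(len(idx), bool)
            bad_next[1:] = bad[:-1]
            drop[idx] = bad | bad_next
        if not drop.any():
            break
        total_removed += int(drop.sum())
        out = out.loc[~drop]
        if out.empty or out.groupby("subject").size().min() == 0:
            raise ValueError("reaction-time filtering removed all trials of a subject")
    report = CleaningReport(n_removed_rt=total_removed, n_total=len(table))
    return out.reset_index(drop=True), report


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value via the t-distribution formula."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(values, alpha: float = 0.05):
    """Iterative two-sided Grubbs test; returns indices of kept observations.

    With fewer than 3 observations, or zero variance, everything is kept
    (pass-through with a warning in the former case).
    """
    x = np.asarray(values, float)
    keep = np.arange(len(x))
    if len(x) < 3:
        warnings.warn("Grubbs test skipped: fewer than 3 observations", stacklevel=2)
        return keep
    while len(keep) >= 3:
        v = x[keep]
        sd = v.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(v - v.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(len(keep), alpha):
            keep = np.delete(keep, i)
        else:
            break
    return keep


def demean_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's mean error (chronic bias) from its errors."""
    out = table if "error" in table.columns else add_derived_columns(table)
    out = out.copy()
    means = out.groupby("subject")["error"].transform("mean")
    out["error"] = out["error"] - means
    return out


def clean_errors(table: pd.DataFrame, alpha: float = 0.05,
                 rt_filter: bool = True):
    """Full outlier pipeline: RT filter, demeaning, per-subject Grubbs.

    Returns the cleaned table (with an ``error`` column) and a report.
    """
    report = CleaningReport(n_total=len(table))
    out = table
    if rt_filter and "rt_ms" in table.columns:
        out, rt_rep = filter_trials(table)
        report.n_removed_rt = rt_rep.n_removed_rt
    out = add_derived_columns(out)
    report.per_subject_mean_error = (
        out.dropna(subset=["error"]).groupby("subject")["error"].mean().to_dict()
    )
    out = demean_errors(out)
    keep_mask = np.ones(len(out), bool)
    err = out["error"].to_numpy(float)
    for _, idx in out.groupby("subject", sort=False).indices.items():
        finite = np.isfinite(err[idx])
        sub_idx = idx[finite]
        if len(sub_idx) >= 3:
            kept = grubbs_filter(err[sub_idx], alpha)
            removed = np.setdiff1d(np.arange(len(sub_idx)), kept)
            keep_mask[sub_idx[removed]] = False
    report.n_removed_grubbs = int((~keep_mask).sum())
    return out.loc[keep_mask].reset_index(drop=True), report


# -- orientation bias residualization -----------------------------------------

def _sum_of_sinusoids(theta_n, params):
    a = params[0::3]
    b = params[1::3]
    c = params[2::3]
    return np.sum([ai * np.sin(bi * theta_n + ci) for ai, bi, ci in zip(a, b, c)],
                  axis=0)


def _fit_sinusoids(theta_n, err, n_components=3, outlier_weight=0.1):
    """Robust sum-of-three-sinusoids fit with FFT-seeded multistart.

    Points beyond +-3 SD of the error mean are down-weighted to 0.1, then a
    bounded trust-region least-squares refines (a_k, b_k, c_k).
    """
    w = np.ones_like(err)
    sd = err.std()
    if sd > 0:
        w[np.abs(err - err.mean()) > 3.0 * sd] = outlier_weight
    sw = np.sqrt(w)

    # seed frequencies from dominant FFT components of binned means
    order = np.argsort(theta_n)
    nb = min(32, max(8, len(err) // 8))
    bins = np.array_split(order, nb)
    bm = np.array([err[b].mean() for b in bins if len(b)])
    bx = np.array([theta_n[b].mean() for b in bins if len(b)])
    span = bx.max() - bx.min() if len(bx) > 1 else 1.0
    spec = np.abs(np.fft.rfft(bm - bm.mean()))
    freqs_cyc = np.fft.rfftfreq(len(bm), d=span / max(len(bm) - 1, 1))
    top = freqs_cyc[1 + np.argsort(spec[1:])[::-1][:n_components]] if len(spec) > 1 else []
    seeds = [max(2.0 * np.pi * f, 0.2) for f in top]
    while len(seeds) < n_components:
        seeds.append(1.0 + len(seeds))

    def residual(p):
        return sw * (err - _sum_of_sinusoids(theta_n, p))

    best = None
    amp0 = max(err.std(), 1e-3)
    for scale in (1.0, 0.5):
        p0 = []
        for k in range(n_components):
            p0 += [amp0, seeds[k] * scale, 0.0]
        try:
            res = optimize.least_squares(residual, np.asarray(p0), max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("sinusoid fit did not converge")
    return best.x, float(np.sqrt(np.mean((err - _sum_of_sinusoids(theta_n, best.x)) ** 2)))


def residualize_orientation_bias(table: pd.DataFrame, n_components: int = 3):
    """Remove each subject's orientation-dependent response bias.

    Fits ``error(theta) = sum_k a_k sin(b_k theta' + c_k)`` per subject on
    centered/scaled orientation ``theta'``, with robust down-weighting of
    points beyond +-3 SD, subtracts the fitted curve, and rebuilds the
    response and delta-R columns from the residual errors.  Falls back to a
    fourth-degree polynomial (with a logged downgrade) on non-convergence.
    """
    out = table.copy() if "error" in table.columns else add_derived_columns(table)
    fits = {}
    err = out["error"].to_numpy(float).copy()
    stim = out["stimulus"].to_numpy(float)
    for subject, idx in out.groupby("subject", sort=False).indices.items():
        finite = np.isfinite(err[idx])
        sub = idx[finite]
        if len(sub) < 12:
            fits[subject] = {"family": "none", "rms": np.nan}
            continue
        th = stim[sub]
        th_n = (th - th.mean()) / (th.std() or 1.0)
        e = err[sub]
        try:
            params, rms = _fit_sinusoids(th_n, e, n_components)
            pred = _sum_of_sinusoids(th_n, params)
            fits[subject] = {"family": "sin3", "params": params.tolist(), "rms": rms}
        except RuntimeError:
            coefs = np.polyfit(th_n, e, deg=4)
            pred = np.polyval(coefs, th_n)
            rms = float(np.sqrt(np.mean((e - pred) ** 2)))
            fits[subject] = {"family": "poly4", "params": coefs.tolist(), "rms": rms,
                             "downgraded": True}
            warnings.warn(f"subject {subject!r}: sinusoid fit failed, "
                          "fell back to fourth-degree polynomial", stacklevel=2)
        err[sub] = e - pred
    out["error"] = err
    out["response"] = np.where(np.isfinite(err),
                               wrap_orientation(stim + err), np.nan)
    # delta_R must reflect the residualized responses
    out = add_derived_columns(out.drop(columns=["delta_S", "delta_R"], errors="ignore"))
    out["error"] = err
    return out, fits


def residualize_size_bias(table: pd.DataFrame):
    """Remove per-subject linear size-dependent bias from size errors.

    Fits ``error = b0 + b1 * size`` per subject and subtracts it; afterwards
    the report-vs-truth slope is ~1 and residual errors are uncorrelated
    with stimulus size by construction.
    """
    out = table.copy()
    if "error" not in out.columns:
        out["error"] = out["response"] - out["stimulus"]
    err = out["error"].to_numpy(float).copy()
    stim = out["stimulus"].to_numpy(float)
    fits = {}
    for subject, idx in out.groupby("subject", sort=False).indices.items():
        finite = np.isfinite(err[idx])
        sub = idx[finite]
        if len(sub) < 3:
            fits[subject] = {"slope": np.nan, "intercept": np.nan}
            continue
        b1, b0 = np.polyfit(stim[sub], err[sub], 1)
        err[sub] = err[sub] - (b0 + b1 * stim[sub])
        fits[subject] = {"slope": float(b1), "intercept": float(b0)}
    out["error"] = err
    out["response"] = np.where(np.isfinite(err), stim + err, np.nan)
    return out, fits


def chance_performance_test(table: pd.DataFrame, n_perm: int = 10_000,
                            seed: int | None = None, circular: bool = False):
    """Empirical test of above-chance accuracy per subject.

    Pairs each response with the target of a randomly chosen trial ``n_perm``
    times; p is the fraction of permuted mean-absolute-errors at or below
    the observed one.  Small p = precision better than chance.
    """
    rng = np.random.default_rng(seed)
    pvals = {}
    for subject, grp in table.groupby("subject", sort=False):
        ok = grp.dropna(subset=["response", "stimulus"])
        resp = ok["response"].to_numpy(float)
        stim = ok["stimulus"].to_numpy(float)
        diff = wrap_delta(resp, stim) if circular else resp - stim
        obs = np.mean(np.abs(diff))
        perm = np.empty(n_perm)
        for b in range(n_perm):
            tgt = stim[rng.integers(0, len(stim), size=len(stim))]
            d = wrap_delta(resp, tgt) if circular else resp - tgt
            perm[b] = np.mean(np.abs(d))
        pvals[subject] = float((1 + np.sum(perm <= obs)) / (n_perm + 1))
    return pvals
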