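"""Synthetic trial designs and behavior with known ground truth.

Emulates the trial structures of eight orientation- and size-adjustment
experiments (orientation grids, constrained stimulus walks, catch-trial
proportions, stimulus sequences, contrast levels, dot ensembles) and
generates responses with a known derivative-of-Gaussian serial-dependence
term, an optional orientation-dependent sinusoidal response bias, and
Gaussian report noise — so every downstream fitting and comparison stage is
testable without human data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap_delta, wrap_orientation
from .dogcurve import dog
from .tables import dump_sequence, parse_sequence, validate_trial_table


class DesignError(ValueError):
    """Raised when a trial design constraint cannot be satisfied."""


@dataclass
class ExperimentDesign:
    """Declarative description of one experiment's trial structure."""

    experiment_id: str
    n_subjects: int
    n_trials_per_subject: int
    orientation_grid: np.ndarray | None = None
    delta_range: float = 0.0        # max |delta-S| between consecutive stimuli
    delta_step: float = 0.0
    catch_fraction: float = 0.0
    n_blocks: int = 4
    sequence_length: int = 0        # stimuli per trial (sequence experiments)
    contrast_levels: tuple = ()
    ensemble_means: tuple = ()      # size experiments: mean diameters (deg)
    n_dots: int = 0                 # size working-memory experiment
    size_levels: np.ndarray | None = None
    seed: int = 0


_DEFAULTS = {
    # orientation adjustment, peripheral; 4 x 140 trials, grid 0..170 step 10,
    # consecutive-stimulus differences on +-50 step 10
    "exp1": dict(n_subjects=10, n_trials_per_subject=560, grid_step=10.0,
                 delta_range=50.0, delta_step=10.0, n_blocks=4),
    # foveal variant: 1-degree grid, continuous-like delta on +-80 step 1
    "exp2": dict(n_subjects=10, n_trials_per_subject=440, grid_step=1.0,
                 delta_range=80.0, delta_step=1.0, n_blocks=4),
    # 40% catch trials; grid 0..165 step 15, delta +-60 step 15
    "exp3": dict(n_subjects=15, n_trials_per_subject=600, grid_step=15.0,
                 delta_range=60.0, delta_step=15.0, catch_fraction=0.40, n_blocks=4),
    # sequences of six 200-ms stimuli, 20% catch (truncated sequences);
    # grid 0..160 step 20, within-sequence delta +-80 step 20
    "exp5": dict(n_subjects=15, n_trials_per_subject=284, grid_step=20.0,
                 delta_range=80.0, delta_step=20.0, catch_fraction=0.20,
                 sequence_length=6, n_blocks=4),
    # exp3 response trials with randomized low/high Michelson contrast
    "exp6": dict(n_subjects=15, n_trials_per_subject=400, grid_step=15.0,
                 delta_range=60.0, delta_step=15.0,
                 contrast_levels=(0.25, 0.75), n_blocks=5),
    # ensemble coding: mean diameter of 16 dots
    "exp7": dict(n_subjects=15, n_trials_per_subject=480,
                 ensemble_means=(0.75, 0.945, 1.19, 1.5), n_blocks=4),
    # size working memory with retro-cue; 2 (default) or 4 dots, diameters on
    # 50 linearly spaced values in [0.5, 5] deg
    "exp8": dict(n_subjects=15, n_trials_per_subject=400, n_dots=2, n_blocks=4),
}


def make_design(experiment_id: str, n_subjects: int | None = None,
                n_trials: int | None = None, seed: int = 0,
                n_dots: int | None = None) -> ExperimentDesign:
    """Build the default :class:`ExperimentDesign` for an experiment."""
    if experiment_id not in _DEFAULTS:
        raise DesignError(f"unsupported experiment: {experiment_id!r}")
    d = _DEFAULTS[experiment_id]
    design = ExperimentDesign(
        experiment_id=experiment_id,
        n_subjects=n_subjects or d["n_subjects"],
        n_trials_per_subject=n_trials or d["n_trials_per_subject"],
        delta_range=d.get("delta_range", 0.0),
        delta_step=d.get("delta_step", 0.0),
        catch_fraction=d.get("catch_fraction", 0.0),
        n_blocks=d.get("n_blocks", 4),
        sequence_length=d.get("sequence_length", 0),
        contrast_levels=d.get("contrast_levels", ()),
        ensemble_means=d.get("ensemble_means", ()),
        n_dots=n_dots if n_dots is not None else d.get("n_dots", 0),
        seed=seed,
    )
    if "grid_step" in d:
        design.orientation_grid = np.arange(0.0, 180.0, d["grid_step"])
    if experiment_id == "exp8":
        design.size_levels = np.linspace(0.5, 5.0, 50)
        if design.n_dots not in (2, 4):
            raise DesignError("exp8 uses 2 or 4 dots")
    return design


def _delta_grid(design: ExperimentDesign) -> np.ndarray:
    return np.arange(-design.delta_range, design.delta_range + 0.5 * design.delta_step,
                     design.delta_step)


def _orientation_walk(n: int, design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Constrained random walk on the orientation grid.

    A balanced multiset of consecutive-stimulus differences from the declared
    delta grid is shuffled and integrated, so every wrapped consecutive
    difference lies on the grid by construction while the levels stay
    (near-)balanced, as in the original pseudorandom designs.
    """
    grid = design.orientation_grid
    step = grid[1] - grid[0] if len(grid) > 1 else 180.0
    if design.delta_step % step != 0:
        raise DesignError(
            f"delta step {design.delta_step} incompatible with orientation grid step {step}: "
            "the stimulus walk would leave the grid"
        )
    deltas = _delta_grid(design)
    reps = np.tile(deltas, (n - 1) // len(deltas) + 1)[: n - 1]
    rng.shuffle(reps)
    theta = np.empty(n)
    theta[0] = rng.choice(grid)
    # delta-S is previous minus present, so the walk subtracts each delta
    theta[1:] = wrap_orientation(theta[0] - np.cumsum(reps))
    return theta


def generate_design(experiment_id: str, n_subjects: int | None = None,
                    n_trials: int | None = None, seed: int = 0,
                    n_dots: int | None = None):
    """Generate an experiment design and its stimulus-only trial table.

    Deterministic under a fixed seed.  Returns ``(design, table)``.
    """
    design = make_design(experiment_id, n_subjects, n_trials, seed, n_dots)
    rng = np.random.default_rng(seed)
    rows = []
    n = design.n_trials_per_subject
    block_size = max(1, n // design.n_blocks)
    for s in range(design.n_subjects):
        if design.experiment_id == "exp7":
            stims = rng.choice(design.ensemble_means, size=n)
        elif design.experiment_id == "exp8":
            dots = rng.choice(design.size_levels, size=(n, design.n_dots))
            cue = rng.integers(0, design.n_dots, size=n)
            stims = dots[np.arange(n), cue]
        else:
            stims = _orientation_walk(n, design, rng)
        catch = np.zeros(n, bool)
        if design.catch_fraction > 0:
            n_catch = int(round(design.catch_fraction * n))
            catch[rng.choice(n, size=n_catch, replace=False)] = True
        contrasts = (rng.choice(design.contrast_levels, size=n)
                     if design.contrast_levels else np.full(n, np.nan))
        for t in range(n):
            row = {
                "subject": s + 1,
                "block": t // block_size + 1,
                "trial": t + 1,
                "experiment": design.experiment_id,
                "stimulus": stims[t],
                "condition": "catch" if catch[t] else "response",
                "contrast": contrasts[t],
            }
            if design.sequence_length:
                seq = _sequence_for(stims, t, design, rng, catch[t])
                row["sequence_json"] = dump_sequence(seq)
                row["stimulus"] = seq[-1]
                stims[t] = seq[-1]
            if design.experiment_id == "exp8":
                comp = np.delete(dots[t], cue[t])
                row["competitor_sizes_json"] = dump_sequence(comp)
            rows.append(row)
    table = pd.DataFrame(rows)
    validate_trial_table(table, orientation=design.experiment_id not in ("exp7", "exp8"))
    return design, table


def _sequence_for(stims, t, design, rng, is_catch):
    """Within-trial stimulus sequence ending at the tabled orientation.

    Catch trials truncate the sequence at a random position before the last
    item, mirroring the attention checks of the sequence experiment.
    """
    length = design.sequence_length
    if is_catch:
        length = int(rng.integers(1, design.sequence_length))
    deltas = _delta_grid(design)
    seq = np.empty(length)
    seq[0] = stims[t] if length == 1 else rng.choice(design.orientation_grid)
    for k in range(1, length):
        seq[k] = wrap_orientation(seq[k - 1] - rng.choice(deltas))
    if not is_catch:
        # re-anchor the walk so it ends at the tabled to-be-reported stimulus
        shift = stims[t] - seq[-1]
        seq = wrap_orientation(seq + shift)
    return seq


@dataclass
class GroundTruth:
    """Generating parameters for synthetic orientation behavior."""

    alpha_true_per_subject: np.ndarray | float = 2.0   # DoG amplitude (deg)
    w_true: float = 0.05                                # DoG inverse width (1/deg)
    bias_sinusoid: tuple = ()    # triplets (a_k, b_k, c_k) on normalized theta
    sigma_noise: float = 10.0                           # report noise SD (deg)
    predictor: str = "delta_S"                          # "delta_S" | "delta_R"
    alpha_after_catch: float | None = None  # amplitude when trial n-1 was a catch
    rt_median_s: float = 2.2
    rt_sigma: float = 0.5
    rt_contaminant_fraction: float = 0.0

    def __post_init__(self):
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be > 0")
        if not 0.0 < self.w_true < 1.0:
            raise ValueError("w_true must be in (0, 1)")
        if self.predictor not in ("delta_S", "delta_R"):
            raise ValueError(f"unknown predictor {self.predictor!r}")


def _rt_ms(n, gt: GroundTruth, rng) -> np.ndarray:
    rt = rng.lognormal(np.log(gt.rt_median_s * 1000.0), gt.rt_sigma, size=n)
    if gt.rt_contaminant_fraction > 0:
        bad = rng.random(n) < gt.rt_contaminant_fraction
        fast = rng.random(n) < 0.5
        rt = np.where(bad & fast, rng.uniform(50.0, 190.0, size=n), rt)
        rt = np.where(bad & ~fast, rt + 20_000.0, rt)
    return rt


def generate_behavior(table: pd.DataFrame, ground_truth: GroundTruth,
                      seed: int = 0) -> pd.DataFrame:
    """Add responses and reaction times with known bias structure.

    ``response = stimulus + DoG(delta; alpha_subject, w) + sinusoidal
    orientation bias + Gaussian noise``, wrapped to [0, 180).  With
    ``predictor="delta_R"`` responses are generated sequentially so each
    report feeds the next trial's predictor.  Catch trials get NaN responses.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["response"] = np.nan
    out["rt_ms"] = np.nan
    subjects = out["subject"].unique()
    alphas = np.broadcast_to(np.atleast_1d(ground_truth.alpha_true_per_subject),
                             (len(subjects),))
    has_cond = "condition" in out.columns
    for alpha_i, (_, idx) in zip(alphas, out.groupby("subject", sort=False).indices.items()):
        stim = out["stimulus"].to_numpy(float)[idx]
        catch = ((out["condition"].astype(str) == "catch").to_numpy()[idx]
                 if has_cond else np.zeros(len(idx), bool))
        theta_n = (stim - stim.mean()) / (stim.std() or 1.0)
        bias = np.zeros(len(idx))
        for a, b, c in ground_truth.bias_sinusoid:
            bias += a * np.sin(b * theta_n + c)
        noise = rng.normal(0.0, ground_truth.sigma_noise, size=len(idx))
        resp = np.full(len(idx), np.nan)
        prev_stim = prev_resp = np.nan
        prev_catch = False
        for t in range(len(idx)):
            if catch[t]:
                prev_stim, prev_resp, prev_catch = stim[t], np.nan, True
                continue
            anchor = prev_stim if ground_truth.predictor == "delta_S" else prev_resp
            amp = alpha_i
            if prev_catch and ground_truth.alpha_after_catch is not None:
                amp = ground_truth.alpha_after_catch
            serial = 0.0
            if not np.isnan(anchor):
                serial = dog(wrap_delta(anchor, stim[t]), amp, ground_truth.w_true)
            resp[t] = wrap_orientation(stim[t] + serial + bias[t] + noise[t])
            prev_stim, prev_resp, prev_catch = stim[t], resp[t], False
        out.iloc[idx, out.columns.get_loc("response")] = resp
        out.iloc[idx, out.columns.get_loc("rt_ms")] = _rt_ms(len(idx), ground_truth, rng)
    return out


@dataclass
class SizeGroundTruth:
    """Generating parameters for size-estimation behavior."""

    slope_delta_s: float = 0.0
    slope_delta_r: float = 0.0
    slope_delta_c: tuple | float = 0.0   # scalar (2 dots) or per-competitor
    bias_slope: float = 1.0              # report-vs-truth slope (1 = calibrated)
    bias_intercept: float = 0.0
    sigma_noise: float = 0.3             # deg of visual angle
    rt_median_s: float = 2.0
    rt_sigma: float = 0.3


def generate_size_behavior(table: pd.DataFrame, ground_truth: SizeGroundTruth,
                           seed: int = 0) -> pd.DataFrame:
    """Responses for the size tasks (ensemble mean or retro-cued diameter).

    ``error = slope_S*deltaS + slope_R*deltaR + sum_k slope_C[k]*deltaC(k)
    + (bias_slope - 1)*(size - midrange) + bias_intercept + noise``.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["response"] = np.nan
    out["rt_ms"] = np.nan
    gt = ground_truth
    has_comp = "competitor_sizes_json" in out.columns
    mid = float(out["stimulus"].mean())
    for _, idx in out.groupby("subject", sort=False).indices.items():
        stim = out["stimulus"].to_numpy(float)[idx]
        noise = rng.normal(0.0, gt.sigma_noise, size=len(idx))
        resp = np.full(len(idx), np.nan)
        prev_stim = prev_resp = np.nan
        for t in range(len(idx)):
            err = (gt.bias_slope - 1.0) * (stim[t] - mid) + gt.bias_intercept + noise[t]
            if not np.isnan(prev_stim):
                err += gt.slope_delta_s * (prev_stim - stim[t])
            if not np.isnan(prev_resp):
                err += gt.slope_delta_r * (prev_resp - stim[t])
            if has_comp:
                comp = parse_sequence(out["competitor_sizes_json"].iloc[idx[t]])
                slopes = np.broadcast_to(np.atleast_1d(gt.slope_delta_c), (len(comp),))
                for k, c in enumerate(comp):
                    err += slopes[k] * (c - stim[t])
            resp[t] = max(stim[t] + err, 0.05)
            prev_stim, prev_resp = stim[t], resp[t]
        out.iloc[idx, out.columns.get_loc("response")] = resp
        rt = rng.lognormal(np.log(gt.rt_median_s * 1000.0), gt.rt_sigma, size=len(idx))
        out.iloc[idx, out.columns.get_loc("rt_ms")] = rt
    return out
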