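"""Three-step calibration of the simulators and the two simulation replicas
used to adjudicate the Gain vs. Two-process accounts.

Step 1 sweeps the sensory gain factor and maps it to the fitted DoG
amplitude it produces under each mechanism (gain: attractive, positive;
adaptation: repulsive, negative).  Step 2 grid-searches the decisional
template (peak amplitude and concentration) so the simulated delta-S error
profile matches a target DoG under a fixed baseline adaptation.  Step 3
picks the forgetting factor minimizing the distance between model-predicted
and reference single-trial errors.  The replicas then simulate artificial
subjects on the standard trial structures and run the full fitting pipeline
on the simulated behavior.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap_delta
from .dogcurve import dog
from .dogmodel import ConditionalDoGModel, DoGModel, add_derived_columns
from .population import SimulationConfig, run_simulation
from .synth import generate_design
from .tables import dump_sequence


def _exp1_table(n_subjects: int, n_trials: int, seed: int) -> pd.DataFrame:
    _, table = generate_design("exp1", n_subjects=n_subjects, n_trials=n_trials,
                               seed=seed)
    return table


def _simulate_and_fit(config: SimulationConfig, table: pd.DataFrame,
                      predictor: str = "delta_S"):
    sim = run_simulation(table, config)
    sim = add_derived_columns(sim)
    return DoGModel.from_dataframe(sim, predictor).fit(), sim


def _mechanism_config(mechanism: str, alpha_g: float, seed: int | None,
                      sigma: float = 10.0, **overrides) -> SimulationConfig:
    """Config with the decisional stage disabled (uniform constant weights)."""
    if mechanism == "gain":
        kw = dict(model="gain")
    elif mechanism == "adaptation":
        kw = dict(model="two_process", template_amplitude=0.0, w_decay=0.0)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    kw.update(gain_factor=alpha_g, response_noise_sd=sigma, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class GainSweep:
    mechanism: str
    grid: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray
    n_trials: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha_g": self.grid, "alpha": self.amplitudes,
                             "w": self.widths})


def sweep_gain_factor(mechanism: str, grid=None, n_trials: int = 10_000,
                      n_subjects: int = 10, seed: int = 0) -> GainSweep:
    """Step 1: fitted DoG amplitude as a function of the gain factor.

    Simulates ``n_trials`` standard-grid trials per grid point with the
    decisional stage off, fits the multilevel DoG on delta-S, and records
    the amplitude.  Uses common trial sequences across grid points.
    """
    if grid is None:
        grid = np.linspace(0.05, 0.95, 50)
    grid = np.asarray(grid, float)
    table = _exp1_table(n_subjects, n_trials // n_subjects, seed)
    amps = np.empty(len(grid))
    widths = np.empty(len(grid))
    for i, ag in enumerate(grid):
        cfg = _mechanism_config(mechanism, float(ag), seed=seed + 1)
        fit, _ = _simulate_and_fit(cfg, table)
        amps[i] = fit.alpha0
        widths[i] = fit.w
    return GainSweep(mechanism, grid, amps, widths, n_trials, seed)


def gain_sweep_point(mechanism: str, alpha_g: float, n_trials: int = 10_000,
                     n_subjects: int = 10, seed: int = 0, n_reps: int = 1):
    """Fitted DoG amplitude at a single gain factor, averaged over
    ``n_reps`` independent simulations (fresh sequences and noise)."""
    amps = []
    for r in range(n_reps):
        table = _exp1_table(n_subjects, n_trials // n_subjects, seed + 7919 * r)
        cfg = _mechanism_config(mechanism, alpha_g, seed=seed + 7919 * r + 1)
        fit, _ = _simulate_and_fit(cfg, table)
        amps.append(fit.alpha0)
    return float(np.mean(amps)), amps


@dataclass
class TemplateOptimization:
    alpha_w_opt: float
    beta_w_opt: float
    objective: pd.DataFrame  # columns alpha_w, beta_w, sse
    n_trials: int
    seed: int


def optimize_template(alpha_g_fixed: float = 0.14, target_alpha: float = 1.35,
                      target_w: float = 0.05, alpha_w_grid=None, beta_w_grid=None,
                      n_trials: int = 2000, seed: int = 0,
                      sigma: float = 10.0) -> TemplateOptimization:
    """Step 2: grid-search the decisional template against a target profile.

    For each (alpha_w, beta_w) the two-process model (adaptation fixed at
    ``alpha_g_fixed``, no forgetting) simulates ``n_trials`` standard-grid
    trials with common random numbers; the objective is the squared distance
    between the mean error per delta-S level and the target DoG curve.
    """
    if alpha_w_grid is None:
        alpha_w_grid = np.linspace(0.0, 1.0, 25)
    if beta_w_grid is None:
        beta_w_grid = np.geomspace(1.0, 50.0, 25)
    table = _exp1_table(1, n_trials, seed)
    base = add_derived_columns(table.assign(response=table["stimulus"]))
    ds = base["delta_S"].to_numpy(float)
    levels = np.unique(ds[np.isfinite(ds)])
    target = dog(levels, target_alpha, target_w)
    rows = []
    best = (np.inf, None, None)
    for aw in alpha_w_grid:
        for bw in beta_w_grid:
            cfg = SimulationConfig(model="two_process", gain_factor=alpha_g_fixed,
                                   template_amplitude=float(aw),
                                   template_concentration=float(bw),
                                   w_decay=0.0, response_noise_sd=sigma,
                                   seed=seed + 1)  # common random numbers
            sim = run_simulation(table, cfg)
            err = wrap_delta(sim["response"].to_numpy(float),
                             sim["stimulus"].to_numpy(float))
            prof = np.array([np.nanmean(err[ds == lv]) for lv in levels])
            sse = float(np.nansum((prof - target) ** 2))
            rows.append({"alpha_w": float(aw), "beta_w": float(bw), "sse": sse})
            if sse < best[0]:
                best = (sse, float(aw), float(bw))
    surface = pd.DataFrame(rows)
    assert best[0] <= surface["sse"].min() + 1e-12
    return TemplateOptimization(best[1], best[2], surface, n_trials, seed)


@dataclass
class DecayOptimization:
    w_decay_opt: float
    grid: np.ndarray
    objective: np.ndarray
    seed: int


def optimize_decay(reference_table: pd.DataFrame, grid=None,
                   alpha_g: float = 0.14, alpha_w: float = 0.08,
                   beta_w: float = 24.5, seed: int = 0) -> DecayOptimization:
    """Step 3: forgetting factor minimizing single-trial error distance.

    ``reference_table`` provides stimuli and observed responses; for each
    candidate decay the model replays the same stimulus sequence noise-free
    and the objective is the summed squared difference between model and
    reference single-trial errors.
    """
    if grid is None:
        grid = np.linspace(0.01, 1.0, 100)
    grid = np.asarray(grid, float)
    ref_err = wrap_delta(reference_table["response"].to_numpy(float),
                         reference_table["stimulus"].to_numpy(float))
    obj = np.empty(len(grid))
    for i, decay in enumerate(grid):
        cfg = SimulationConfig(model="two_process", gain_factor=alpha_g,
                               template_amplitude=alpha_w,
                               template_concentration=beta_w,
                               w_decay=float(decay), response_noise_sd=0.0,
                               seed=seed)
        sim = run_simulation(reference_table, cfg)
        model_err = wrap_delta(sim["response"].to_numpy(float),
                               sim["stimulus"].to_numpy(float))
        ok = np.isfinite(ref_err) & np.isfinite(model_err)
        obj[i] = float(np.sum((ref_err[ok] - model_err[ok]) ** 2))
    best = int(np.argmin(obj))
    return DecayOptimization(float(grid[best]), grid, obj, seed)


@dataclass
class ReplicaResult:
    rmse_diffs: np.ndarray
    mean_abs_error: float
    alpha_S: float
    alpha_R: float
    details: dict = field(default_factory=dict)


def two_process_config(seed=None, sigma: float = 10.0, alpha_g: float = 0.14,
                       alpha_w: float = 0.08, beta_w: float = 24.5,
                       w_decay: float = 0.19) -> SimulationConfig:
    """The two-process model at its calibrated optimum."""
    return SimulationConfig(model="two_process", gain_factor=alpha_g,
                            template_amplitude=alpha_w,
                            template_concentration=beta_w, w_decay=w_decay,
                            response_noise_sd=sigma, seed=seed)


def gain_config(seed=None, sigma: float = 10.0, alpha_g: float = 0.33) -> SimulationConfig:
    """The gain model at the calibrated common gain factor."""
    return SimulationConfig(model="gain", gain_factor=alpha_g,
                            response_noise_sd=sigma, seed=seed)


def replicate_exp12(config: SimulationConfig, n_iter: int = 1000,
                    n_subjects: int = 10, n_trials: int = 500,
                    seed: int = 0) -> ReplicaResult:
    """Artificial-subject replica of the adjustment experiments.

    Each iteration simulates ``n_subjects`` subjects on standard-grid
    sequences under ``config``, fits the multilevel DoG with delta-S and
    with delta-R, and records rmse(delta_S fit) - rmse(delta_R fit).
    """
    diffs = np.empty(n_iter)
    abs_errors = []
    a_s = a_r = 0.0
    for it in range(n_iter):
        table = _exp1_table(n_subjects, n_trials, seed + 104729 * it)
        cfg_it = SimulationConfig(**{**config.__dict__, "seed": seed + 104729 * it + 1})
        sim = add_derived_columns(run_simulation(table, cfg_it))
        fit_s = DoGModel.from_dataframe(sim, "delta_S").fit()
        fit_r = DoGModel.from_dataframe(sim, "delta_R").fit()
        diffs[it] = fit_s.rmse - fit_r.rmse
        abs_errors.append(np.nanmean(np.abs(sim["error"].to_numpy(float))))
        a_s += fit_s.alpha0 / n_iter
        a_r += fit_r.alpha0 / n_iter
    return ReplicaResult(rmse_diffs=diffs, mean_abs_error=float(np.mean(abs_errors)),
                         alpha_S=a_s, alpha_R=a_r)


def _exp5_like_table(n_trials: int, n_subjects: int, seed: int) -> pd.DataFrame:
    """Response-only sequence trials: five nonreported stimuli then a report."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 180.0, 20.0)
    deltas = np.arange(-80.0, 81.0, 20.0)
    rows = []
    per = n_trials // n_subjects
    for s in range(n_subjects):
        for t in range(per):
            seq = np.empty(6)
            seq[0] = rng.choice(grid)
            for k in range(1, 6):
                seq[k] = np.mod(seq[k - 1] - rng.choice(deltas), 180.0)
            rows.append({"subject": s + 1, "block": 1, "trial": t + 1,
                         "experiment": "exp5", "stimulus": seq[-1],
                         "condition": "response",
                         "sequence_json": dump_sequence(seq)})
    return pd.DataFrame(rows)


def replicate_exp5(config: SimulationConfig, n_trials: int = 10_000,
                   n_subjects: int = 10, seed: int = 0):
    """Sequence-experiment replica: reported vs. nonreported one-back biases.

    Errors are conditioned on (a) the previous trial's *reported* stimulus
    and (b) the current trial's last *nonreported* stimulus (the fifth in
    the sequence), stacked into a conditional DoG fit.  Returns the fit
    (condition 1 = reported) and the simulated table.
    """
    table = _exp5_like_table(n_trials, n_subjects, seed)
    sim = run_simulation(table, SimulationConfig(**{**config.__dict__, "seed": seed + 1}))
    sim["error"] = wrap_delta(sim["response"], sim["stimulus"])
    seqs = sim["sequence_json"].map(lambda v: [float(x) for x in json.loads(v)])
    last_nonreported = seqs.map(lambda s: s[-2])
    stim = sim["stimulus"].to_numpy(float)
    d_nonrep = wrap_delta(last_nonreported.to_numpy(float), stim)
    d_rep = np.full(len(sim), np.nan)
    for _, idx in sim.groupby("subject", sort=False).indices.items():
        d_rep[idx[1:]] = wrap_delta(stim[idx[:-1]], stim[idx[1:]])
    err = sim["error"].to_numpy(float)
    stacked = pd.DataFrame({
        "subject": np.r_[sim["subject"], sim["subject"]],
        "error": np.r_[err, err],
        "predictor": np.r_[d_nonrep, d_rep],
        "reported": np.r_[np.zeros(len(sim), int), np.ones(len(sim), int)],
    }).dropna(subset=["predictor", "error"])
    fit = ConditionalDoGModel(stacked["error"], stacked["predictor"],
                              stacked["subject"], stacked["reported"]).fit()
    return fit, sim
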