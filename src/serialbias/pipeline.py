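"""End-to-end pipeline: synth -> preprocess -> fit -> compare (-> optimize).

Configuration is a plain dict (typically loaded from YAML/JSON); every
stochastic stage receives an explicit seed derived from the run seed, and a
manifest records all effective parameters plus SHA-256 hashes of every
output file so a rerun can be verified bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .compare import cross_validate, rmse_permutation_test
from .dogmodel import DoGModel, add_derived_columns
from .preprocessing import clean_errors, residualize_orientation_bias
from .synth import GroundTruth, generate_behavior, generate_design
from .tables import write_trial_table

DEFAULT_CONFIG = {
    "profile": "exp1-synthetic",
    "experiment": "exp1",
    "n_subjects": 8,
    "n_trials": 400,
    "seed": 0,
    "ground_truth": {"alpha_true_per_subject": 2.0, "w_true": 0.05,
                     "sigma_noise": 10.0, "predictor": "delta_R"},
    "residualize": True,
    "compare": {"n_permutations": 50, "n_cv": 50},
    "verbosity": 1,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> dict:
    """Run the configured stages and return the manifest dict.

    Raises with the failing stage's name; outputs of completed stages are
    kept on disk.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg["seed"]).generate_state(4)
    seeds = [int(s % (2 ** 31)) for s in seeds]
    manifest = {"config": cfg, "seeds": seeds, "version": __version__,
                "stages": [], "hashes": {}}
    stage = "synth"
    try:
        _, table = generate_design(cfg["experiment"], cfg["n_subjects"],
                                   cfg["n_trials"], seed=seeds[0])
        gt = GroundTruth(**cfg["ground_truth"])
        table = generate_behavior(table, gt, seed=seeds[1])
        write_trial_table(table, out / "trials.csv")
        manifest["stages"].append(stage)

        stage = "preprocess"
        clean, report = clean_errors(table)
        if cfg.get("residualize"):
            clean, _ = residualize_orientation_bias(clean)
        (out / "cleaning.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["stages"].append(stage)

        stage = "fit"
        clean = add_derived_columns(clean.drop(
            columns=["error", "delta_S", "delta_R"], errors="ignore"))
        if clean["error"].notna().sum() == 0:
            raise ValueError("no response trials available for fitting")
        fits = {}
        for predictor in ("delta_S", "delta_R"):
            res = DoGModel.from_dataframe(clean, predictor).fit()
            fits[predictor] = {"alpha0": res.alpha0, "se": res.se_alpha0,
                               "w": res.w, "p": res.pvalue, "rmse": res.rmse,
                               "aic": res.aic}
        (out / "fits.json").write_text(json.dumps(fits, indent=2))
        manifest["stages"].append(stage)

        stage = "compare"
        diff, perm_p, _ = rmse_permutation_test(
            clean, n=cfg["compare"]["n_permutations"], seed=seeds[2])
        win, _ = cross_validate(clean, n=cfg["compare"]["n_cv"], seed=seeds[3])
        (out / "comparison.json").write_text(json.dumps(
            {"rmse_diff": diff, "perm_p": perm_p, "cv_win_fraction": win}, indent=2))
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["hashes"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
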