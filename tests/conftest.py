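import numpy as np
import pandas as pd
import pytest

import serialbias as sb


@pytest.fixture(scope="session")
def exp1_behavior():
    """10 subjects x 400 trials with a known delta-S DoG (alpha=2, w=0.05)."""
    _, table = sb.generate_design("exp1", n_subjects=10, n_trials=400, seed=11)
    gt = sb.GroundTruth(alpha_true_per_subject=2.0, w_true=0.05, sigma_noise=10.0)
    return sb.add_derived_columns(sb.generate_behavior(table, gt, seed=12))


@pytest.fixture(scope="session")
def null_behavior():
    """8 subjects x 300 trials with no serial dependence at all."""
    _, table = sb.generate_design("exp1", n_subjects=8, n_trials=300, seed=21)
    gt = sb.GroundTruth(alpha_true_per_subject=0.0, w_true=0.05, sigma_noise=10.0)
    return sb.add_derived_columns(sb.generate_behavior(table, gt, seed=22))


@pytest.fixture(scope="session")
def delta_r_behavior():
    """Behavior whose serial dependence follows the previous *response*."""
    _, table = sb.generate_design("exp1", n_subjects=10, n_trials=400, seed=31)
    gt = sb.GroundTruth(alpha_true_per_subject=3.0, w_true=0.05, sigma_noise=8.0,
                        predictor="delta_R")
    return sb.add_derived_columns(sb.generate_behavior(table, gt, seed=32))
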