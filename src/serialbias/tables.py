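"""Trial-table I/O and validation.

The trial table is the exchange format between every pipeline stage: one row
per trial, ordered within subject (row order is temporal order and is
semantically load-bearing).  Orientation columns are degrees in [0, 180);
size columns are degrees of visual angle.  Catch trials carry NaN responses.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject", "trial", "stimulus")
STANDARD_COLUMNS = (
    "subject",
    "block",
    "trial",
    "experiment",
    "stimulus",
    "response",
    "rt_ms",
    "condition",
    "contrast",
    "sequence_json",
    "competitor_sizes_json",
)

ORIENTATION_EXPERIMENTS = {"exp1", "exp2", "exp3", "exp5", "exp6"}


class TrialTableError(ValueError):
    """Raised when a trial table fails schema or range validation."""


def validate_trial_table(table: pd.DataFrame, orientation: bool | None = None) -> pd.DataFrame:
    """Validate schema, orientation ranges and per-subject trial ordering.

    Parameters
    ----------
    orientation
        Whether stimulus/response are orientations in [0, 180).  If None it
        is inferred from the ``experiment`` column when present.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    if orientation is None:
        if "experiment" in table.columns and len(table):
            orientation = str(table["experiment"].iloc[0]) in ORIENTATION_EXPERIMENTS
        else:
            orientation = True
    if orientation:
        for col in ("stimulus", "response"):
            if col not in table.columns:
                continue
            vals = pd.to_numeric(table[col], errors="coerce")
            bad = vals.notna() & ((vals < 0) | (vals >= 180))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TrialTableError(
                    f"column {col!r} out of orientation range [0, 180) at row {row} "
                    f"(value {vals.iloc[row]})"
                )
    for subject, grp in table.groupby("subject", sort=False):
        tr = grp["trial"].to_numpy()
        if np.any(np.diff(tr) <= 0):
            row = int(grp.index[np.flatnonzero(np.diff(tr) <= 0)[0] + 1])
            raise TrialTableError(
                f"non-monotone trial index for subject {subject!r} at row {row}"
            )
    return table


def read_trial_table(path, orientation: bool | None = None) -> pd.DataFrame:
    """Read and validate a trial table from CSV, preserving row order."""
    table = pd.read_csv(path)
    return validate_trial_table(table, orientation=orientation)


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table to CSV with the standard column ordering first."""
    cols = [c for c in STANDARD_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols)


def parse_sequence(value):
    """Parse a ``sequence_json`` cell to a list of orientations (or None)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    seq = json.loads(value)
    if not isinstance(seq, list):
        raise TrialTableError(f"sequence_json is not a list: {value!r}")
    return [float(v) for v in seq]


def dump_sequence(seq) -> str:
    return json.dumps([float(v) for v in seq])
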