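"""Cohort schema, CSV I/O, cleaning rules and blood-pressure outcome labelling.

A cohort is a pandas DataFrame with one row per patient:

    patient_id, <19 attribute columns>, monotherapy, on_label_dose,
    sbp_d1..sbp_d5, dbp_d1..dbp_d5, [label]

The 19 attribute columns hold pre-initiation values in native units (Sex coded
1=male / 2=female); ``sbp_d*``/``dbp_d*`` are the daily blood pressures of the
five days immediately after therapy initiation.  Treatment is *successful* iff
the 5-day mean SBP is strictly below 140 mmHg AND the 5-day mean DBP is
strictly below 90 mmHg; equality at either threshold is unsuccessful.
"""

from __future__ import annotations

import json
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .normalize import ATTRIBUTE_ORDER

__all__ = [
    "BPSeries",
    "COHORT_COLUMNS",
    "DBP_DAY_COLUMNS",
    "SBP_DAY_COLUMNS",
    "SUCCESSFUL",
    "UNSUCCESSFUL",
    "clean_cohort",
    "label_cohort",
    "label_outcome",
    "read_cohort",
    "write_cohort",
    "write_exclusion_log",
]

SUCCESSFUL = "successful"
UNSUCCESSFUL = "unsuccessful"

#: Strict outcome thresholds on the 5-day means, in mmHg.
SBP_THRESHOLD = 140.0
DBP_THRESHOLD = 90.0

N_OUTCOME_DAYS = 5
SBP_DAY_COLUMNS = tuple(f"sbp_d{i}" for i in range(1, N_OUTCOME_DAYS + 1))
DBP_DAY_COLUMNS = tuple(f"dbp_d{i}" for i in range(1, N_OUTCOME_DAYS + 1))

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    *ATTRIBUTE_ORDER,
    "monotherapy",
    "on_label_dose",
    *SBP_DAY_COLUMNS,
    *DBP_DAY_COLUMNS,
)
LABEL_COLUMN = "label"

_NUMERIC_COLUMNS = (*ATTRIBUTE_ORDER, *SBP_DAY_COLUMNS, *DBP_DAY_COLUMNS)
_FLAG_COLUMNS = ("monotherapy", "on_label_dose")

#: Cleaning rules, in the order they fire; a record is counted under the first
#: rule that excludes it.
EXCLUSION_RULES = ("non_monotherapy", "off_label_dose", "missing_value")


class BPSeries(NamedTuple):
    """Five daily (SBP, DBP) pairs following therapy initiation, in mmHg."""

    sbp: np.ndarray
    dbp: np.ndarray


def label_outcome(sbp: Sequence[float], dbp: Sequence[float]) -> str:
    """Label a 5-day BP series as ``successful`` or ``unsuccessful``.

    Successful requires mean(SBP) < 140 AND mean(DBP) < 90, both strict; a
    mean exactly at a threshold is unsuccessful.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if sbp.shape != (N_OUTCOME_DAYS,) or dbp.shape != (N_OUTCOME_DAYS,):
        raise ValueError(f"expected exactly {N_OUTCOME_DAYS} daily values per series")
    if np.any(sbp <= 0) or np.any(dbp <= 0):
        raise ValueError("blood pressures must be positive")
    ok = sbp.mean() < SBP_THRESHOLD and dbp.mean() < DBP_THRESHOLD
    return SUCCESSFUL if ok else UNSUCCESSFUL


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``cohort`` with the ``label`` column (re)computed."""
    sbp_mean = cohort[list(SBP_DAY_COLUMNS)].to_numpy(dtype=float).mean(axis=1)
    dbp_mean = cohort[list(DBP_DAY_COLUMNS)].to_numpy(dtype=float).mean(axis=1)
    ok = (sbp_mean < SBP_THRESHOLD) & (dbp_mean < DBP_THRESHOLD)
    out = cohort.copy()
    out[LABEL_COLUMN] = np.where(ok, SUCCESSFUL, UNSUCCESSFUL)
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, preserving missing cells as NaN for later cleaning.

    The header must start with the canonical schema columns (a trailing
    ``label`` column is optional).  Non-numeric text in a numeric column is an
    error; blank cells are not.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    cols = list(df.columns)
    expected = list(COHORT_COLUMNS)
    if cols != expected and cols != expected + [LABEL_COLUMN]:
        raise ValueError(
            f"malformed cohort header: expected {expected} (+ optional '{LABEL_COLUMN}'), got {cols}"
        )
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with columns in canonical schema order."""
    cols = list(COHORT_COLUMNS)
    if LABEL_COLUMN in cohort.columns:
        cols.append(LABEL_COLUMN)
    cohort.loc[:, cols].to_csv(path, index=False)


def clean_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the exclusion funnel and return (kept rows, exclusion log).

    Rules fire in order — non-monotherapy, off-label dose, any missing value
    among the 19 attributes — and each excluded record is counted once, under
    the first rule that fires.  Row order is preserved;
    ``len(kept) + sum(log.values()) == len(cohort)``.
    """
    non_mono = ~cohort["monotherapy"].astype(bool).to_numpy()
    off_label = ~cohort["on_label_dose"].astype(bool).to_numpy()
    missing = cohort[list(ATTRIBUTE_ORDER)].isna().any(axis=1).to_numpy()

    rule = np.full(len(cohort), "", dtype=object)
    rule[missing] = "missing_value"
    rule[off_label] = "off_label_dose"
    rule[non_mono] = "non_monotherapy"

    log = {name: int(np.sum(rule == name)) for name in EXCLUSION_RULES}
    kept = cohort.loc[rule == ""].copy()
    return kept, log


def write_exclusion_log(log: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
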