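"""Aggregation schemes for rated divergent-thinking tasks.

Classical schemes (average, summative, max-n, snapshot, fluency) and
IRT-adjusted scores built from EAP trait estimates.  Every scheme yields
one value per participant x task plus a cross-task composite: the
unweighted mean over tasks with data, with participants missing two or
more tasks dropped from the composite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .rating_data import RatingTable

COMPOSITE = "composite"


def response_means(table: RatingTable) -> pd.DataFrame:
    """Mean observed rating per response unit (missing-robust).

    Returns a frame indexed by unit id with columns ``participant_id,
    task_id, mean``, preserving the original response order within each
    participant-task (needed for deterministic max-n tie-breaking).
    """
    if table.level != "response":
        raise ValueError("response_means needs a response-level table")
    rec = table.records
    if len(rec) == 0:
        return pd.DataFrame(columns=["participant_id", "task_id", "mean"])
    means = rec.groupby("unit_id", sort=False)["rating"].mean()
    meta = rec.drop_duplicates("unit_id").set_index("unit_id")
    out = meta[["participant_id", "task_id"]].copy()
    out["mean"] = means.reindex(out.index)
    return out


def _composite(task_frame: pd.DataFrame, n_tasks: int) -> pd.DataFrame:
    """Append the cross-task composite; drop participants missing >= 2 tasks."""
    out = task_frame.copy()
    observed = out.notna().sum(axis=1)
    comp = out.mean(axis=1)
    comp[observed < max(n_tasks - 1, 1)] = np.nan
    out[COMPOSITE] = comp
    return out


def _per_task(values: pd.Series, meta: pd.DataFrame, agg) -> pd.DataFrame:
    df = meta[["participant_id", "task_id"]].copy()
    df["value"] = values
    wide = df.groupby(["participant_id", "task_id"], sort=True)["value"].agg(agg).unstack()
    wide.columns.name = None
    return wide


def average_score(table: RatingTable) -> pd.DataFrame:
    """Mean of response means per task, then cross-task composite."""
    rm = response_means(table)
    wide = _per_task(rm["mean"], rm, "mean")
    return _composite(wide, wide.shape[1])


def summative_score(table: RatingTable) -> pd.DataFrame:
    """Sum of response means per task (fluency-confounded by design)."""
    rm = response_means(table)
    wide = _per_task(rm["mean"], rm, "sum")
    return _composite(wide, wide.shape[1])


def max_n_score(table: RatingTable, n: int) -> pd.DataFrame:
    """Mean of the n highest-rated responses per task.

    Ties in response means are broken by original response order (stable
    sort), and a participant with fewer than n responses is scored on all
    the responses they gave, so e.g. a three-response participant has
    identical max-3, max-4 and max-5 scores.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rm = response_means(table)

    def top_n(vals):
        arr = np.asarray(vals, dtype=float)
        order = np.argsort(-arr, kind="stable")
        return float(arr[order[: min(n, len(arr))]].mean())

    wide = _per_task(rm["mean"], rm, top_n)
    return _composite(wide, wide.shape[1])


def fluency_score(table: RatingTable) -> pd.DataFrame:
    """Number of responses per participant-task (a count, not a rating)."""
    rm = response_means(table)
    wide = _per_task(rm["mean"], rm, "size")
    return _composite(wide, wide.shape[1])


def snapshot_score(table: RatingTable) -> pd.DataFrame:
    """Missing-robust mean over snapshot raters per pool, then composite."""
    if table.level != "pool":
        raise ValueError("snapshot_score needs a pool-level table")
    rec = table.records
    means = rec.groupby("unit_id", sort=False)["rating"].mean()
    meta = rec.drop_duplicates("unit_id").set_index("unit_id")
    wide = _per_task(means.reindex(meta.index), meta, "mean")
    return _composite(wide, wide.shape[1])


def irt_adjusted_scores(abilities, table: RatingTable) -> pd.DataFrame:
    """Participant x task means of unit EAP scores, then composite.

    For response-level tables the task score is the unweighted mean of
    that task's response EAPs; for pool-level tables it is the pool EAP
    itself.
    """
    theta = abilities.theta_eap if hasattr(abilities, "theta_eap") else abilities
    meta = table.records.drop_duplicates("unit_id").set_index("unit_id")
    vals = theta.reindex(meta.index)
    missing = vals.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} units lack EAP estimates; excluded")
        meta, vals = meta[~missing], vals[~missing]
    wide = _per_task(vals, meta, "mean")
    return _composite(wide, wide.shape[1])


def standardize(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (sample SD); errors on a zero-variance column."""
    out = scores.copy().astype(float)
    for col in out.columns:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def score_matrix(individual_table=None, snapshot_table=None,
                 abilities_individual=None, abilities_snapshot=None,
                 max_ns=(1, 2, 3, 4, 5)) -> dict:
    """All available schemes as a dict scheme -> participant x task frame.

    Keys follow the reporting convention: ``average, summative, max1..
    max5, fluency, snapshot, irt_individual, irt_snapshot`` (only those
    computable from the supplied inputs are present).
    """
    out = {}
    if individual_table is not None:
        out["average"] = average_score(individual_table)
        out["summative"] = summative_score(individual_table)
        for n in max_ns:
            out[f"max{n}"] = max_n_score(individual_table, n)
        out["fluency"] = fluency_score(individual_table)
        if abilities_individual is not None:
            out["irt_individual"] = irt_adjusted_scores(abilities_individual,
                                                        individual_table)
    if snapshot_table is not None:
        out["snapshot"] = snapshot_score(snapshot_table)
        if abilities_snapshot is not None:
            out["irt_snapshot"] = irt_adjusted_scores(abilities_snapshot, snapshot_table)
    return out


def composites(scores: dict) -> pd.DataFrame:
    """Participant x scheme frame of cross-task composite scores."""
    return pd.DataFrame({name: frame[COMPOSITE] for name, frame in scores.items()})
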