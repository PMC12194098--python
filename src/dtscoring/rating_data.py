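"""Long-format rating tables and wide unit x rater matrices.

A rating table holds one row per (unit, rater) pair: the unit is either a
single response (level ``"response"``) or a participant x task ideational
pool (level ``"pool"``), and the rating is an ordinal category on a 1..K
scale.  Missing ratings are simply absent records in long format and NaN
cells in wide format; no imputation happens at this layer because the IRT
marginal likelihood downstream handles missingness natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("response", "pool")

#: canonical CSV header order
CSV_COLUMNS = ["participant_id", "task_id", "unit_id", "rater_id", "rating", "level"]


class RatingValidationError(ValueError):
    """A record violates the rating-table invariants."""


@dataclass
class RatingTable:
    """Validated long-format table of ordinal ratings.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``participant_id, task_id, unit_id, rater_id, rating``;
        one row per observed (unit, rater) pair.
    K : int
        Number of ordinal categories (ratings are integers in 1..K).
    level : str
        ``"response"`` (unit = one idea) or ``"pool"`` (unit = the whole
        participant x task ideational pool).
    raters : list of str
        Ordered rater roster.  Defaults to the raters present in
        ``records``, in order of first appearance.
    """

    records: pd.DataFrame
    K: int
    level: str
    raters: list = field(default=None)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise RatingValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.K < 2:
            raise RatingValidationError(f"K must be >= 2, got {self.K}")
        df = self.records.copy()
        for col in ("participant_id", "task_id", "unit_id", "rater_id"):
            df[col] = df[col].astype(str)
        df["rating"] = pd.to_numeric(df["rating"])
        bad = df[(df["rating"] % 1 != 0) | (df["rating"] < 1) | (df["rating"] > self.K)]
        if len(bad):
            r = bad.iloc[0]
            raise RatingValidationError(
                f"rating {r['rating']} outside 1..{self.K} for unit "
                f"{r['unit_id']!r}, rater {r['rater_id']!r}"
            )
        df["rating"] = df["rating"].astype(int)
        dup = df.duplicated(subset=["unit_id", "rater_id"])
        if dup.any():
            r = df[dup].iloc[0]
            raise RatingValidationError(
                f"duplicate record for unit {r['unit_id']!r}, rater {r['rater_id']!r}"
            )
        if self.raters is None:
            self.raters = list(dict.fromkeys(df["rater_id"]))
        else:
            self.raters = [str(r) for r in self.raters]
            unknown = set(df["rater_id"]) - set(self.raters)
            if unknown:
                raise RatingValidationError(f"rater ids not in roster: {sorted(unknown)}")
        self.records = df.reset_index(drop=True)

    @property
    def n_units(self) -> int:
        return self.records["unit_id"].nunique()

    def unit_meta(self) -> pd.DataFrame:
        """Unique (unit_id, participant_id, task_id) rows, sorted by unit id."""
        meta = self.records[["unit_id", "participant_id", "task_id"]].drop_duplicates("unit_id")
        return meta.sort_values("unit_id").set_index("unit_id")


@dataclass
class WideMatrix:
    """Units x raters rating matrix with NaN for missing cells.

    ``values`` is a DataFrame indexed by unit id (sorted) with one column
    per rater in roster order; ``meta`` maps each unit id to its
    participant and task.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    K: int
    level: str

    @property
    def raters(self) -> list:
        return list(self.values.columns)

    @property
    def missing_fraction(self) -> float:
        if self.values.size == 0:
            return 0.0
        return float(self.values.isna().to_numpy().mean())

    def to_long(self) -> RatingTable:
        """Inverse of :func:`to_wide` (on the records it preserves)."""
        stacked = self.values.stack()
        df = stacked.rename("rating").reset_index()
        df.columns = ["unit_id", "rater_id", "rating"]
        df = df.merge(self.meta.reset_index(), on="unit_id")
        return RatingTable(
            records=df[["participant_id", "task_id", "unit_id", "rater_id", "rating"]],
            K=self.K,
            level=self.level,
            raters=self.raters,
        )


def to_wide(table: RatingTable) -> WideMatrix:
    """Pivot a long rating table to a units x raters matrix.

    Rows are sorted by unit id so the output is deterministic regardless of
    record order; absent records become NaN cells.
    """
    meta = table.unit_meta()
    if len(table.records) == 0:
        values = pd.DataFrame(index=pd.Index([], name="unit_id"),
                              columns=pd.Index(table.raters, name="rater_id"), dtype=float)
    else:
        values = table.records.pivot(index="unit_id", columns="rater_id", values="rating")
        values = values.reindex(columns=table.raters).sort_index().astype(float)
        values.columns.name = "rater_id"
    return WideMatrix(values=values, meta=meta, K=table.K, level=table.level)


def read_long_csv(path, K: int, level: str) -> RatingTable:
    """Read a long-format rating CSV.

    The file must carry the header ``participant_id,task_id,unit_id,
    rater_id,rating,level`` (UTF-8).  Rows whose rating cell is empty are
    treated as missing and omitted; a ``level`` column, if present, must
    agree with the requested level.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise RatingValidationError(f"malformed CSV {path}: {exc}") from exc
    missing_cols = [c for c in CSV_COLUMNS[:5] if c not in df.columns]
    if missing_cols:
        raise RatingValidationError(f"{path}: missing columns {missing_cols}")
    if "level" in df.columns:
        levels = set(df["level"][df["level"] != ""])
        if levels - {level}:
            raise RatingValidationError(
                f"{path}: file contains level(s) {sorted(levels)}, expected {level!r}")
    df = df[df["rating"] != ""].copy()
    try:
        df["rating"] = pd.to_numeric(df["rating"])
    except (ValueError, TypeError) as exc:
        raise RatingValidationError(f"{path}: non-numeric rating: {exc}") from exc
    return RatingTable(records=df[CSV_COLUMNS[:5]], K=K, level=level)


def write_long_csv(table: RatingTable, path) -> None:
    """Write a rating table in the canonical long CSV layout."""
    df = table.records.copy()
    df["level"] = table.level
    df[CSV_COLUMNS].to_csv(path, index=False)


def category_counts(table: RatingTable) -> pd.DataFrame:
    """Per-rater frequency of each category 1..K.

    Returns a raters x K DataFrame (roster order); raters with no records
    get all-zero rows.  Row sums equal each rater's record count.
    """
    counts = pd.DataFrame(0, index=pd.Index(table.raters, name="rater_id"),
                          columns=pd.RangeIndex(1, table.K + 1, name="category"))
    obs = table.records.groupby(["rater_id", "rating"]).size()
    for (rater, rating), n in obs.items():
        counts.loc[rater, rating] = n
    return counts
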