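"""Planned-missingness rater designs and robustness experiments.

In an m-of-J design each unit (response or ideational pool) is rated by a
uniformly random subset of m of the J raters, cutting the rating burden
to m/J while the IRT marginal likelihood absorbs the missingness.  The
subset is keyed by unit id (not row position), so applying a design is
invariant to row order and reproducible from its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irt import RaterIRT
from .rating_data import RatingTable, WideMatrix, to_wide
from .reliability import OneFactorCFA, cronbach_alpha, hancock_h, omega
from .scoring import average_score, irt_adjusted_scores, snapshot_score


@dataclass(frozen=True)
class MissingDesign:
    """Retain m of J rater columns per unit; missing fraction = 1 - m/J."""

    J: int
    m: int
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.m <= self.J:
            raise ValueError(f"need 1 <= m <= J, got m={self.m}, J={self.J}")

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.m / self.J


def _unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(str(unit_id).encode())])


def apply_planned_missingness(data: WideMatrix, design: MissingDesign) -> WideMatrix:
    """Blank all but m rater cells per row, keyed by unit id and seed."""
    if len(data.raters) != design.J:
        raise ValueError(f"design expects J={design.J} raters, data has {len(data.raters)}")
    values = data.values.copy()
    J, m = design.J, design.m
    for uid in values.index:
        keep = _unit_rng(design.seed, uid).choice(J, size=m, replace=False)
        mask = np.ones(J, dtype=bool)
        mask[keep] = False
        values.loc[uid, values.columns[mask]] = np.nan
    return WideMatrix(values=values, meta=data.meta, K=data.K, level=data.level)


def reduce_table(table: RatingTable, design: MissingDesign) -> RatingTable:
    """Long-table convenience wrapper around the wide design application."""
    return apply_planned_missingness(to_wide(table), design).to_long()


def full_vs_reduced(scores_full: pd.DataFrame, scores_reduced: pd.DataFrame,
                    schemes=None) -> pd.DataFrame:
    """Pearson correlations between complete- and reduced-data composites.

    Rows index the complete-data schemes, columns the reduced-data
    schemes; participants are matched on the index.
    """
    schemes = list(schemes) if schemes is not None else list(scores_full.columns)
    matched = scores_full[schemes].join(scores_reduced[schemes], how="inner",
                                        lsuffix="_full", rsuffix="_red").dropna()
    if len(matched) < 10:
        raise ValueError("fewer than 10 matched participants")
    out = pd.DataFrame(index=schemes, columns=schemes, dtype=float)
    for a in schemes:
        for b in schemes:
            out.loc[a, b] = matched[f"{a}_full"].corr(matched[f"{b}_red"])
    return out


@dataclass
class RobustnessReport:
    """Full-vs-reduced score correlations plus reliability deltas."""

    correlations: pd.DataFrame
    reliability: pd.DataFrame      # (scheme, dataset) -> alpha / omega / H
    missing_fractions: dict
    reduced_scores: pd.DataFrame = None


def _reliability_row(task_scores: pd.DataFrame) -> dict:
    df = task_scores.drop(columns=["composite"], errors="ignore").dropna()
    fit = OneFactorCFA().fit(df)
    return {"alpha": cronbach_alpha(df), "omega": omega(fit), "hancock_h": hancock_h(fit)}


def run_missingness_experiment(individual_table: RatingTable,
                               snapshot_table: RatingTable,
                               design_individual: MissingDesign = None,
                               design_snapshot: MissingDesign = None,
                               family: str = "grm",
                               seed: int = 0) -> RobustnessReport:
    """Apply designs, refit the IRT model, rescore, and compare.

    Defaults to the 2-of-3 individual and 2-of-5 snapshot designs.  The
    reduced-data refit uses the same model family that was selected on
    complete data.  Reliability (alpha / omega / H on the three task
    scores) is reported for complete and reduced data side by side.
    """
    ind_J = len(individual_table.raters)
    snap_J = len(snapshot_table.raters)
    design_individual = design_individual or MissingDesign(ind_J, 2, seed)
    design_snapshot = design_snapshot or MissingDesign(snap_J, 2, seed + 1)

    wide_ind = to_wide(individual_table)
    wide_snap = to_wide(snapshot_table)
    red_ind = apply_planned_missingness(wide_ind, design_individual)
    red_snap = apply_planned_missingness(wide_snap, design_snapshot)

    def score_set(wide, table_level_ind, table_level_snap):
        ind_tab, snap_tab = table_level_ind, table_level_snap
        model_ind = RaterIRT(family=family, K=ind_tab.K).fit(wide[0])
        model_snap = RaterIRT(family=family, K=snap_tab.K).fit(wide[1])
        per_task = {
            "average": average_score(ind_tab),
            "irt_individual": irt_adjusted_scores(model_ind.eap(wide[0]), ind_tab),
            "snapshot": snapshot_score(snap_tab),
            "irt_snapshot": irt_adjusted_scores(model_snap.eap(wide[1]), snap_tab),
        }
        return per_task

    full_tasks = score_set((wide_ind, wide_snap), individual_table, snapshot_table)
    red_tasks = score_set((red_ind, red_snap), red_ind.to_long(), red_snap.to_long())

    schemes = list(full_tasks)
    comp_full = pd.DataFrame({s: full_tasks[s]["composite"] for s in schemes})
    comp_red = pd.DataFrame({s: red_tasks[s]["composite"] for s in schemes})
    corr = full_vs_reduced(comp_full, comp_red, schemes)

    rel_rows = {}
    for s in schemes:
        rel_rows[(s, "complete")] = _reliability_row(full_tasks[s])
        rel_rows[(s, "reduced")] = _reliability_row(red_tasks[s])
    reliability = pd.DataFrame(rel_rows).T
    reliability.index.names = ["scheme", "dataset"]

    return RobustnessReport(
        correlations=corr,
        reliability=reliability,
        missing_fractions={"individual": red_ind.missing_fraction,
                           "snapshot": red_snap.missing_fraction},
        reduced_scores=comp_red,
    )
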