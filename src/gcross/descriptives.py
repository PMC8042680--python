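"""Descriptive summaries of a rating cube: scenario difficulty, rater
stringency, and the pairwise correlations between raters and between tasks.

A large gap between task means signals unequal scenario difficulty; a gap
between rater means signals unequal stringency.  The inter-task correlation
(per-person task scores after averaging over raters) is the empirical face
of context specificity: when the person x task component dominates the
person component, performance on one scenario barely predicts the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import RatingCube

__all__ = [
    "CellSummary",
    "cell_means",
    "cell_means_table",
    "pearson",
    "inter_rater_correlation",
    "inter_task_correlation",
]


@dataclass(frozen=True)
class CellSummary:
    """Mean and sample SD over persons for one task x rater cell."""

    task_id: str
    rater_id: str
    measure: str
    mean: float
    sd: float | None  # n-1 denominator; undefined for n < 2
    n: int


def cell_means(cube: RatingCube) -> list[CellSummary]:
    """One summary per task x rater cell, averaging over persons."""
    out = []
    for j, t in enumerate(cube.tasks):
        for k, r in enumerate(cube.raters):
            col = cube.scores[:, j, k]
            sd = float(col.std(ddof=1)) if cube.n_p >= 2 else None
            out.append(
                CellSummary(
                    task_id=t, rater_id=r, measure=cube.measure,
                    mean=float(col.mean()), sd=sd, n=cube.n_p,
                )
            )
    return out


def cell_means_table(cube: RatingCube) -> pd.DataFrame:
    """Cell summaries as a task x (rater, statistic) table."""
    rows = cell_means(cube)
    df = pd.DataFrame([vars(s) for s in rows])
    return df.pivot(index="task_id", columns="rater_id", values=["mean", "sd"])


def pearson(x, y) -> float:
    """Sample Pearson correlation; errors on constant input or length < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def inter_rater_correlation(cube: RatingCube, per_task: bool = False):
    """Correlation between the two raters' scores.

    By default all (person, task) units are pooled across tasks — the
    scenario being rated is ignored.  With ``per_task=True`` a dict of
    per-task correlations is returned instead.
    """
    if cube.n_r != 2:
        raise ValueError(f"inter-rater correlation requires exactly 2 raters, got {cube.n_r}")
    if per_task:
        return {
            t: pearson(cube.scores[:, j, 0], cube.scores[:, j, 1])
            for j, t in enumerate(cube.tasks)
        }
    r1 = cube.scores[:, :, 0].ravel()
    r2 = cube.scores[:, :, 1].ravel()
    return pearson(r1, r2)


def inter_task_correlation(cube: RatingCube) -> float:
    """Correlation across persons between the two tasks' rater-averaged scores."""
    if cube.n_t != 2:
        raise ValueError(f"inter-task correlation requires exactly 2 tasks, got {cube.n_t}")
    by_task = cube.scores.mean(axis=2)  # person x task
    return pearson(by_task[:, 0], by_task[:, 1])
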