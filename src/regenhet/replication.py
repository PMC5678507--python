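"""Replicate-subsampling reproducibility of mean and CV estimates.

CV estimates need far more biological replication than mean estimates to
stabilize.  This module quantifies that: per timepoint, k of the available
replicates are drawn at random, the summary is recomputed, and the Pearson
correlation across probesets between full-replication and subsampled
values is recorded — separately for the mean and for the CV — over many
random draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import ExpressionMatrix, SummaryTable, summarize

__all__ = ["SubsamplingResult", "subsample_summary", "run_subsampling_study"]

DEFAULT_KS = (3, 4, 5, 6)


@dataclass
class SubsamplingResult:
    """Per-iteration Pearson r values and their five-number summaries.

    ``iterations`` columns: timepoint_day, k, iteration, r_mean, r_cv
    (NaN where a subsampled vector was degenerate).  ``summary`` columns:
    timepoint_day, k, statistic, min, q1, median, q3, max, n_defined.
    """

    iterations: pd.DataFrame
    summary: pd.DataFrame
    n_iter: int

    def write_tsv(self, path: str | Path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)


def subsample_summary(
    matrix: ExpressionMatrix, k: int, seed: int, ddof: int = 1
) -> SummaryTable:
    """Summary statistics after keeping k random replicates per timepoint.

    Replicates are chosen uniformly without replacement, independently per
    timepoint (a replicate index is not assumed to be the same animal
    across timepoints).  Deterministic under a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.Generator(np.random.PCG64(seed))
    keep: list[str] = []
    for day in matrix.timepoints:
        cols = matrix.columns_at(day)
        if k > len(cols):
            raise ValueError(f"k={k} exceeds the {len(cols)} replicates at day {day}")
        keep.extend(np.array(cols)[rng.choice(len(cols), size=k, replace=False)])
    reduced = ExpressionMatrix(
        values=matrix.values[keep], samples=matrix.samples.loc[keep]
    )
    return summarize(reduced, ddof=ddof)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def run_subsampling_study(
    matrix: ExpressionMatrix,
    ks: tuple[int, ...] = DEFAULT_KS,
    n_iter: int = 1000,
    seed: int = 0,
    ddof: int = 1,
) -> SubsamplingResult:
    """Pearson-r reproducibility of mean and CV under reduced replication.

    One random draw per (k, iteration) feeds both the mean and the CV
    correlation.  Degenerate (zero-variance) vectors give an undefined r,
    which is recorded as NaN and counted, never silently resampled.
    """
    full = summarize(matrix, ddof=ddof)
    full_mean = full.wide("mean")
    full_cv = full.wide("cv")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(ks) * n_iter, dtype=np.uint32
    )
    rows = []
    for ki, k in enumerate(ks):
        for it in range(n_iter):
            sub_seed = int(seeds[ki * n_iter + it] % (2 ** 31))
            sub = subsample_summary(matrix, k, sub_seed, ddof=ddof)
            sub_mean = sub.wide("mean")
            sub_cv = sub.wide("cv")
            for day in full.timepoints:
                rows.append(
                    {
                        "timepoint_day": day,
                        "k": k,
                        "iteration": it,
                        "r_mean": _safe_pearson(
                            full_mean[day].to_numpy(), sub_mean[day].to_numpy()
                        ),
                        "r_cv": _safe_pearson(
                            full_cv[day].to_numpy(), sub_cv[day].to_numpy()
                        ),
                    }
                )
    iterations = pd.DataFrame(rows)
    summary_rows = []
    for (day, k), grp in iterations.groupby(["timepoint_day", "k"]):
        for stat in ("r_mean", "r_cv"):
            vals = grp[stat].dropna().to_numpy()
            q = (
                np.percentile(vals, [0, 25, 50, 75, 100])
                if vals.size
                else [np.nan] * 5
            )
            summary_rows.append(
                {
                    "timepoint_day": day,
                    "k": k,
                    "statistic": stat,
                    "min": q[0],
                    "q1": q[1],
                    "median": q[2],
                    "q3": q[3],
                    "max": q[4],
                    "n_defined": vals.size,
                }
            )
    return SubsamplingResult(
        iterations=iterations, summary=pd.DataFrame(summary_rows), n_iter=n_iter
    )
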