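"""Replicate-level expression tables and per-timepoint summary statistics.

The analysis operates on a replicate-level matrix of normalized transcript
abundances (probesets x samples) in which every sample is annotated with a
numeric timepoint (days post-amputation; day 0 is the amputation baseline)
and a replicate identifier.  Abundances are consumed as deposited: strictly
positive, already normalized, no log transform.

Per probeset and timepoint the pipeline needs two proxies:

* the arithmetic **mean** of replicate abundances (expression level), and
* the **coefficient of variation** ``CV = sd / mean`` (expression
  heterogeneity), with the sample (``n-1``) standard deviation by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SummaryTable",
    "read_expression_table",
    "read_sample_metadata",
    "summarize",
    "write_summary_table",
    "read_summary_table",
    "write_expression_table",
]

#: decimal precision used when writing summary tables; read-back reproduces
#: the table exactly at this precision.
SUMMARY_DECIMALS = 10

_SUMMARY_COLUMNS = ["probeset", "timepoint_day", "mean", "cv", "n"]


@dataclass
class ExpressionMatrix:
    """Replicate-level abundances plus sample -> (timepoint, replicate) map.

    Parameters
    ----------
    values
        DataFrame indexed by probeset id, one column per sample.  Missing
        cells (NaN) are permitted; present values must be finite and >= 0.
    samples
        DataFrame indexed by sample id with columns ``timepoint_day``
        (non-negative float) and ``replicate_id`` (string).  Must cover the
        value columns exactly, in order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "probeset"
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probeset ids: {dups}")
        if list(self.values.columns) != list(self.samples.index):
            missing = set(self.values.columns) - set(self.samples.index)
            raise ValueError(
                f"sample metadata does not match value columns; samples "
                f"without metadata: {sorted(missing)}"
            )
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        tp = self.samples["timepoint_day"].to_numpy(dtype=float)
        if not np.all(np.isfinite(tp)) or np.any(tp < 0):
            raise ValueError("timepoint_day must be finite and >= 0")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if not np.all(np.isfinite(arr[present])):
            raise ValueError("non-finite expression value present")
        if np.any(arr[present] < 0):
            raise ValueError("negative expression value present")
        counts = self.samples.groupby("timepoint_day").size()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                f"each timepoint needs >= 2 samples; offending days: "
                f"{thin.index.tolist()}"
            )

    @property
    def probeset_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique timepoint days."""
        return np.sort(self.samples["timepoint_day"].unique())

    def columns_at(self, day: float) -> list[str]:
        """Sample ids measured at nominal day ``day``."""
        mask = self.samples["timepoint_day"] == day
        return self.samples.index[mask].tolist()


@dataclass
class SummaryTable:
    """Per (probeset, timepoint) mean, CV and replicate count, long format.

    ``data`` columns: probeset, timepoint_day, mean, cv, n.  Rows are kept
    sorted by (timepoint_day, probeset order of first appearance).
    """

    data: pd.DataFrame
    ddof: int = 1
    _wide_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in _SUMMARY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"summary table missing columns: {missing}")
        self.data = self.data.loc[:, _SUMMARY_COLUMNS].reset_index(drop=True)
        if len(self.data):
            if (self.data["mean"] <= 0).any():
                raise ValueError("summary means must be > 0")
            if (self.data["cv"] < 0).any():
                raise ValueError("summary CVs must be >= 0")
            if (self.data["n"] < 2).any():
                raise ValueError("summary replicate counts must be >= 2")
            self.data = self.data.sort_values(
                ["timepoint_day", "probeset"], kind="stable"
            ).reset_index(drop=True)

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["timepoint_day"].unique())

    def wide(self, stat: str) -> pd.DataFrame:
        """Pivot to probesets x timepoints for ``stat`` in {mean, cv, n}."""
        if stat not in self._wide_cache:
            self._wide_cache[stat] = self.data.pivot(
                index="probeset", columns="timepoint_day", values=stat
            )
        return self._wide_cache[stat]

    def column(self, stat: str, day: float) -> pd.Series:
        """One statistic at one timepoint, indexed by probeset."""
        w = self.wide(stat)
        if day not in w.columns:
            raise KeyError(f"timepoint day {day} not in summary")
        return w[day]


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, timepoint_day, replicate_id)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate_id": str})
    required = {"sample_id", "timepoint_day", "replicate_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {path} missing columns: {sorted(missing)}")
    meta["timepoint_day"] = meta["timepoint_day"].astype(float)
    return meta.set_index("sample_id")


def read_expression_table(
    path: str | Path, metadata: str | Path | pd.DataFrame
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix plus sample metadata.

    The matrix has probeset ids in the first column and one column per
    sample.  ``metadata`` is a path to (or pre-loaded frame of) the sample
    annotation TSV mapping each sample to its timepoint day and replicate.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probeset ids in {path}: {dups}")
    bad = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(values[col], errors="coerce")
            culprit = values.index[coerced.isna() & values[col].notna()]
            if len(culprit):
                raise ValueError(
                    f"non-numeric cell at probeset {culprit[0]!r}, "
                    f"sample {col!r} in {path}"
                )
        values = values.apply(pd.to_numeric)
    if isinstance(metadata, (str, Path)):
        meta = read_sample_metadata(metadata)
    else:
        meta = metadata
    meta = meta.reindex(values.columns)
    if meta["timepoint_day"].isna().any():
        orphans = meta.index[meta["timepoint_day"].isna()].tolist()
        raise ValueError(f"samples with no metadata: {orphans}")
    mat = ExpressionMatrix(values=values, samples=meta)
    logger.info(
        "read expression table: %d probesets, %d samples, %d timepoints",
        len(mat.probeset_ids), len(mat.samples), len(mat.timepoints),
    )
    return mat


def summarize(matrix: ExpressionMatrix, ddof: int = 1) -> SummaryTable:
    """Compute per (probeset, timepoint) mean, CV and replicate count.

    Missing replicate values are dropped per cell; a cell with fewer than
    two remaining values, or a non-positive mean, is an error (CV would be
    undefined).  ``ddof=1`` gives the sample standard deviation (default);
    ``ddof=0`` the population variant.
    """
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    frames = []
    for day in matrix.timepoints:
        cols = matrix.columns_at(day)
        block = matrix.values[cols].to_numpy(dtype=float)
        n = np.sum(~np.isnan(block), axis=1)
        if np.any(n < 2):
            pid = matrix.probeset_ids[np.argmax(n < 2)]
            raise ValueError(
                f"fewer than 2 replicate values for probeset {pid!r} at "
                f"day {day}"
            )
        mean = np.nanmean(block, axis=1)
        if np.any(mean <= 0):
            pid = matrix.probeset_ids[np.argmax(mean <= 0)]
            raise ValueError(f"non-positive mean for probeset {pid!r} at day {day}")
        sd = np.nanstd(block, axis=1, ddof=ddof)
        frames.append(
            pd.DataFrame(
                {
                    "probeset": matrix.probeset_ids,
                    "timepoint_day": day,
                    "mean": mean,
                    "cv": sd / mean,
                    "n": n,
                }
            )
        )
    return SummaryTable(pd.concat(frames, ignore_index=True), ddof=ddof)


def write_summary_table(summary: SummaryTable, path: str | Path) -> None:
    """Write a summary as long-format TSV, rows sorted by timepoint then id."""
    out = summary.data.copy()
    for col in ("mean", "cv"):
        out[col] = out[col].astype(float).round(SUMMARY_DECIMALS)
    out.to_csv(path, sep="\t", index=False, float_format=f"%.{SUMMARY_DECIMALS}g")


def write_expression_table(
    matrix: ExpressionMatrix, values_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a matrix and its sample metadata in the TSV dialect read back
    by :func:`read_expression_table`."""
    matrix.values.to_csv(values_path, sep="\t", index_label="probeset")
    matrix.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_summary_table(path: str | Path) -> SummaryTable:
    """Read back a TSV produced by :func:`write_summary_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"probeset": str})
    df["timepoint_day"] = df["timepoint_day"].astype(float)
    return SummaryTable(df)
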