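"""CV fold-change gene prioritization and ranked-list export.

Probesets are ranked by the monotonicity-corrected log2 CV fold change
between 1 and 1.5 days post-amputation.  The raw fold change
``log2(CV_T1.5 / CV_T1)`` is kept only for probesets whose heterogeneity
change is a clear tendency shift within the 0.5-2 day window — both early
CVs (0.5 d, 1 d) strictly above both late CVs (1.5 d, 2 d), or strictly
below — and set to 0 otherwise (erratic fluctuation).  The resulting list,
most negative first, feeds external ranked-list enrichment tools; matched
randomized lists provide their negative controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SummaryTable

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "cv_foldchange",
    "export_ranked_gene_list",
    "make_random_lists",
    "read_gene_mapping",
]


@dataclass
class RankedList:
    """Per-probeset fold changes and the resulting rank order.

    ``data`` columns: probeset, raw_log2fc, corrected_log2fc, rank,
    undefined_ratio (True where a zero CV made the raw ratio undefined).
    Rank 1 is the most negative corrected value; ties keep input order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        ranks = np.sort(self.data["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.data) + 1)):
            raise ValueError("rank must be a permutation of 1..n")

    @property
    def in_rank_order(self) -> pd.DataFrame:
        return self.data.sort_values("rank", kind="stable").reset_index(drop=True)


def cv_foldchange(
    summary: SummaryTable,
    t_pre: float = 1.0,
    t_post: float = 1.5,
    window: tuple[float, float] = (0.5, 2.0),
) -> RankedList:
    """Monotonicity-corrected log2 CV fold change between two timepoints.

    The window condition compares the early CV pair (window start, t_pre)
    against the late pair (t_post, window end) with strict inequalities;
    equality in either direction zeroes the corrected value.  A degenerate
    window equal to (t_pre, t_post) reduces the condition to the two CVs
    simply differing.
    """
    for day in {window[0], t_pre, t_post, window[1]}:
        if day not in summary.timepoints:
            raise ValueError(f"timepoint day {day} missing from summary")
    cv_w0 = summary.column("cv", window[0])
    cv_pre = summary.column("cv", t_pre).reindex(cv_w0.index)
    cv_post = summary.column("cv", t_post).reindex(cv_w0.index)
    cv_w1 = summary.column("cv", window[1]).reindex(cv_w0.index)

    early = np.column_stack([cv_w0.to_numpy(), cv_pre.to_numpy()])
    late = np.column_stack([cv_post.to_numpy(), cv_w1.to_numpy()])
    monotone = (early.min(axis=1) > late.max(axis=1)) | (
        early.max(axis=1) < late.min(axis=1)
    )

    pre = cv_pre.to_numpy()
    post = cv_post.to_numpy()
    undefined = (pre <= 0) | (post <= 0)
    raw = np.full(pre.shape, np.nan)
    ok = ~undefined
    raw[ok] = np.log2(post[ok] / pre[ok])
    corrected = np.where(monotone & ok, raw, 0.0)

    order = np.argsort(corrected, kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    return RankedList(
        pd.DataFrame(
            {
                "probeset": cv_w0.index.to_numpy(),
                "raw_log2fc": raw,
                "corrected_log2fc": corrected,
                "rank": rank,
                "undefined_ratio": undefined,
            }
        )
    )


def read_gene_mapping(path: str | Path) -> pd.DataFrame:
    """Read a two-column probeset -> gene-symbol TSV (no header)."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed mapping row at line {line_no}")
            rows.append(parts)
    return pd.DataFrame(rows, columns=["probeset", "gene_symbol"])


def export_ranked_gene_list(
    ranking: RankedList,
    mapping: pd.DataFrame | str | Path,
    path: str | Path,
) -> int:
    """Write one gene symbol per line in rank order; returns genes written.

    Probesets without a mapped gene are dropped (count logged); a gene hit
    by several probesets is emitted once at its best (earliest) rank, since
    ranked-list enrichment weights the top of the list.
    """
    if isinstance(mapping, (str, Path)):
        mapping = read_gene_mapping(mapping)
    ordered = ranking.in_rank_order
    merged = ordered.merge(
        mapping.drop_duplicates("probeset"), on="probeset", how="left"
    )
    unmapped = merged["gene_symbol"].isna().sum()
    mapped = merged.dropna(subset=["gene_symbol"])
    if mapped.empty:
        raise ValueError("mapping covers no ranked probeset")
    genes = mapped.drop_duplicates("gene_symbol", keep="first")["gene_symbol"]
    if unmapped:
        logger.info("dropped %d probesets with no gene mapping", unmapped)
    Path(path).write_text("\n".join(genes) + "\n")
    return len(genes)


def make_random_lists(
    ranking: RankedList, n_lists: int = 10, seed: int = 0
) -> list[RankedList]:
    """Independent uniform re-rankings of all probesets (negative controls)."""
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_lists, dtype=np.uint32)
    out = []
    n = len(ranking.data)
    for s in seeds:
        rng = np.random.Generator(np.random.PCG64(int(s % (2 ** 31))))
        df = ranking.data.copy()
        df["rank"] = rng.permutation(n) + 1
        out.append(RankedList(df))
    return out
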