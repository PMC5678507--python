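"""Monte-Carlo Wilcoxon (MCW) bias indexes for paired expression measures.

For a paired contrast of one post-amputation timepoint (TX) against the
amputation-day baseline (T0), the **gene expression bias index** is a
normalized Wilcoxon sum of signed ranks computed over *all* probesets:

    d_i   = x_i(TX) - x_i(T0)
    W     = sum_i sgn(d_i) * rank(|d_i|)      (midranks for ties)
    W_max = n (n + 1) / 2
    GEBI  = W / W_max  in [-1, 1]

``cvGEBI`` uses the per-probeset CV (heterogeneity), ``mGEBI`` the mean
(level).  GEBI = +1 (-1) means the measure rose (fell) post-amputation for
every probeset.  Zero differences keep their rank (they count toward
``W_max``) but contribute sign 0, so the index stays normalized over the
full probeset set.

Significance is assessed by recomputing the index under Monte-Carlo
rearrangements of the measure.  Four null designs simulate different
explanations of an observed bias:

``unrestricted``
    pool the 2n values of the comparison and deal them back at random —
    pure chance.
``timepoint_restricted``
    shuffle values independently within the T0 column and within the TX
    column — preserves each timepoint's marginal distribution, i.e. the
    effect of factors acting on the transcriptome as a whole.
``expression_restricted_2dp`` / ``expression_restricted_3dp``
    shuffle only within bins of cells whose abundance *mean* rounds to the
    same 2 (3) decimals — preserves the mean-CV coupling, i.e. the effect
    of expression-level changes.
``functionally_restricted``
    recompute the index for a tagged gene subset after randomly
    reassigning the subset tag across the whole probeset universe.

Empirical p-values are the plain fractions of simulated indexes >= (upper)
or <= (lower) the observed one; bias-corrected ``(k+1)/(N+1)`` variants are
reported alongside but the headline significance calls use the plain
fractions with the ``p < 0.05`` rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import SummaryTable

__all__ = [
    "DESIGNS",
    "PairedMeasure",
    "BinAssignment",
    "GEBIResult",
    "ComparisonSeries",
    "compute_gebi",
    "gebi_rows",
    "make_expression_bins",
    "permutation_test",
    "run_series",
    "read_gmt",
    "read_id_list",
]

DESIGNS = (
    "unrestricted",
    "timepoint_restricted",
    "expression_restricted_2dp",
    "expression_restricted_3dp",
    "functionally_restricted",
)

#: permutations are simulated in blocks of this many draws to bound memory.
_CHUNK = 512


@dataclass
class PairedMeasure:
    """One TX-vs-T0 contrast of a per-probeset measure (CV or mean)."""

    probeset_ids: np.ndarray
    value_t0: np.ndarray
    value_tx: np.ndarray
    measure_kind: str  # "cv" | "mean"
    tx_day: float

    def __post_init__(self) -> None:
        self.value_t0 = np.asarray(self.value_t0, dtype=float)
        self.value_tx = np.asarray(self.value_tx, dtype=float)
        self.probeset_ids = np.asarray(self.probeset_ids)
        if not (len(self.probeset_ids) == len(self.value_t0) == len(self.value_tx)):
            raise ValueError("probeset_ids, value_t0, value_tx lengths differ")
        if self.measure_kind not in ("cv", "mean"):
            raise ValueError(f"unknown measure_kind {self.measure_kind!r}")
        if len(self.value_t0) and not (
            np.all(np.isfinite(self.value_t0)) and np.all(np.isfinite(self.value_tx))
        ):
            raise ValueError("non-finite measure value")

    @classmethod
    def from_summary(
        cls, summary: SummaryTable, measure_kind: str, tx_day: float,
        t0_day: float = 0.0,
    ) -> "PairedMeasure":
        t0 = summary.column(measure_kind, t0_day)
        tx = summary.column(measure_kind, tx_day)
        tx = tx.reindex(t0.index)
        if t0.isna().any() or tx.isna().any():
            raise ValueError(f"missing {measure_kind} values for comparison day {tx_day}")
        return cls(t0.index.to_numpy(), t0.to_numpy(), tx.to_numpy(),
                   measure_kind, float(tx_day))


@dataclass
class BinAssignment:
    """Exchangeability bins for the expression-restricted designs.

    Each of the 2n cells of a comparison (n probesets x {T0, TX}) carries an
    integer bin code derived from its abundance mean rounded to ``decimals``
    digits; a permutation may only move values between cells sharing a
    code.  Bins span both columns unless ``within_timepoint`` was set.
    """

    codes_t0: np.ndarray
    codes_tx: np.ndarray
    decimals: int
    tx_day: float
    within_timepoint: bool = False

    @property
    def n_bins(self) -> int:
        return len(np.unique(np.concatenate([self.codes_t0, self.codes_tx])))

    def size_histogram(self) -> pd.Series:
        """Histogram of bin sizes (cells per bin) -> number of bins."""
        _, counts = np.unique(
            np.concatenate([self.codes_t0, self.codes_tx]), return_counts=True
        )
        return pd.Series(counts).value_counts().sort_index()


@dataclass
class GEBIResult:
    """Observed index, its Monte-Carlo null sample and empirical p-values."""

    tx_day: float
    measure_kind: str
    design: str
    n: int
    observed_w: float
    w_max: float
    observed_gebi: float
    simulated_gebis: np.ndarray
    p_upper: float
    p_lower: float
    p_upper_corrected: float
    p_lower_corrected: float
    n_perm: int
    seed: int

    @property
    def significant_lower(self) -> bool:
        return self.p_lower < 0.05

    @property
    def significant_upper(self) -> bool:
        return self.p_upper < 0.05


@dataclass
class ComparisonSeries:
    """Ordered GEBI results across post-amputation timepoints (one design)."""

    results: list[GEBIResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [r.tx_day for r in self.results]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("tx_days must be strictly increasing")
        if len({(r.design, r.measure_kind, r.n_perm) for r in self.results}) > 1:
            raise ValueError("series mixes designs, measures or n_perm")

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def tx_days(self) -> np.ndarray:
        return np.array([r.tx_day for r in self.results])

    @property
    def observed(self) -> np.ndarray:
        return np.array([r.observed_gebi for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        """One row per comparison with simulated-sample percentile summaries."""
        rows = []
        for r in self.results:
            sims = r.simulated_gebis
            rows.append(
                {
                    "tx_day": r.tx_day,
                    "design": r.design,
                    "measure_kind": r.measure_kind,
                    "n": r.n,
                    "observed_w": r.observed_w,
                    "observed_gebi": r.observed_gebi,
                    "p_upper": r.p_upper,
                    "p_lower": r.p_lower,
                    "sim_min": sims.min(),
                    "sim_p5": float(np.percentile(sims, 5)),
                    "sim_p95": float(np.percentile(sims, 95)),
                    "sim_max": sims.max(),
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# index computation

def gebi_rows(delta: np.ndarray) -> np.ndarray:
    """Vectorized GEBI over rows of a (m, n) matrix of paired differences."""
    delta = np.atleast_2d(delta)
    n = delta.shape[1]
    ranks = rankdata(np.abs(delta), axis=1, method="average")
    w = np.einsum("ij,ij->i", np.sign(delta), ranks)
    return w / (n * (n + 1) / 2.0)


def compute_gebi(
    pairs: PairedMeasure | None = None,
    value_t0: Sequence[float] | None = None,
    value_tx: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Return ``(W, W_max, GEBI)`` for one paired contrast.

    Accepts either a :class:`PairedMeasure` or two aligned value arrays.
    Ties in |d| receive midranks; zero differences contribute sign 0 but
    occupy a rank, keeping ``W_max = n(n+1)/2`` exact.
    """
    if pairs is not None:
        t0, tx = pairs.value_t0, pairs.value_tx
    else:
        t0 = np.asarray(value_t0, dtype=float)
        tx = np.asarray(value_tx, dtype=float)
    if t0.size == 0:
        raise ValueError("need >= 1 probeset")
    if not (np.all(np.isfinite(t0)) and np.all(np.isfinite(tx))):
        raise ValueError("non-finite value")
    delta = tx - t0
    ranks = rankdata(np.abs(delta), method="average")
    w = float(np.sum(np.sign(delta) * ranks))
    n = delta.size
    w_max = n * (n + 1) / 2.0
    return w, w_max, w / w_max


# ---------------------------------------------------------------------------
# null-design draws (each yields per-draw (t0, tx) column pairs)

def draw_unrestricted(
    t0: np.ndarray, tx: np.ndarray, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pool the 2n values and deal them back to cells uniformly at random."""
    n = t0.size
    pooled = np.concatenate([t0, tx])
    idx = np.argsort(rng.random((m, 2 * n)), axis=1)
    shuffled = pooled[idx]
    return shuffled[:, :n], shuffled[:, n:]


def draw_timepoint_restricted(
    t0: np.ndarray, tx: np.ndarray, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle within the T0 column and within the TX column independently."""
    n = t0.size
    new_t0 = t0[np.argsort(rng.random((m, n)), axis=1)]
    new_tx = tx[np.argsort(rng.random((m, n)), axis=1)]
    return new_t0, new_tx


def draw_expression_restricted(
    t0: np.ndarray, tx: np.ndarray, m: int, rng: np.random.Generator,
    bins: BinAssignment,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle values only among cells sharing an expression bin."""
    n = t0.size
    pooled = np.concatenate([t0, tx])
    codes = np.concatenate([bins.codes_t0, bins.codes_tx]).astype(np.int64)
    order = np.argsort(codes, kind="stable")  # cells grouped by bin
    grouped_vals = pooled[order]
    # sorting (code + U[0,1) key) shuffles cells uniformly within each bin
    keys = codes[order][None, :] + rng.random((m, 2 * n))
    within = np.argsort(keys, axis=1)
    new_pooled = np.empty((m, 2 * n))
    new_pooled[:, order] = grouped_vals[within]
    return new_pooled[:, :n], new_pooled[:, n:]


def draw_subset_indices(
    n_universe: int, subset_size: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random same-size subsets of the probeset universe (tags
    rearranged over the whole dataset)."""
    keys = rng.random((m, n_universe))
    return np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]


def make_expression_bins(
    summary: SummaryTable,
    tx_day: float,
    decimals: int,
    t0_day: float = 0.0,
    rounding: str = "half_even",
    within_timepoint: bool = False,
    allow_any_decimals: bool = False,
) -> BinAssignment:
    """Bin comparison cells by their abundance mean rounded to ``decimals``.

    ``rounding="half_even"`` uses standard banker's rounding (default);
    ``rounding="ceil"`` rounds up to the given digit, kept for sensitivity
    analysis.  Bins normally span both columns of the comparison (a T0 cell
    may exchange with a TX cell of equal rounded mean);
    ``within_timepoint=True`` additionally stratifies by column.
    """
    if decimals not in (2, 3) and not allow_any_decimals:
        raise ValueError("decimals must be 2 or 3 (set allow_any_decimals to override)")
    mean_t0 = summary.column("mean", t0_day)
    mean_tx = summary.column("mean", tx_day).reindex(mean_t0.index)
    if rounding == "half_even":
        k0 = np.round(mean_t0.to_numpy(), decimals)
        kx = np.round(mean_tx.to_numpy(), decimals)
    elif rounding == "ceil":
        scale = 10.0 ** decimals
        k0 = np.ceil(mean_t0.to_numpy() * scale) / scale
        kx = np.ceil(mean_tx.to_numpy() * scale) / scale
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    keys = np.concatenate([k0, kx])
    if within_timepoint:
        # distinct code spaces per column: no cross-column exchange
        codes, _ = pd.factorize(
            pd.MultiIndex.from_arrays(
                [np.repeat([0, 1], len(k0)), keys]
            )
        )
    else:
        codes, _ = pd.factorize(keys)
    n = len(k0)
    return BinAssignment(
        codes_t0=codes[:n], codes_tx=codes[n:], decimals=decimals,
        tx_day=float(tx_day), within_timepoint=within_timepoint,
    )


# ---------------------------------------------------------------------------
# permutation test

def _empirical_pvalues(
    observed: float, sims: np.ndarray
) -> tuple[float, float, float, float]:
    n = sims.size
    k_up = int(np.sum(sims >= observed))
    k_lo = int(np.sum(sims <= observed))
    return k_up / n, k_lo / n, (k_up + 1) / (n + 1), (k_lo + 1) / (n + 1)


def permutation_test(
    pairs: PairedMeasure,
    design: str,
    n_perm: int,
    seed: int,
    bins: BinAssignment | None = None,
    subset: Iterable[str] | None = None,
    universe: PairedMeasure | None = None,
) -> GEBIResult:
    """Assess an observed GEBI against one Monte-Carlo null design.

    For the expression-restricted designs ``bins`` must be supplied (see
    :func:`make_expression_bins`); for the functionally-restricted design
    ``pairs`` is ignored as data and ``subset`` (probeset ids) plus
    ``universe`` (the full-dataset contrast) define the test.  Identical
    seeds yield identical results.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))

    if design == "functionally_restricted":
        if subset is None or universe is None:
            raise ValueError("functionally_restricted needs subset and universe")
        subset = set(subset)
        if not subset:
            raise ValueError("subset is empty")
        uni_ids = universe.probeset_ids
        mask = np.isin(uni_ids, list(subset))
        if mask.sum() != len(subset):
            missing = subset - set(map(str, uni_ids))
            raise ValueError(f"subset ids not in universe: {sorted(missing)[:5]}")
        delta_all = universe.value_tx - universe.value_t0
        obs_w, w_max, obs = compute_gebi(
            value_t0=universe.value_t0[mask], value_tx=universe.value_tx[mask]
        )
        n = int(mask.sum())
        sims = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(_CHUNK, n_perm - done)
            idx = draw_subset_indices(delta_all.size, n, m, rng)
            sims[done:done + m] = gebi_rows(delta_all[idx])
            done += m
        tx_day, measure = universe.tx_day, universe.measure_kind
    else:
        t0, tx = pairs.value_t0, pairs.value_tx
        obs_w, w_max, obs = compute_gebi(pairs)
        n = t0.size
        if design in ("expression_restricted_2dp", "expression_restricted_3dp"):
            if bins is None:
                raise ValueError(f"{design} needs a BinAssignment")
            expected = 2 if design.endswith("2dp") else 3
            if bins.decimals != expected:
                raise ValueError(
                    f"bins built at {bins.decimals} decimals but design is {design}"
                )
        sims = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(_CHUNK, n_perm - done)
            if design == "unrestricted":
                a, b = draw_unrestricted(t0, tx, m, rng)
            elif design == "timepoint_restricted":
                a, b = draw_timepoint_restricted(t0, tx, m, rng)
            else:
                a, b = draw_expression_restricted(t0, tx, m, rng, bins)
            sims[done:done + m] = gebi_rows(b - a)
            done += m
        tx_day, measure = pairs.tx_day, pairs.measure_kind

    p_up, p_lo, p_up_c, p_lo_c = _empirical_pvalues(obs, sims)
    return GEBIResult(
        tx_day=tx_day, measure_kind=measure, design=design, n=n,
        observed_w=obs_w, w_max=w_max, observed_gebi=obs,
        simulated_gebis=sims, p_upper=p_up, p_lower=p_lo,
        p_upper_corrected=p_up_c, p_lower_corrected=p_lo_c,
        n_perm=n_perm, seed=seed,
    )


def comparison_seeds(master_seed: int, n_comparisons: int) -> list[int]:
    """Deterministic per-comparison seeds from one master seed.

    Uses the SeedSequence counter stream of the master seed so any single
    comparison can be rerun in isolation with its reported seed.
    """
    state = np.random.SeedSequence(master_seed).generate_state(
        n_comparisons, dtype=np.uint32
    )
    return [int(s % (2 ** 31)) for s in state]


def run_series(
    summary: SummaryTable,
    measure_kind: str,
    design: str,
    n_perm: int,
    seed: int,
    subset: Iterable[str] | None = None,
    rounding: str = "half_even",
    within_timepoint_bins: bool = False,
) -> ComparisonSeries:
    """One GEBI permutation test per post-amputation timepoint, in day order.

    The day-0 baseline must be present.  Per-comparison seeds derive
    deterministically from ``seed`` (see :func:`comparison_seeds`).
    """
    days = summary.timepoints
    if 0.0 not in days:
        raise ValueError("summary has no day-0 baseline")
    post = [d for d in days if d > 0]
    if not post:
        raise ValueError("summary has no post-amputation timepoint")
    seeds = comparison_seeds(seed, len(post))
    results = []
    for day, sub_seed in zip(post, seeds):
        pairs = PairedMeasure.from_summary(summary, measure_kind, day)
        bins = None
        kwargs: dict = {}
        if design in ("expression_restricted_2dp", "expression_restricted_3dp"):
            bins = make_expression_bins(
                summary, day, 2 if design.endswith("2dp") else 3,
                rounding=rounding, within_timepoint=within_timepoint_bins,
            )
        if design == "functionally_restricted":
            if subset is None:
                raise ValueError("functionally_restricted series needs a subset")
            kwargs = {"subset": subset, "universe": pairs}
        results.append(
            permutation_test(pairs, design, n_perm, sub_seed, bins=bins, **kwargs)
        )
    return ComparisonSeries(results)


# ---------------------------------------------------------------------------
# gene-set inputs

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <TAB> description <TAB> member ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT row needs >= 3 fields")
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line subset membership file."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
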