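import numpy as np
import pandas as pd
import pytest

from regenhet.io import ExpressionMatrix, SummaryTable, summarize


def make_matrix(values: np.ndarray, days: list[float], reps_per_day: int,
                probesets: list[str] | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a (probesets x samples) array laid out
    day-major (all replicates of day 0, then day 1, ...)."""
    n, m = values.shape
    assert m == len(days) * reps_per_day
    sample_ids, meta = [], []
    for d in days:
        for r in range(reps_per_day):
            sid = f"d{d:g}_r{r + 1}"
            sample_ids.append(sid)
            meta.append((sid, float(d), f"r{r + 1}"))
    probesets = probesets or [f"p{i}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probesets, columns=sample_ids),
        samples=pd.DataFrame(
            meta, columns=["sample_id", "timepoint_day", "replicate_id"]
        ).set_index("sample_id"),
    )


def make_summary(probesets, days, means, cvs, n=10) -> SummaryTable:
    """Build a SummaryTable from per-day mean/cv arrays (days x probesets)."""
    rows = []
    for di, d in enumerate(days):
        for pi, p in enumerate(probesets):
            rows.append(
                {"probeset": p, "timepoint_day": float(d),
                 "mean": means[di][pi], "cv": cvs[di][pi], "n": n}
            )
    return SummaryTable(pd.DataFrame(rows))


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 probesets x 4 samples: 2 timepoints (0, 1) x 2 replicates."""
    values = np.array(
        [
            [2.0, 4.0, 6.0, 6.0],
            [5.0, 5.0, 1.0, 3.0],
            [1.0, 2.0, 2.0, 4.0],
        ]
    )
    return make_matrix(values, days=[0.0, 1.0], reps_per_day=2)


@pytest.fixture
def toy_summary(toy_matrix) -> SummaryTable:
    return summarize(toy_matrix)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(20251001))
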