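"""Synthetic replicate-level expression data with known ground truth.

The generator emulates the structure the analysis assumes in a bulk
regeneration time course: ~20 ordered timepoints from a day-0 amputation
baseline out to 28 days, 9-10 biological replicates per timepoint, strictly
positive abundances, and a negative mean-CV coupling
(``CV_base = c0 * mean^-beta``).  Configurable *effects* multiply the
target mean and/or CV of a random probeset subset from an onset day
onwards — e.g. a dedifferentiation-like CV reduction or a global
expression-level shift — and per-replicate developmental asynchrony jitters
each animal's effective day, shared across all probesets of that replicate
(whole-animal stage noise, which is what makes within-timepoint nulls
explanatory).

Values are drawn from a gamma law parameterized by the target mean m and
target CV c (shape ``1/c^2``, scale ``m c^2``) so the first two moments are
exact by construction; the emitted :class:`SimulationTruth` records every
target and membership for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["Effect", "SimulationConfig", "SimulationTruth", "simulate", "preset",
           "PRESETS"]

#: 20-point day grid: dense over the first two days, then coarsening to 28.
DEFAULT_DAYS = (
    0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0,
    9.0, 11.0, 13.0, 15.0, 17.0, 19.0, 21.0, 24.0, 26.0, 28.0,
)

PRESETS = ("null", "dediff", "level_shift", "asynchrony_stress")


@dataclass(frozen=True)
class Effect:
    """A step change in target mean and/or CV for a probeset subset.

    Active for a replicate when its effective day (nominal day plus
    asynchrony offset) is at or past ``onset_day``.
    """

    name: str
    probeset_fraction: float
    onset_day: float
    cv_multiplier: float = 1.0
    mean_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probeset_fraction <= 1.0:
            raise ValueError(f"effect {self.name!r}: probeset_fraction not in [0,1]")
        if self.cv_multiplier <= 0 or self.mean_multiplier <= 0:
            raise ValueError(f"effect {self.name!r}: multipliers must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_probesets: int = 2000
    timepoint_days: tuple[float, ...] = DEFAULT_DAYS
    replicates_per_timepoint: int | tuple[int, ...] = 10
    seed: int = 0
    #: lognormal law of baseline means: (mu, sigma) on the log scale
    baseline_mean_law: tuple[float, float] = (2.0, 1.0)
    #: (c0, beta) in CV_base = c0 * mean^(-beta)
    cv_coupling: tuple[float, float] = (0.25, 0.15)
    effects: tuple[Effect, ...] = ()
    asynchrony_sd_days: float = 0.0
    #: tag -> probeset fraction (float) or explicit id tuple
    functional_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_probesets < 1:
            raise ValueError("n_probesets must be >= 1")
        days = tuple(float(d) for d in self.timepoint_days)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("timepoint_days must be >= 2 strictly increasing values")
        if self.asynchrony_sd_days < 0:
            raise ValueError("asynchrony_sd_days must be >= 0")
        if self.cv_coupling[0] <= 0:
            raise ValueError("cv_coupling c0 must be > 0")
        span = (min(days), max(days))
        for e in self.effects:
            if not span[0] <= e.onset_day <= span[1]:
                raise ValueError(
                    f"effect {e.name!r}: onset_day {e.onset_day} outside day grid"
                )
        reps = self.replicates_per_timepoint
        if isinstance(reps, int):
            if reps < 2:
                raise ValueError("replicates_per_timepoint must be >= 2")
        else:
            if len(reps) != len(days):
                raise ValueError("per-timepoint replicate list length mismatch")
            if any(r < 2 for r in reps):
                raise ValueError("replicates_per_timepoint entries must be >= 2")

    def replicates_at(self, day_index: int) -> int:
        reps = self.replicates_per_timepoint
        return reps if isinstance(reps, int) else reps[day_index]


@dataclass
class SimulationTruth:
    """Generator ground truth for parameter-recovery tests.

    ``probesets``: baseline mean/CV plus one boolean membership column per
    effect (``in_<name>``) and per functional tag (``tag_<name>``).
    ``offsets``: per-sample asynchrony offsets (days).  ``expected_signs``:
    per post-baseline day, the cvGEBI / mGEBI sign implied by the config
    (-1, 0 or +1).
    """

    config: SimulationConfig
    probesets: pd.DataFrame
    offsets: pd.DataFrame
    expected_signs: pd.DataFrame

    def members(self, effect_name: str) -> np.ndarray:
        return self.probesets.index[self.probesets[f"in_{effect_name}"]].to_numpy()

    def tagged(self, tag: str) -> np.ndarray:
        return self.probesets.index[self.probesets[f"tag_{tag}"]].to_numpy()


def _direction(multipliers: list[float]) -> int:
    prod = float(np.prod(multipliers)) if multipliers else 1.0
    return 0 if prod == 1.0 else (1 if prod > 1.0 else -1)


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw a replicate-level matrix plus its ground truth, deterministically."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    n = config.n_probesets
    days = tuple(float(d) for d in config.timepoint_days)

    mu, sigma = config.baseline_mean_law
    base_mean = rng.lognormal(mean=mu, sigma=sigma, size=n)
    c0, beta = config.cv_coupling
    base_cv = c0 * base_mean ** (-beta)
    probeset_ids = np.array([f"ps{i:05d}" for i in range(n)])

    truth_cols: dict = {"baseline_mean": base_mean, "baseline_cv": base_cv}
    memberships = {}
    for e in config.effects:
        size = int(round(e.probeset_fraction * n))
        members = np.zeros(n, dtype=bool)
        members[rng.choice(n, size=size, replace=False)] = True
        memberships[e.name] = members
        truth_cols[f"in_{e.name}"] = members
    for tag, spec_val in config.functional_tags.items():
        tagged = np.zeros(n, dtype=bool)
        if isinstance(spec_val, float):
            size = int(round(spec_val * n))
            tagged[rng.choice(n, size=size, replace=False)] = True
        else:
            tagged[np.isin(probeset_ids, np.asarray(spec_val))] = True
        truth_cols[f"tag_{tag}"] = tagged

    sample_ids, meta_rows, offset_rows, columns = [], [], [], []
    for di, day in enumerate(days):
        n_rep = config.replicates_at(di)
        for r in range(n_rep):
            eps = (
                float(rng.normal(0.0, config.asynchrony_sd_days))
                if config.asynchrony_sd_days > 0
                else 0.0
            )
            t_eff = day + eps
            mean_t = base_mean.copy()
            cv_t = base_cv.copy()
            for e in config.effects:
                if t_eff >= e.onset_day:
                    m = memberships[e.name]
                    mean_t[m] *= e.mean_multiplier
                    cv_t[m] *= e.cv_multiplier
            shape = 1.0 / cv_t ** 2
            scale = mean_t * cv_t ** 2
            values = rng.gamma(shape=shape, scale=scale)
            sid = f"d{day:g}_r{r + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append((sid, day, f"r{r + 1:02d}"))
            offset_rows.append((sid, day, f"r{r + 1:02d}", eps))
            columns.append(values)

    values_df = pd.DataFrame(
        np.column_stack(columns), index=probeset_ids, columns=sample_ids
    )
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "timepoint_day", "replicate_id"]
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values=values_df, samples=samples)

    sign_rows = []
    for day in days[1:]:
        cv_mults, mean_mults = [], []
        for e in config.effects:
            if day >= e.onset_day and e.probeset_fraction > 0:
                cv_mults.append(e.cv_multiplier)
                mean_mults.append(e.mean_multiplier)
        sign_rows.append(
            {
                "tx_day": day,
                "cv_sign": _direction(cv_mults),
                "mean_sign": _direction(mean_mults),
            }
        )
    truth = SimulationTruth(
        config=config,
        probesets=pd.DataFrame(truth_cols, index=pd.Index(probeset_ids, name="probeset")),
        offsets=pd.DataFrame(
            offset_rows, columns=["sample_id", "timepoint_day", "replicate_id", "offset_days"]
        ).set_index("sample_id"),
        expected_signs=pd.DataFrame(sign_rows),
    )
    return matrix, truth


def preset(name: str, seed: int = 0, n_probesets: int = 2000) -> SimulationConfig:
    """Documented parameter sets used throughout the validation suites.

    ``null``
        no effects, no asynchrony — calibration baseline.
    ``dediff``
        CV halved for 60% of probesets from day 1.5 on (mean untouched):
        the dedifferentiation-like heterogeneity collapse.
    ``level_shift``
        mean x1.5 for 60% of probesets from day 2 on (CV untouched): a
        generalized expression increase without a heterogeneity change.
    ``asynchrony_stress``
        the ``dediff`` effect plus 0.5-day whole-animal stage jitter.
    """
    base = SimulationConfig(n_probesets=n_probesets, seed=seed)
    if name == "null":
        return base
    if name == "dediff":
        return replace(
            base,
            effects=(Effect("dediff", 0.6, 1.5, cv_multiplier=0.5),),
        )
    if name == "level_shift":
        return replace(
            base,
            effects=(Effect("level_shift", 0.6, 2.0, mean_multiplier=1.5),),
        )
    if name == "asynchrony_stress":
        return replace(
            base,
            effects=(Effect("dediff", 0.6, 1.5, cv_multiplier=0.5),),
            asynchrony_sd_days=0.5,
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
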