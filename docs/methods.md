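# Methods

## The statistic

The package quantifies transcriptome-wide biases in a paired per-probeset
measure between one post-amputation timepoint (TX) and the day-0 baseline
(T0). For n probesets with differences `d_i = x_i(TX) − x_i(T0)`, the gene
expression bias index is the normalized Wilcoxon sum of signed ranks

    W = Σ sgn(d_i)·rk(|d_i|),  W_max = n(n+1)/2,  GEBI = W / W_max.

Unlike the classical Wilcoxon signed-rank test, every probeset is kept:
ties in |d| receive midranks, and zero differences retain their rank (so
they count toward `W_max`) while contributing sign 0. This keeps the index
normalized over the full probeset set and exactly inside [−1, 1], with ±1
reached iff every difference is nonzero and of one sign. `cvGEBI` applies
the index to the per-probeset coefficient of variation across biological
replicates (heterogeneity proxy), `mGEBI` to the replicate mean (level
proxy). CVs use the sample (n−1) standard deviation by default — the
unbiased-variance convention at ~10 replicates; a `ddof=0` switch gives
the population variant. Abundances are consumed as deposited: positive,
already normalized, not log-transformed.

## Monte-Carlo null designs

Significance is assessed against GEBIs recomputed under random
rearrangements of the measure, per TX-vs-T0 comparison:

* **unrestricted** — the 2n values of the comparison are pooled and dealt
  back to cells uniformly at random. The permutation is confined to one
  comparison, not the whole time course.
* **timepoint-restricted** — independent uniform shuffles within the T0
  column and within the TX column. Each timepoint's value multiset is
  preserved exactly, so any transcriptome-wide shift survives the null;
  what is destroyed is the probeset pairing.
* **expression-restricted** — values may only exchange between cells whose
  abundance *mean* rounds to the same 2 or 3 decimals. Bins are built from
  comparison-specific means and span both columns (a T0 cell may swap with
  a TX cell of equal rounded mean); a `within_timepoint` switch stratifies
  bins by column, and a dataset-wide-mean variant can be obtained by
  passing a different summary. "Rounded" means standard half-even
  rounding; a `ceil` mode is retained for sensitivity analysis. Singleton
  bins keep their value.
* **functionally-restricted** — the observed index is computed on a tagged
  probeset subset; null draws reassign the tag uniformly over the whole
  universe (equivalently, same-size simple random subsets without
  replacement).

Empirical p-values are the plain fractions of simulated indexes ≥ (upper
tail) or ≤ (lower tail) the observed value, with significance called at
p < 0.05 per tail; the bias-corrected `(k+1)/(N+1)` fractions are reported
alongside but never drive the calls. No multiple-testing adjustment is
applied across the ~19 comparisons of a series — this mirrors the
procedure the pipeline reproduces and is a known limitation; users
combining calls across timepoints should account for it.

Reproducibility: one master seed per series; per-comparison seeds are the
SeedSequence counter stream of that seed (`comparison_seeds`), so any
single comparison can be rerun in isolation from its reported seed.
Permutations are simulated in blocks of 512 draws with vectorized ranking,
bounding memory at roughly `512 × 2n` doubles.

## PC_AUC

For each comparison the simulated index closest to the observed one
(minimum |sim − obs|) is the best the null design can do; the proportional
cumulative area under the curve at timepoint t is the running ratio
`Σ_{i≤t} closest_sim(i) / Σ_{i≤t} observed(i)` in day order — a
cumulative-sum construction, not a trapezoid integral. Equally close
simulated values tie-break to the smaller absolute value, negative first
at an exact symmetric tie: the conservative choice that attributes *less*
explanation to the null. Near-ties within floating-point rounding of the
distances are treated as ties. Points where the cumulative observed sum is
exactly zero are flagged undefined (NaN) rather than dropped; the final
cumulative value is the headline number.

## Replication subsampling

Per timepoint, k ∈ {3,4,5,6} replicate columns are drawn uniformly without
replacement (independently per timepoint — a replicate index is not
assumed to identify the same animal across timepoints), the summary is
recomputed, and Pearson r between full-replication and subsampled values
across probesets is recorded for the mean and the CV; one draw feeds both
statistics. Default 1,000 iterations. Degenerate zero-variance vectors
yield an undefined r that is recorded and counted, never silently
resampled. Five-number summaries per (timepoint, k, statistic) are the
exported surface.

## Prioritization

`log2(CV_T1.5 / CV_T1)` is computed per probeset and zeroed unless the CV
change is a clear tendency shift within the 0.5–2 day window: both early
CVs (0.5 d, 1 d) strictly above both late CVs (1.5 d, 2 d), or strictly
below. Equalities fail the condition in either direction. A zero CV makes
the raw ratio undefined; such probesets are flagged and their corrected
value set to 0. Ranking is by increasing corrected value (most negative —
strongest heterogeneity drop — first) with stable tie order. Gene-symbol
export deduplicates to the best rank, because downstream
minimum-hypergeometric tools weight the top of the list; probesets with no
mapped gene are dropped with a logged count. Randomized control lists are
independent uniform permutations of all probesets. The enrichment
computation itself is external; the package ships the two GO gene sets
used for functionally-restricted runs (`data/dediff_go_sets.gmt`:
GO:1903047 mitotic cell cycle process, GO:0006325 chromatin organization)
as a fixture.

## Synthetic data generator

The generator emulates the statistical skeleton of a replicated bulk
regeneration time course:

* **Grid**: 20 timepoints over 0–28 days, dense early (0, 0.5, 1, 1.5, 2)
  then coarsening; 10 replicates per timepoint (9 allowed per-timepoint).
* **Baselines**: per-probeset means are lognormal(μ=2, σ=1 on the log
  scale) — a decades-wide positive abundance distribution; baseline CVs
  follow the empirical negative mean-CV coupling as a power law
  `CV = c0·mean^−β` with c0=0.25, β=0.15, giving CVs of roughly 0.1–0.3.
* **Sampling law**: gamma parameterized by (mean m, CV c) — shape `1/c²`,
  scale `mc²` — positive support with the first two moments exact by
  construction. A lognormal alternative would match moments only
  approximately; gamma was chosen for exact control.
* **Effects**: step changes multiplying target mean and/or CV for a random
  probeset fraction from an onset day. Presets: `dediff` (CV ×0.5 for 60%
  of probesets from day 1.5 — the heterogeneity collapse), `level_shift`
  (mean ×1.5 for 60% from day 2 — expression increase with no
  heterogeneity change; gamma's mean/CV separation makes the two effects
  orthogonal by construction), `asynchrony_stress` (dediff plus jitter),
  `null`.
* **Asynchrony**: each replicate (animal) gets one Normal(0, sd) offset in
  days, shared across all probesets, added to its nominal day before
  effects are evaluated — whole-animal stage jitter, the ingredient that
  makes timepoint-restricted nulls partially explanatory, as staging
  imprecision is in real regeneration series. Default sd 0; 0.5 days in
  the stress preset.

What the generator does **not** emulate: probe-level microarray physics
and normalization artifacts, probeset cross-hybridization, correlated
gene-gene regulation, cell-type composition shifts, or heavy-tailed
outlier replicates. Passing tests on synthetic data therefore demonstrate
that the statistics recover the effects they are designed for under the
generator's assumptions — not that real tissue obeys those assumptions.
One consequence worth noting: with continuous lognormal means, rounding to
2 decimals leaves most expression bins as singletons, so the
expression-restricted null degenerates toward no-permutation on synthetic
data; on array data quantized to a few decimals the bins are populated.

## Validation problem sizes

The validation suites run the full chain at 2,000 probesets, 10
replicates and 1,000 permutations per comparison — sizes at which the
index's null standard deviation (≈ `sqrt(4/3n)` ≈ 0.026) is well below the
injected effect magnitudes (observed cvGEBI ≈ −0.7 for the dediff preset).
Type-I calibration uses 200 independent null comparisons against a 99%
binomial acceptance band; the subsampling study uses 200 draws per k on a
5-timepoint grid. Stochastic onset readouts report the *sustained* onset
(earliest day from which every later timepoint is significant), since
isolated 5%-level rejections are expected under the null.

## Error handling conventions

Duplicate probeset ids, unannotated samples, non-numeric cells,
non-positive means, and cells with fewer than two replicate values are
hard errors naming the offending row/column — never silent NaNs. A missing
day-0 baseline aborts a series. CLI exit codes: 0 success, 2 configuration
error, 3 data error; pipeline failures still write a manifest marking the
stages completed.
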