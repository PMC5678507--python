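# regenhet

Gene-expression **heterogeneity** dynamics in regenerating tissue, from
replicate-level expression tables.

When specialized cells dedifferentiate — as hypothesized for the blastema
that forms after salamander limb amputation — their chromatin relaxes
extensively, which should show up in bulk transcriptomics as a broad
*reduction in expression variability between biological replicates*.
`regenhet` implements the analysis chain needed to detect and dissect such
transcriptome-wide heterogeneity shifts in a replicated time course:

1. **Summaries** — per probeset and timepoint, the replicate mean
   (expression level) and coefficient of variation `CV = sd/mean`
   (expression heterogeneity).
2. **Monte-Carlo Wilcoxon (MCW) bias indexes** — for each post-amputation
   timepoint TX against the day-0 baseline T0, the gene expression bias
   index over all n probesets:

       d_i   = x_i(TX) − x_i(T0)
       W     = Σ_i sgn(d_i) · rk(|d_i|),   W_max = n(n+1)/2
       GEBI  = W / W_max  ∈ [−1, 1]

   (`cvGEBI` on CVs, `mGEBI` on means; midranks for ties; zero differences
   keep their rank but contribute sign 0). Significance comes from
   empirical p-values against 10,000 Monte-Carlo rearrangements under four
   null designs: **unrestricted** (pure chance), **timepoint-restricted**
   (whole-transcriptome factors), **expression-restricted** (mean-level
   coupling, values shuffled only within bins of equal rounded mean), and
   **functionally-restricted** (random reassignment of a gene-set tag).
3. **PC_AUC** — the cumulative sum of closest-to-observed simulated GEBIs
   divided by the cumulative sum of observed GEBIs: the fraction of the
   observed dynamics each null design can account for.
4. **Replication subsampling** — Pearson-r reproducibility of mean and CV
   when only k ∈ {3,4,5,6} of the available replicates are used (CV needs
   far more replication than the mean).
5. **Prioritization** — probesets ranked by the monotonicity-corrected
   `log2(CV_T1.5 / CV_T1)` fold change, exported as ranked gene lists for
   external enrichment tools, plus randomized control lists.
6. **Synthetic data** — a generator with known mean/CV trajectories,
   mean-CV coupling, step effects (CV reduction, level shift) and
   whole-animal developmental-asynchrony jitter, with full ground truth
   for parameter-recovery testing.

## Worked example

Simulate a regeneration time course in which 60% of 500 probesets halve
their CV from day 1.5 on, then test every timepoint against the day-0
baseline:

```python
from regenhet import preset, simulate, summarize, run_series
from regenhet.pcauc import pc_auc_curve

matrix, truth = simulate(preset("dediff", seed=1, n_probesets=500))
s = summarize(matrix)
series = run_series(s, "cv", "unrestricted", n_perm=1000, seed=1)
print(series.to_frame()[["tx_day", "observed_gebi", "p_lower",
                         "sim_p5", "sim_p95"]].head(6).to_string(index=False))
print("final PC_AUC (unrestricted):", round(pc_auc_curve(series).final_pc_auc, 3))
```

```
 tx_day  observed_gebi  p_lower    sim_p5  sim_p95
    0.5      -0.008287    0.425 -0.080639 0.088353
    1.0      -0.006802    0.440 -0.084473 0.086974
    1.5      -0.703521    0.000 -0.087874 0.078583
    2.0      -0.736255    0.000 -0.083044 0.084241
    3.0      -0.718834    0.000 -0.085515 0.088873
    4.0      -0.753900    0.000 -0.084558 0.084753
final PC_AUC (unrestricted): 0.228
```

Before the injected onset the cvGEBI sits inside the simulated 5th–95th
percentile band (no bias); from day 1.5 on it is strongly negative with
`p_lower < 0.05` — heterogeneity collapsed for most of the transcriptome —
and the chance-only null explains under a quarter of the cumulative
dynamics.

The same stages are available from the shell:

```sh
regenhet simulate out/ --preset dediff --n-probesets 500 --seed 1
regenhet summarize out/expression.tsv out/samples.tsv out/summary.tsv
regenhet mcw out/summary.tsv out/mcw.tsv --design timepoint_restricted --n-perm 10000
regenhet run-all config.yaml      # full pipeline from a YAML config
```

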