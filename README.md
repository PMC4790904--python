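# roisummary

Benchmarking of **ROI single-value summary measures** for task-fMRI contrast
maps: which scalar summary of a region of interest most reliably detects a
group difference in activation?

Group analyses in imaging genetics and clinical fMRI often reduce each
subject's contrast (beta) map to one number per a-priori ROI before testing
for group or genotype effects. The summary chosen matters: a plain ROI mean
dilutes a focal activation with inactive voxels, while peak-oriented
summaries follow each subject's own activation locus. This package
implements ten summary measures, three ROI definition strategies, the group
statistics and effect sizes used to rank them, a covariate-matched
resampling scheme, a permutation test for peak-localization confounds, and a
synthetic blocked-design BOLD cohort generator so every stage can be
validated against known ground truth.

## The measures

Each measure maps one subject's first-level results — beta map $\hat\beta(v)$,
t map $t(v) = \hat\beta(v)/\widehat{SE}(v)$ with df $= T-k$ — and an ROI
$R$ to a scalar. Variant **A** uses all of $R$; variant **B** first keeps the
"activated" voxels $\{v \in R : t(v) > t_{1-p,\,df}\}$ (one-sided, $p=0.05$
per voxel).

| # | summary | variants | parameter |
|---|---------|----------|-----------|
| 1 | mean beta | A, B | — |
| 2 | median beta | A, B | — |
| 3 | eigenimage-weighted mean: weights = first spatial singular vector of the time-centered voxel×time matrix, $\sum_i w_i\hat\beta_i / \sum_i w_i$ | A, B | — |
| 4 | mean beta of top-percentile-t voxels, keeping $\lceil q/100 \cdot m\rceil$ of $m$ | A, B | q ∈ {25, 10, 5} |
| 5 | beta at the ROI peak (max t) | — | — |
| 6 | mean beta of the top-N 26-connected voxels grown best-first from the peak | — | N ∈ {10, 20, 50} |
| 7 | mean beta within a sphere around the peak (∩ ROI) | A, B | r ∈ {6, 7.5, 10} mm |
| 8 | mean beta of voxels whose timecourse correlates with the peak's at $r \ge$ threshold, 26-connected to the peak | A, B | r ∈ {0.7, 0.8, 0.9} |
| 9 | mean beta of the suprathreshold cluster containing the peak | B | — |
| 10 | extent (voxel count) of that cluster | B | — |

A B-variant with no suprathreshold voxel yields a **missing** value that is
dropped per measure in the group analysis.

Group sensitivity is quantified by the pooled-variance two-sample t with
Cohen's $d = (\bar x_1 - \bar x_2)/s_p$, or one-way ANOVA with
$\omega^2 = (SS_b - (k-1)\,MS_w)/(SS_t + MS_w)$ (unclamped).

## Worked example

`analysis/` holds numbered drivers that chain through `results/`:

```bash
python analysis/01_simulate_cohort.py     # 50 pt vs 50 nc, planted d = 0.5
python analysis/02_extract_measures.py    # 16 measures x 3 ROI strategies
python analysis/03_group_comparison.py
python analysis/06_power_benchmark.py     # focal blob in a large ROI
```

The power benchmark (focal ~10-voxel blob, jittered per subject, inside a
1728-voxel ROI; 20 vs 20 per replicate, 200 replicates) prints:

```
    measure  power_p05  mean_d
       m01A      0.205   0.375
   m04A_q10      0.565   0.692
    m06_n20      0.590   0.732
m07A_r7.5mm      0.560   0.706
  m08A_r0.8      0.610   0.692
```

i.e. the plain ROI mean (1A) detects the planted group difference in ~21% of
cohorts while the percentile (4), top-N (6), peak-sphere (7) and
peak-correlated (8) measures all reach 56–61% power at the same sample size
— the focal signal survives peak-oriented selection but is diluted by the
ROI average. The localization driver
(`analysis/05_peak_localization.py`) confirms via permutation that the group
difference is not a peak-placement confound (centroid distance 1.65 mm,
87th percentile of the null).

A `roisummary` CLI wraps the same steps for file-based workflows
(`simulate`, `extract`, `compare`, `resample`, `permute`); volumes are
NIfTI-1, tables CSV, configs YAML.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch under the given seed — simulate a
cohort, build the three ROI types, extract all 16 measure variants, run the
group comparisons, the matched resampling, and the peak-localization
permutation test — printing a summary of each stage and writing its JSON
result file to `--out`.
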