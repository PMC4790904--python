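# Methods

## Model and pipeline

Per subject, a voxel-wise ordinary-least-squares GLM relates the BOLD time
series to a design of a task boxcar plus intercept. For contrast vector
`c`, `beta = c'(X'X)^-1 X'y` and `t = beta / sqrt(sigma2 * c'(X'X)^-1 c)`
with `df = T - k`. No prewhitening, drift regressors, or high-pass filtering
are modeled: the simulated noise is white, and the package's scope is the
summary-measure comparison downstream of the first level, not preprocessing.
Voxels with exactly zero residual variance (possible only on noise-free
synthetic data) carry a `+inf` t sentinel rather than NaN, so they survive
any threshold and never poison selection.

"Activated" voxels are those with `t` above the **one-sided upper-tail**
critical value at per-voxel `p` (default 0.05, uncorrected). One-sided is a
deliberate choice: the measures summarize positive task activation, and a
two-sided rule would let strongly deactivated voxels into the B variants.

## The ten measures: conventions that needed fixing

Several details are under-determined by the usual verbal definitions; the
package fixes them once, identically in implementation and tests:

- **Connectivity** is 26-neighbor everywhere (clusters, region growing,
  peak-correlated components).
- **Tie-breaking**: equal t values are resolved toward the lexicographically
  smallest voxel index — in peak finding, percentile cuts, and greedy
  growth. Reproducibility is worth more than any particular tie choice.
- **Percentile count** (measure 4): `ceil(q/100 * m)` of the `m` candidates,
  which guarantees at least one voxel for a nonempty candidate set.
- **Peak sphere** (measure 7) is intersected with the ROI; voxels outside
  the ROI would contaminate an ROI summary.
- **Peak-correlated voxels** (measure 8) must both pass the correlation
  threshold against the peak timecourse *and* lie in the peak's 26-connected
  component of the kept set ("clustered together with the peak"). A
  zero-variance timecourse counts as correlation 0.
- **Eigenimage weights** (measure 3): voxel timecourses are mean-centered in
  time; the weights are the first right singular vector of the T×V matrix,
  sign-fixed so their sum is positive; the value is `sum(w*beta)/sum(w)`.
- **Missing rule**: any B variant whose selection comes out empty yields a
  missing value (dropped per measure in group analysis), mirroring the
  explicit rule for the peak-cluster measures 9/10.
- Measure 6's growth runs best-first from the peak (add the highest-t
  frontier voxel of the current set) until `min(N, |ROI|)` voxels; the set is
  always connected and contains the peak. When t decreases monotonically
  away from the peak this equals the global top-N set.

## ROI strategies

Sphere ROIs use voxel-center distance (no partial volumes). The
task-activated ROI thresholds per-group one-sample t maps of subject betas
within an anatomical mask at `alpha` **Bonferroni-corrected over the mask's
voxel count** — the conservative, exactly-testable replacement for
random-field FWE, which would require smoothness estimation outside this
package's scope. The per-group suprathreshold maps are combined as a
**union** by default ("activation present in either group");
`joint="intersection"` is available since the joint-map convention is
genuinely ambiguous.

## Group statistics

Pooled-variance (Student) t tests, with Welch available by flag; Cohen's d
uses the pooled SD. One-way ANOVA is the omnibus between/within
decomposition; an ordered-contrast alternative was considered and not
implemented (the benchmark criterion is omnibus sensitivity). Omega squared
is reported **unclamped** — it can be slightly negative in finite samples,
which is exactly what keeps its null expectation at zero; clamp only for
display.

## Matching and resampling

The matching contract is statistical indistinguishability: every covariate's
two-sample t test between reference and selected subset must have p > 0.2
(binary covariates coded 0/1 and t-tested like the rest). The search —
rejection sampling over random subsets with greedy single-swap refinement on
the worst covariate p, budget 10,000 evaluations — is a design choice; any
subset passing the checks is equally valid. In the resampling evaluation,
replicates whose matching fails are redrawn and counted; more failures than
successes aborts with a diagnostic. One subject draw per replicate is shared
by all measures, so per-measure results are comparable within replicate.

## Peak-localization permutation test

Per-group centroids of subject peak coordinates; two groups → Euclidean
centroid distance, three or more → the maximum pairwise distance. The null
is built from simple label shuffles preserving group sizes (sampled with
replacement, default 1000). The percentile counts strict inferiorities, so
ties push toward the conservative side; a percentile above 95 flags a
localization difference. The whole construction is invariant under rigid
motions of the coordinates, which the tests verify.

## Synthetic cohorts: what they emulate and what they do not

Each subject's series is
`baseline + amplitude * blob(v) * boxcar(t) + N(0, noise_sd)`,
optionally Gaussian-smoothed spatially. The blob is an isotropic Gaussian
profile (unit peak) centered on a per-subject peak drawn as
`nominal_center + N(0, jitter_sd)` per axis in mm, rounded to the nearest
voxel and clipped into the grid (clipping, not resampling — the generator
never loops). Group structure enters only through the amplitude
distribution; covariates (age, sex, WRAT, accuracy) are drawn i.i.d. per
group. Defaults state a typical 3 T blocked working-memory run: eight 30-s
blocks at TR 2 s (120 volumes, 15-volume blocks), 3 mm isotropic grid,
baseline 100 with noise SD 2 → baseline TSNR ≈ 50. The boxcar is not
HRF-convolved by default (block lengths far exceed the HRF width; a
canonical double-gamma convolution is available by flag). TSNR is the
timecourse mean over its **sample** SD (n−1); constant timecourses are
missing. Real-data TSNR distributions are not published for the motivating
cohorts, so synthetic TSNR targets are user-chosen, not calibrated.

Not emulated: physiological/motion noise, spatial noise correlations beyond
optional smoothing, multi-session or event-related designs, anatomical
variability beyond peak jitter. A green simulation test therefore
establishes algorithmic correctness and statistical calibration under the
stated generative model — not robustness to real acquisition artifacts.

## Test-suite scenario choices

The calibration, recovery, and power scenarios in the acceptance tests were
fixed analytically before running them:

- **Null calibration**: two identical groups (amplitude N(1.0, 0.25²)),
  n = 50/50, 1000 replicates on an 8³ grid, 40 volumes — the type-I rate of
  the measure-level t test is threshold-free, so grid and noise level only
  set the runtime.
- **Effect recovery**: planted amplitude difference 0.2 over pooled SD 0.25
  (d = 0.8). The extracted peak measure adds GLM noise with SE
  `noise_sd * sqrt(4/T)` ≈ 0.063 at `noise_sd = 0.2`, `T = 40`, diluting the
  expected measured d to `0.8/sqrt(1 + (0.063/0.25)²)` ≈ 0.78 — inside the
  ±0.1 acceptance band by design, not by tuning.
- **Power ordering**: a 6-mm-FWHM blob (~10 voxels of mass) jittered 4 mm SD
  inside a 1728-voxel ROI, 20 vs 20, `noise_sd = 0.4`, 60 volumes. Predicted
  effect sizes: ROI mean ≈ 0.39 (noise-diluted), peak-oriented measures
  0.65–0.78; the measured powers (0.21 vs 0.56–0.61 over 500 replicates)
  match. Replicate counts and grid sizes are scaled to a single CPU.

## Numerical notes and limitations

- The zero-residual sentinel triggers at `SSR <= 1e-20 * ||y||²`, well above
  the float64 rounding floor of an exact fit (~1e-28·||y||²) and below any
  genuine noise.
- t maps with sub-machine noise still have argmax ambiguity among blob
  voxels: the t statistic's coefficient of variation stays ≈ sqrt(2/df)
  regardless of noise scale, so a shoulder voxel with a lucky residual
  variance can out-t the true center. Peak-recovery checks use sharp blobs
  for this reason.
- Only axis-aligned (diagonal-affine) NIfTI grids are supported.
- The matching search is heuristic; infeasibility is reported after the
  iteration budget, not proven.
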