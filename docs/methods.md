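# Methods

This note documents the models, numerical choices and limitations of
`fncpipe`. It covers what the code computes and why the defaults are
what they are; every empirical figure quoted here is produced by the
test suite or by `scripts/acceptance.py`.

## Task design

A delayed item recognition trial is three consecutive epochs: stimulus
(3 s), retention (7 s) and probe. The probe epoch lasts until the
response, so its boxcar width is the trial's RT; timeout trials use the
full 3 s response window. Crossing load {1, 3, 6} with phase {stimulus,
retention, probe} gives nine regressors of interest; incorrect and
timeout trials route *all three* of their phases to a single error
regressor and are excluded from every higher-level analysis.

Boxcars are built on a microtime grid of TR/16 (configurable), convolved
with the canonical double-gamma HRF — the difference of gamma densities
with shapes 6 and 16 (unit scale), undershoot ratio 1/6, support
[0, 32] s, scaled to unit peak (peak at ≈ 5 s) — and sampled at scan
onsets. Task columns are mean-centered within each run so that per-run
intercepts absorb the baseline; the intercepts and the error regressor
carry zero contrast weight.

Contrast weights are not dictated by the experiment's description beyond
"load-dependent and load-independent effects within each phase", so the
load-dependent weights are the centered load values (−7/3, −1/3, +8/3)
normalized to unit length — a linear-in-load "slope" coding consistent
with the sRT slope outcome — and the load-independent weights are
(1/3, 1/3, 1/3). Within each phase the two are orthogonal.

## Group spatial ICA

PCA is *temporal*: the scans dimension is reduced, the voxel dimension
preserved. Within each run the scans × scans covariance (normalized by
the voxel count) is eigendecomposed and 30 whitened components retained
by default; the reduced data of all subject-runs are stacked
(subject-major, run-minor; the order is stored in the model) and reduced
a second time to the model order (36 in a full-size analysis; equal to
the planted source count in the synthetic benchmarks). Voxel-demeaned
data have temporal rank scans − 1, so "lossless" retention means
scans − 1 components.

Infomax ICA maximizes output entropy through a logistic nonlinearity
with natural-gradient updates over random-permutation mini-batches
(block ⌊√(voxels/3)⌋). Numerical choices that matter:

* **Initialization** is a seeded random rotation, not the identity.
  Repetitions started from distinct rotations explore distinct basins,
  which is what makes ICASSO stability informative: a Gaussian-only
  subspace keeps whatever rotation it started from and clusters poorly,
  while genuinely super-Gaussian sources converge to the same estimates
  from any start.
* **Learning rate** 0.01/ln(n) initially. On unit-variance whitened
  data this is large enough that the separating rotation completes
  within the 64-sweep full-rate burn-in; afterwards the rate decays
  geometrically (× 0.97 per sweep), which drives the update norm to the
  10⁻⁶ convergence threshold. A blown-up update (non-finite or huge
  weights) anneals the rate by 0.9 and restarts from the initial
  rotation.
* **Convergence** is measured on the row-normalized unmixing matrix:
  at the logistic fixed point the weight *scale* keeps creeping while
  the separating directions are stationary, and rows are rescaled to
  unit-variance sources afterwards anyway.
* **Sign convention**: each source is flipped so its largest-|weight|
  voxel is positive (idempotent; the mixing column flips with it).

ICASSO repeats the decomposition (20 times by default; fewer in reduced
benchmarks) with seeds drawn from a master seed, pools all estimates,
and clusters them by average linkage on 1 − |spatial correlation|. Each
cluster is summarized by its centrotype (the member with the largest
total within-cluster similarity) and the stability index Iq = mean
intra-cluster − mean extra-cluster similarity. Repetitions use seed
variation only, no voxel resampling. Note that even duplicated estimates
give Iq marginally below 1 because the extra-cluster term is small but
nonzero.

Back-reconstruction is GICA by default: a subject-run's time courses are
`run_dewhitening @ group_dewhitening[partition] @ mixing`, and its
spatial maps solve the partitioned forward model by pseudo-inverse. Dual
regression (regressing the aggregate maps onto the run data) is
available behind a flag; on noiseless phantoms the two agree to r > 0.95
and both recover planted time courses at r > 0.99.

Visual artifact screening is replaced by a rule: a component whose peak
voxel falls outside the 1-voxel-eroded mask interior, or whose mean time
course carries more than half its power above 0.1 Hz, is flagged; the
flagged list can be overridden in the pipeline config.

## Group tests and FNC

Within-group tests regress the contrast values on an intercept plus a
centered gender indicator (t for the intercept, df = n − 2; a
single-gender group falls back to a plain one-sample t with a warning).
Between-group tests add a group indicator oriented so positive t means
young > old. Task-relatedness uses Bonferroni over components ×
6 contrasts × 2 groups (the full set of within-group decisions; 300 for
25 tested components), configurable.

FNC demeans each run individually, concatenates, and takes the plain
zero-lag Pearson correlation per component pair; r is clipped at
1 − 10⁻¹² before atanh so z stays finite, and a constant time course
masks its incident edges with a warning (masked subjects are excluded
pairwise from edge tests, with the exclusion count reported). Edge tests
Bonferroni-correct over the pair count (153 for 18 components);
components incident to no significant edge are pruned. Edge-performance
regressions (sRT on z, gender-adjusted) correct over the number of
significant edges carried forward.

## Behavioral and structural covariates

Median RT uses correct, responded trials only. sRT is the OLS slope of
the three per-load medians against the raw loads (1, 3, 6), in seconds
per letter. Accuracy uses the logistic discrimination index
d_L = ln{[H(1−FA)]/[(1−H)FA]} with the log-linear 0.5/(n+1) correction,
which keeps perfect scores finite; the correction shrinks d_L toward 0
at small trial counts (see limitations). nWBV = (GM+WM)/(GM+WM+CSF).

## Mediation

All three regressions (y~x, m~x, y~x+m) share the same centered
covariates, so c = c′ + a·b holds to machine precision and is asserted
at 10⁻¹⁰. The bootstrap is stratified: every replicate draws exactly
n_young and n_old subjects with replacement within group, so the group
imbalance of the design is preserved. Replicates with a degenerate
resample — zero variance in mediator or outcome, or a covariate constant
within every stratum (which aliases the intercept/group columns, e.g. an
all-male young draw with an all-female old draw) — are redrawn and
counted. The confidence interval is bias-corrected percentile (BC, no
acceleration): z₀ = Φ⁻¹(fraction of bootstrap values below the point
estimate, ties counted half, clamped to ±Φ⁻¹(1−1/B)), with endpoints at
the Φ(2z₀ + z_{α/2}) and Φ(2z₀ + z_{1−α/2}) bootstrap quantiles. BCa
acceleration is deliberately omitted. Known property: with a binary
exposure and a strong b path the BC interval is mildly anti-conservative
under the a = 0 null (measured ≈ 7% at n = 112, B = 1000, against a
nominal 5%); coverage of a planted nonzero indirect effect measures
≈ 94% at the 95% level.

## The synthetic study generator

The generator emulates the target study's design: 75 young + 37 old
subjects (gender ratios ≈ 2:1 M young, 15:22 M old), 3 runs × 69 scans
at TR = 3 s, 6 spatial sources on a 12³ grid with a spherical mask.
Defaults were calibrated once, from the emulated study's published
summary tables, before any test was run:

* **RT model**: per-trial RT = intercept + slope·load + N(0, 0.18 s),
  truncated to (0, 3]; group intercept/slope (0.824, 0.0597) young and
  (0.814, 0.0897) old reproduce per-load group median RTs of
  0.88/1.01/1.18 s and 0.90/1.09/1.35 s.
* **FNC targets**: two headline edges planted at young/old r of
  0.514/0.059 and 0.448/0.113, background edges at 0.25/0.10; a
  subject's edge-level Fisher z jitters around the group mean with sd
  0.25. The planted matrix is projected to the nearest correlation
  matrix (eigenvalue floor) when jitter breaks positive definiteness.
* **Mediation structure**: subject sRT couples to the first planted
  edge with κ = −0.04 s/letter per unit z (weaker connectivity, steeper
  slope) plus N(0, 0.018) subject noise — so a = z̄_old − z̄_young ≈
  −0.51, b = κ, and the group slope difference c ≈ 0.030 decomposes into
  a·b ≈ 0.020 indirect and c′ ≈ 0.010 direct (partial mediation).
  Tissue volumes are lognormal with group-specific means (nWBV ≈ 0.89
  young, 0.81 old) and are drawn independently of FNC within group, so
  the age → volume → FNC path carries no indirect effect by
  construction.
* **Sources and images**: Gaussian blobs at farthest-point-sampled
  centers inside the eroded mask interior, unit-variance rows, pairwise
  |spatial r| < 0.2 (the blob width shrinks if needed). Rows are *not*
  spatially centered: positive disjoint blobs are near-orthogonal in the
  raw inner product the PCA/ICA chain uses, which avoids cross-talk in
  back-reconstruction. Voxel data are time courses × maps plus N(0, 1)
  noise. Task time-course signal is the convolved design times
  per-source loadings, rescaled to sd 0.2 (≈ 4% task-locked variance,
  realistic for event-related components); the residual covariance is
  compensated for the task-signal covariance so the *total* time-course
  correlations converge to the planted FNC targets (with zero loadings
  the residual target is the planted matrix itself).

Two design constraints deserve note. First, a 69-scan run (207 s)
physically holds nine ~21 s trials, not the 30 the emulated study ran
per (longer) run, so the generator defaults to 3 trials per load per
run; d_L's small-sample correction consequently shrinks the measured
index to ≈ 2.0 against an asymptotic 2.53. Second,
`SynthConfig.reduced()` — the configuration used by the benchmarks —
scales the edge→sRT coupling by √(n_full/n_reduced) × 1.3. The √n factor
preserves the mediator-path noncentrality of the full design; the 1.3
margin exists because the full-size coupling is deliberately marginal
(the emulated effect was itself borderline-significant, with
per-replicate detection probability near 85%), whereas a reduced smoke
study must detect the planted mediation reliably (≥ 90% of seeded
replicates) to be informative about pipeline correctness rather than
about borderline power.

## What passing tests do and do not show

The phantom has no motion, drift, physiological noise, spatial
autocorrelation of the noise, or anatomical realism; sources are
compact, disjoint and strongly super-Gaussian, which is close to a
best case for infomax. Recovery at |r| > 0.9 on this phantom therefore
validates the *mechanics* of the reduction/ICA/back-reconstruction
chain — operator bookkeeping, whitening, sign and ordering conventions —
not performance on real scanner data. Likewise the FNC and mediation
benchmarks validate calibration (type-I, coverage, sign recovery) under
the generator's Gaussian residual model, not robustness to the heavier
artifacts of real BOLD series. Problem sizes in the test suite (12 + 12
subjects, 10³ grids, B = 1000, 500-simulation calibrations) are the
package's benchmark defaults; all scale up through configuration.

## Known limitations

* Model order is a config parameter; no information-criterion estimate.
* Bonferroni only, as in the analysis emulated; no FDR option.
* Plain zero-lag correlation; no lagged FNC, no dynamic connectivity,
  no graph-theoretic summaries.
* Single mediator per model; no moderated mediation, no Sobel test.
* The artifact rule is a coarse stand-in for expert visual screening.
* The printed path coefficients of the emulated study do not satisfy
  a·b = indirect exactly (its indirect column likely summarizes the
  bootstrap rather than the point-estimate product); this package
  reports a·b from point estimates.
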