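# Methods

## The question and the procedure

Trainable white-matter-hyperintensity (WMH) segmenters are usually
developed on cohorts with heavy, confluent lesion loads.  In a normal
aging population most subjects carry little or no WMH, and the key
practical question is how many manually delineated training images are
needed before the *volume* read-out of such a segmenter becomes accurate
and, above all, robust to the luck of the draw.

The harness answers this with a resampling experiment:

1. **Cohort.**  `n_paired` participants, each with a baseline (BL) and a
   follow-up (FU) observation (the resampling partition, `2 × n_paired`
   observations), plus a fixed external partition of `n_external`
   observations that is never used for training.
2. **Design.**  For each training sample size `n` in `sample_sizes`,
   `n_draws` training sets are drawn without replacement, with at most
   one observation (BL *or* FU) per participant.  For every draw the
   validation data are the BL scans and the FU scans of all
   *non-training* participants (internal-BL and internal-FU sets, each of
   size `n_paired − n`) plus the external partition.  A participant who
   contributes either scan to a training set is excluded from both
   internal sets of that draw — the data-leakage rule, checked
   explicitly by `verify_no_leakage`.
3. **Model.**  Per draw, a voxel-wise k-nearest-neighbour classifier is
   fitted (below) and used to predict a lesion-probability map for every
   validation observation.
4. **Metrics.**  Maps are thresholded on a grid (default 0 to 1 by 0.1,
   11 values); per threshold the predicted volume in ml, the signed
   volume error (predicted − manual; > 0 overestimation) and the Dice
   similarity index `2|A∩B|/(|A|+|B|)` are recorded.  Per model ×
   validation set × threshold the signed errors are aggregated (mean,
   sample SD with n−1, median, IQR).  The working threshold `t*`
   minimizes the magnitude of the across-model mean signed error over
   the internal sets (ties toward the larger, more conservative
   threshold).  Post-hoc analyses relate each draw's proportion of
   low-volume training subjects (< 0.1 ml, < 0.5 ml) to its model-level
   error, and stratify observation-level errors by manual volume
   (bins 0, (0, 0.1], (0.1, 0.5], (0.5, 2], > 2 ml).

At the full defaults (80 paired + 41 external, sizes 10–40 step 5, 100
draws) the bookkeeping gives 700 models and 105,700 predicted maps; the
design table reproduces these counts exactly and they are asserted in
the tests.

## The synthetic cohort

No public imaging data accompany the study design, so every stage runs
on phantoms generated by `wmhresample.phantom`:

- **Anatomy.**  Nested ellipsoids on a configurable grid (default 64³ at
  1 mm isotropic): a brain mask, a GM-like shell, a WM-eligible shell and
  a CSF-like core (semi-axis fractions 0.42 / 0.36 / 0.10 of the grid).
  The anatomy is deterministic given the geometry parameters; there is no
  inter-subject anatomical variability.
- **Lesion-volume law.**  A zero-inflated log-normal.  `p_zero = 21/160`
  and `(log_mu, log_sigma) = (−0.67773, 2.10545)`, obtained once by
  quantile matching so the mixture median is 0.34 ml and its IQR 1.6 ml —
  the summary statistics of the emulated cohort.  Matching median and
  IQR leaves the upper tail heavier than the cohort's empirical mean
  suggests; tail draws are therefore clipped to `capacity_frac` (default
  0.5) of the WM-eligible region when a cohort is generated.
- **Lesion geometry.**  The target volume is converted to a voxel count
  and realized as quasi-spherical blobs (mean ≈ 150 voxels each) grown
  voxel-by-voxel, nearest-to-seed first in millimetre metric with a
  jittered priority, inside the WM-eligible region.  A final frontier
  pass tops the mask up so the realized count equals the target exactly
  whenever it fits; overflow raises a generation error.
- **Longitudinal progression.**  The FU mask dilates the BL mask by a
  multiplicative factor ~ Normal(1.6, 0.3) truncated at 1, plus
  Poisson(0.2) de-novo small lesions (log-normal, median 0.1 ml), so FU
  volume ≥ BL volume always.  The FU image is re-rendered on the same
  anatomy with fresh noise.
- **Intensities.**  Per-tissue means/SDs in arbitrary units (lesions
  hyperintense on FLAIR: 150 vs WM 100; mildly hypointense on T1) plus
  additive Gaussian noise (SD 8) inside the brain mask.  The tissue
  contrast is deliberately imperfect so the classifier makes realistic
  boundary errors.
- **Randomness.**  One master seed; every participant, external subject,
  draw and fit consumes a named substream
  (`SeedSequence(master, hash(tokens))`), so cohorts are reproducible
  voxel-for-voxel and adding participants or draws does not perturb
  existing ones.

What the phantoms do *not* emulate: cortical anatomy, periventricular vs
deep lesion taxonomy, bias fields, registration error, partial-volume
voxels, scanner artifacts, or rater noise.  Passing tests therefore show
that the *harness and its statistics* behave as designed under a cohort
with the right volume distribution — not that any real-data accuracy
number transfers.

## The voxel classifier

Features per brain-mask voxel: each modality's intensity standardized to
mean 0 / SD 1 within that subject's own mask (zero-variance guard), plus
the three voxel coordinates normalized to [0, 1] per axis and multiplied
by a spatial weight (default 1; grid-normalized coordinates stand in for
atlas-space coordinates since registration is out of scope).  Training
pools lesion voxels (from the manual masks) and non-lesion brain voxels
across the draw's subjects and subsamples each class uniformly without
replacement to caps of 2000 / 10000; `k = 40`.  These defaults follow the
published recommendations for this family of tools; all are exposed in
the configuration.  A training set with no lesion voxel at all yields a
degenerate model that predicts 0 everywhere (with a warning).

The probability of a voxel is the fraction of lesion-labelled points
among its `k` nearest reference points (Euclidean metric in feature
space).  Numerical contracts:

- **Ties.**  Exact distance ties at the k-th neighbour are broken by
  stable reference-point order (lowest stored index wins; `fit` stores
  non-lesion points before lesion points, so an exact tie resolves
  conservatively).  The tree-based search looks ahead one neighbour to
  detect boundary ties and falls back to an exact stable sort for the
  affected voxels only.
- **Screening.**  Voxels with at least `k` non-lesion references
  strictly closer than the nearest lesion reference provably have
  probability 0; two cheap tree queries certify this (the strictness is
  enforced by shrinking the count radius by one ulp) and the full search
  runs only on the remaining voxels.  The screened path is exact and is
  tested against the brute-force oracle.
- **Thresholding.**  `t > 0` keeps voxels with probability ≥ t; `t = 0`
  keeps probability > 0, so the zero threshold returns the support of
  the map rather than the whole brain mask.  Probabilities are multiples
  of 1/k; masks are nested in t.
- **Aggregation.**  Sample SD uses the n−1 denominator and is reported
  as 0 with a flag for single-observation sets; median/IQR use the
  linear-interpolation quartile convention.
- **Dice.**  Empty manual with non-empty prediction gives 0 (zero volume
  cannot be underestimated); both-empty is undefined (NaN) and excluded
  from averages.

## Problem sizes

Three built-in profiles set the experiment scale:

- `full`: 80 paired + 41 external on 64³ grids, sizes 10–40 step 5,
  100 draws — the complete published-scale design (hours of compute; run
  it with `run-all --profile full`).
- `scaled`: 40 paired + 20 external on 32³ grids at 1.5 mm, sizes
  {5, 10, 20}, 20 draws, reference caps 400/2000 (the 1:5 class ratio of
  the full defaults), k = 40.  This is the package's desk-scale
  experiment, sized to complete in minutes on one CPU; the acceptance
  script and the qualitative tests use it.
- `toy`: 8 paired + 4 external on 24³ grids, sizes {2, 4}, 5 draws —
  seconds; used for end-to-end determinism and bookkeeping tests.

The qualitative read-outs checked on the scaled profile are direction
claims, not magnitudes: (i) the across-draw SD of the per-model mean
signed error shrinks as the training sample size grows (trend test:
SD at the largest size below the smallest, Kendall tau ≤ 0 over sizes);
(ii) the Spearman correlation between a draw's proportion of < 0.5 ml
training members and its mean signed error is negative; (iii) the mean
signed error decreases across increasing manual-volume strata (the zero
stratum is necessarily ≥ 0).

## Known limitations

- The feature set is minimal (two intensities + coordinates); the
  original tool's documented extensions (local averages, atlas-space
  coordinates) are not claimed or emulated bit-for-bit.
- Threshold selection aggregates the internal BL and FU sets by default;
  this is a configuration choice, as is minimizing the magnitude rather
  than the signed value of the mean error.
- The phantom's selected threshold and Dice values depend on the chosen
  tissue contrast and noise; only their qualitative behaviour is
  meaningful.
- `run_experiment` holds the cohort in memory; at the full default
  geometry this is a few hundred MB.  Resumability is per
  (sample size, replicate) unit.
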