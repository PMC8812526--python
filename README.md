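# wmhresample

**How many manually labelled training scans does a trainable
white-matter-hyperintensity (WMH) segmenter need in a healthy, low
lesion-load population?**

WMH of presumed vascular origin appear as bright FLAIR lesions and are a
core imaging marker of small-vessel disease.  In population cohorts most
participants have little or no WMH, which makes automated volumetry with
trainable tools fragile: a model trained on an unlucky draw of subjects
can badly over- or underestimate lesion volume.  `wmhresample` is a
harness for quantifying that fragility as a function of training sample
size, aimed at imaging methodologists planning manual-segmentation
budgets for population studies.

The package provides, as tested library code plus a CLI:

- **`wmhresample.phantom`** — a synthetic cohort generator: co-registered
  FLAIR-like/T1-like 3D phantom pairs with ground-truth lesion masks.
  Lesion volumes follow a zero-inflated log-normal law calibrated to a
  pooled median of 0.34 ml, IQR 1.6 ml and a 13 % zero-lesion mass, with
  paired baseline/follow-up scans and intra-individual lesion growth.
- **`wmhresample.design`** — the resampling design: training sets of
  sizes 10–40 (step 5) drawn 100× each without replacement, one
  observation per participant, with leakage-consistent internal-BL,
  internal-FU and external validation sets, plus the design table
  (181…121 predictions per model, 700 models, 105,700 maps at the full
  defaults) and an explicit leakage verifier.
- **`wmhresample.knn`** — a voxel-wise k-nearest-neighbour lesion
  classifier (standardized FLAIR+T1 intensities plus spatially weighted
  grid coordinates; probability = lesion fraction among the k = 40
  nearest reference points, caps 2000/10000), the trainable-segmenter
  family these studies evaluate.
- **`wmhresample.metrics`** — volumes in ml, signed volume error
  (predicted − manual; > 0 overestimation), per-model aggregation,
  global threshold selection, Dice similarity index
  `2|A∩B|/(|A|+|B|)`, training-set composition and volume-stratified
  error analyses.
- **`wmhresample.experiment` / `wmhresample.cli`** — the end-to-end
  driver: reproducible from one master seed, resumable per
  (size, replicate) unit, with CSV outputs, a JSON manifest, summary
  tables and plots.

See `docs/methods.md` for the model, its assumptions and the numerical
conventions.

## Worked example

The built-in `toy` profile (8 paired + 4 external phantoms on 24³ grids,
training sizes {2, 4}, 5 draws each) runs in seconds:

```bash
wmh-resample run-all --profile toy --seed 7 --outdir runs/toy
```

which ends with (abridged):

```
selected threshold: 0.8
 sample_size     external  internal_bl  internal_fu
           2 -1.80 (0.39)  0.14 (0.22)  0.06 (0.26)
           4 -1.82 (0.39)  0.03 (0.28) -0.10 (0.36)
```

Reading: the working threshold 0.8 minimized the magnitude of the
across-model mean signed volume error on the internal validation sets.
Each cell is the mean (SD) over the 5 draws of the per-model mean signed
error in ml — e.g. models trained on 4 subjects misestimate internal-BL
volumes by +0.03 ml on average, with an SD of 0.28 ml across draws.  (At
toy scale the external set is a single phantom that happens to carry a
large lesion, hence its constant underestimation; the desk-scale profile
below is the meaningful experiment.)

The run directory contains `raw_records.csv` (one row per draw ×
observation × threshold), `summaries.csv`, `design_table.csv`,
`threshold_selection.csv`, `table_mean_errors.csv`, `composition.csv`,
`stratified_errors.csv`, a `manifest.json` with config echo and
checksums, and plots under `plots/`.

The same pipeline is available as library calls:

```python
from wmhresample import PROFILES, run_experiment, report

cfg = PROFILES["scaled"](seed=1)     # 40+20 phantoms, sizes {5,10,20}, 20 draws
outdir = run_experiment(cfg, "runs/scaled")
result = report(outdir)
result["selected_threshold"], result["error_matrix"]
```

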