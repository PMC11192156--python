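# seedscan

Automated seed counting and species classification from flatbed-scanner
images. The pipeline segments seed silhouettes from binary scans, extracts
an ImageJ-style morphometric feature vector per seed (area, perimeter,
fitted ellipse, rotating-calipers Feret diameters, circularity, solidity,
intensity statistics, …), classifies each seed to species with a random
forest, evaluates the classifier (confusion matrix, exact binomial CI of
accuracy, Cohen's kappa, no-information rate), and reconciles the two
replicate scans of each seed batch into a consensus count with an absolute
and relative discrepancy measure.

A synthetic-scan generator (`seedscan.synthgen`) renders binary images of
winged conifer-like seeds with ground truth, so the entire pipeline is
testable end to end without any external data.

## Modules

| Module | Role |
| --- | --- |
| `seedscan.scanio` | TIFF/PNG scan I/O, dpi calibration, file-name tag parsing (`SITE_TRAP_DATE_SPECIES_FILL_REPn`) |
| `seedscan.segmentation` | thresholding (Otsu/fixed/none), 8-connected particle labeling, debris size filter, crack-boundary tracing |
| `seedscan.morphometry` | the full per-particle measurement vector in calibrated mm |
| `seedscan.features` | feature-table assembly (25 measurements + Site = 26 predictors), stratified train/test split |
| `seedscan.classifier` | random forest (default 500 trees, mtry = floor(sqrt(p))), tuning, Gini importance, importance-filtered refit |
| `seedscan.evaluation` | confusion matrix, accuracy with exact (Clopper–Pearson) CI, kappa, NIR |
| `seedscan.consensus` | replicate pairing, per-species counts, consensus mean + discrepancy |
| `seedscan.synthgen` | synthetic seed scans with ground truth and paired replicate renders |
| `seedscan.cli` / `seedscan.pipeline` | stage wiring, run manifests, reproducible runs |

## CLI

Every stage is a subcommand of `seedscan`:

```bash
# synthetic data with truth labels
seedscan simulate --n-seeds 600 --seed 1 --out data/

# segment + measure every scan in a directory
seedscan measure --in data/ --out features.csv --threshold none --min-area-mm2 0.2

# assemble the feature table and split 80/20 stratified by species
seedscan split --features features.csv --train-out train.csv --test-out test.csv \
    --train-frac 0.8 --seed 1

# train / tune / predict
seedscan train --train train.csv --model model.joblib --ntree 500 --seed 1
seedscan tune --train train.csv --ntree-grid 100,500 --mtry-grid 3,5,8
seedscan predict --model model.joblib --in test.csv --out calls.csv

# statistics and replicate consensus
seedscan evaluate --calls calls.csv --out report.json
seedscan consensus --calls calls.csv --out consensus.csv

# or the whole thing, with a reproducibility manifest
seedscan all --config config.yaml --out run/
```

`seedscan all` is byte-reproducible under a fixed configuration: rerunning
with the same config produces identical feature, call, consensus and
report files, and `manifest.json` records the config hash.

## Notes

* Scans are assumed dark-on-light (seeds on a white platen) at a known
  dpi (default 600); both are configurable.
* The perimeter is the exact crack-boundary polygon length. This is a
  deliberate, reproducible choice; it overestimates smooth outlines, so
  circularity of round seeds plateaus near 0.6 rather than 1.0. The
  classifier is trained on features from this implementation, so the
  shift is internally consistent.
* Skew/Kurt are measured but excluded from prediction (binary scans give
  them no variance), matching the default 26-predictor schema.
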