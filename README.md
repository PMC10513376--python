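# kinapse

Automated classification of T-lymphocyte motility behaviors from time-lapse
cell tracks. From per-timepoint track tables (an Imaris-export-like CSV
dialect), the pipeline computes a 90-feature sliding-window representation of
each (cell, timepoint) sample, ranks features with mRMR (ANOVA-F relevance,
Pearson redundancy), chooses how many to keep inside experiment-grouped
3-fold cross-validation, and trains a balanced random forest for either
binary (synapse vs. kinapse) or 3-class (poking / scanning / dancing)
classification. A built-in trajectory simulator produces labeled fields of
tracks so every stage is testable without microscopy data.

## Layout

| module | role |
| --- | --- |
| `kinapse.track_io` | read/write/merge/filter/label track CSVs |
| `kinapse.features` | 29 base + 61 window features (90 total) |
| `kinapse.selection` | mRMR ranking + CV feature-count search |
| `kinapse.model` | balanced random forest, grouped CV, metrics |
| `kinapse.synthetic` | labeled trajectory simulator |
| `kinapse.cli` | `kinapse` command-line tool |
| `kinapse.config` | YAML pipeline configuration |

Key conventions (all configurable):

* tracks shorter than 5 timepoints (300 s at 1 frame/min) are excluded;
* the moving window is 5 points wide, centered, stepping 1 point; edge
  timepoints copy the first/last fully computed window;
* the coast coefficient counts window points with speed below 1/30 um/s;
* raw `round` labels are merged into `poking`; the binary scheme maps
  poking to `synapse` and dancing/scanning to `kinapse`;
* all train/validation/test splits are grouped by experiment id —
  no experiment ever appears on both sides of a split.

## CLI

```sh
# simulate a labeled field of tracks
kinapse simulate --config config.yaml --seed 1 --out train.csv
kinapse simulate --config config.yaml --seed 2 --out test.csv

# full pipeline: feature-count search, final mRMR, balanced forest, metrics
kinapse run train.csv test.csv --scheme binary --seed 0 --out runs/binary

# or stepwise
kinapse extract tracks.csv --scheme binary --out matrix.csv
kinapse select matrix.csv --n-features 13 --out feats.csv
kinapse train matrix.csv --features feats.csv --out model.joblib
kinapse evaluate heldout.csv --model model.joblib
kinapse predict unlabeled.csv --model model.joblib --out preds.csv
```

`kinapse run` writes metrics, the row-normalized confusion matrix, the CV
accuracy curve, the selected-feature list, a model artifact, and a
`manifest.json` recording the seed and full configuration, from which the
run is reproducible.

A config file is optional; defaults are sensible. Example:

```yaml
seed: 0
coast_threshold: 0.0333333
mrmr: {scheme: quotient, grid_start: 3, grid_step: 2, grid_max: 21,
       stop_delta: 0.005, stop_horizon: 5}
forest: {n_trees: 500, max_features: sqrt}
cv: {n_folds: 3}
sim: {n_experiments: 6, cells_per_experiment: 100, n_frames: 120}
```

## Python API

```python
from kinapse import (SimConfig, simulate_field, filter_short_tracks,
                     run_experiment)

train = filter_short_tracks(simulate_field(SimConfig(n_experiments=6,
                                                     cells_per_experiment=100,
                                                     seed=1)))
test = filter_short_tracks(simulate_field(SimConfig(n_experiments=2,
                                                    cells_per_experiment=100,
                                                    seed=2,
                                                    experiment_prefix="held")))
result = run_experiment(train, test, scheme="binary", seed=0)
print(result.n_features, result.report.accuracy, result.report.gmean)
```
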