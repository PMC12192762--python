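# maxsdm

Maximum-entropy habitat-suitability modelling as a reusable, tested
pipeline: occurrence thinning, Pearson-correlation variable pruning,
L1-regularized maximum-entropy (presence-background) model fitting,
AICc/omission tuning over a regularization-multiplier × feature-class grid,
replicated evaluation with variable-importance analyses, projection onto
climate-shift scenarios, four-class suitability binning, area-change
accounting, and range-centroid shift analysis.

Everything runs on plain-text inputs (ESRI ASCII grids + occurrence CSVs),
and a synthetic-landscape generator with known truth makes every stage
testable without any external data.

## Package layout

| module | what it does |
| --- | --- |
| `maxsdm.grid_io` | ESRI ASCII grid read/write (corner + center dialects), geometry-checked multi-layer stacks with a shared validity mask |
| `maxsdm.synthetic_data` | correlated smooth random layers, a Gibbs-form truth surface, presence sampling, additive future scenarios |
| `maxsdm.preprocess` | spatial thinning (one record per k-km cell), presence/background sample extraction, greedy \|r\| > 0.8 pruning |
| `maxsdm.maxent_core` | feature expansion (linear/quadratic/product/hinge/threshold), L1 coordinate-descent fitting, raw + logistic prediction with clamping |
| `maxsdm.evaluation` | repeated 75/25 splits, AUC/TSS/omission, percent contribution, permutation importance, jackknife gains, response curves |
| `maxsdm.model_selection` | candidate grid (40 RM values × 31 class combos = 1240), landscape-normalised AICc, omission/ΔAICc selection rules |
| `maxsdm.postprocess` | suitability classes at 0.05/0.33/0.66, per-class areas (10^4 km²), change percentages, weighted high-class centroid shifts |
| `maxsdm.cli` | `maxsdm` command-line entry point and the end-to-end pipeline |

## CLI

```bash
# generate a synthetic landscape + occurrences
maxsdm simulate --out data/ --seed 1 --n-presences 400

# write a run configuration
python - <<'PY'
from maxsdm.cli import RunConfig
RunConfig(
    raster_dir="data", occurrence_csv="data/occurrences.csv", out_dir="run1",
    background_size=2000, rm_min=0.5, rm_max=2.0, rm_step=0.5,
    feature_classes=["L", "Q", "H"], tune_knots=8,
    scenarios=[{"label": "warm_2050", "deltas": {"bio6": 1.0, "bio12": 0.5}}],
    master_seed=1,
).to_yaml("config.yaml")
PY

# full pipeline: thin -> extract -> filter -> tune -> fit -> evaluate
#                -> project -> classify -> report -> centroid
maxsdm run-all --config config.yaml
```

Intermediate stages are independently invocable (`maxsdm thin`,
`filter-vars`, `tune`, `fit`, `evaluate`, `project`, `classify`, `report`,
`centroid`); artifacts (CSV tables, `.asc` maps, model JSON, logs) land in
the configured output directory, and a fixed `master_seed` makes tabular
artifacts byte-identical across runs.

Note the default tuning grid (1240 candidates) is sized for real studies;
for quick runs shrink `rm_min/rm_max/rm_step` and `feature_classes` as in
the example above.

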