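# longisel

Joint feature selection and prediction of longitudinal clinical scores from
baseline imaging features.

A single baseline feature table (e.g., regional gray-matter volumes) is used
to predict several clinical score types at several future time points at
once. One weight matrix per time point is fit jointly under three
heat-kernel graph-smoothness penalties — between features, between subjects,
and between score types — plus an l2,1 penalty on the row-wise unfolding of
all weight matrices, which zeroes whole feature rows and therefore selects
one common feature subset across every (time, score) task. The optimizer
alternates diagonal reweighting of the l2,1 term with closed-form Sylvester
equation solves, one per time point, and has a provably non-increasing
objective. Selected features feed one linear epsilon-SVR per (time, score)
cell; evaluation is nested cross-validation (outer 10-fold, inner 5-fold
hyperparameter search) reporting Pearson correlation and RMSE per cell plus
feature-stability tables across folds. A per-task lasso baseline under the
identical protocol and a synthetic cohort generator with a planted common
support round out the package.

## Layout

| module                | contents                                                              |
|-----------------------|-----------------------------------------------------------------------|
| `longisel.datatypes`  | `FeatureMatrix`, `ScoreTensor`, `WeightStack`, normalization stats     |
| `longisel.graphs`     | z-scoring, heat-kernel similarity graphs, Laplacians, l2,1 reweighting |
| `longisel.optimizer`  | objective, regularizers, Sylvester step, iterative `fit`               |
| `longisel.pipeline`   | feature ranking/selection, SVR grid, nested CV, lasso baseline, region stability report |
| `longisel.simulate`   | synthetic longitudinal cohorts with planted sparse common support      |
| `longisel.io` / `longisel.cli` | CSV/TSV readers, JSON/TSV writers, `longisel` command line        |

## Command line

```bash
# generate a synthetic cohort (features.csv, scores.csv, truth.json)
longisel simulate --seed 7 --out data/ --subjects 200 --features 93

# one joint fit, weights + objective trace as JSON
longisel fit --features data/features.csv --scores data/scores.csv \
    --out weights.json --lambda1 0.1 --lambda2 1.0

# nested cross-validated evaluation: report.json + regions.tsv
longisel cv --features data/features.csv --scores data/scores.csv \
    --out results/ --seed 7 --lambda1-grid 0.1,1 --lambda2-grid 1,10,100

# re-derive the top-k stability table from a saved report
longisel report-regions --report results/report.json --out regions.tsv --top-k 30
```

Inputs: the feature table is wide (first column `subject_id`, one numeric
column per feature, header required); scores are tidy/long with columns
`subject_id,time_label,score_name,value`, one row per combination. A YAML
`--config` file can supply any option; explicit flags win.

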