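# landboost

Dynamic 1-year risk prediction from longitudinal EHR-style event tables,
built around **landmark-boosting**: a gradient-boosted-tree model that is
re-ensembled at yearly landmark times, carrying each patient's previously
predicted risk forward as a log-odds offset and fitting new trees to the
updated predictors. The package targets biostatisticians and clinical
informaticians studying progression of chronic disease — the worked domain
is diabetic kidney disease (DKD) in patients with type 2 diabetes — and
anyone comparing temporal representations of irregular clinical data.

## The model

At landmark time t (t full years since diabetes onset), among patients
still at risk and observable, we predict the probability of a first DKD
event in the coming year from everything recorded strictly before the
landmark. Landmark-boosting solves, sequentially for t = 1..T,

    min E_t|t-1 [ L( y_t, F_t(x_t, F_{t-1}(x_{t-1})) ) ]

with L the binomial log-loss and F_t an additive tree ensemble whose
per-patient *base margin* is the previous landmark's predicted log-odds:

    margin_t(i) = logit( F_{t-1} risk of patient i ) + sum_m eta * h_m(x_it)

New trees h_m are grown by exact greedy, sparsity-aware split search (both
routings of missing values are scored at every node), the tree count is
chosen by early stopping on holdout AUROC, and hyperparameters can be
re-tuned by stratified 10-fold cross-validation at each landmark. Three
comparator representations are included — latest-value (last observation
per feature), stack-temporal (one column per feature x window) and
discrete-survival (pooled person-period rows) — plus the full phenotyping
rules (diabetes onset, MDRD eGFR, yearly DKD status sequences with NA
years, landmark eligibility), an evaluation suite (AUROC/AUPRC, top-40%
threshold metrics, bootstrap CIs, 20-bin observed-to-expected calibration)
and a synthetic cohort generator with known ground-truth hazards.

See `docs/methods.md` for the complete model and design documentation.

## Worked example

Simulate a 1,000-patient cohort with drifting feature effects, run the
landmark-boosting and latest-value pipelines end to end, and print the
per-landmark test metrics:

```python
from landboost import ExperimentConfig, TrainConfig, run_experiment
from landboost.synthetic import preset_scenarios

config = ExperimentConfig(
    scenario=preset_scenarios(n_patients=1000, seed=42)["time_varying"],
    methods=("landmark_boosting", "latest_value"),
    horizon=5,
    grid=(TrainConfig(max_trees=100, early_stop_rounds=15, seed=42),),
    seed=42,
)
bundle = run_experiment(config)
print(bundle.metrics[["method", "landmark", "n", "prevalence", "auroc",
                      "auroc_lo", "auroc_hi"]].round(3).to_string(index=False))
```

```
           method  landmark   n  prevalence  auroc  auroc_lo  auroc_hi
landmark_boosting         0 165       0.273  0.656     0.571     0.734
landmark_boosting         1 125       0.240  0.567     0.453     0.687
landmark_boosting         2  87       0.172  0.519     0.417     0.638
landmark_boosting         3  80       0.212  0.679     0.587     0.796
landmark_boosting         4  63       0.143  0.506     0.289     0.681
     latest_value         0 165       0.273  0.656     0.571     0.734
     latest_value         1 125       0.240  0.531     0.463     0.640
     latest_value         2  87       0.172  0.524     0.390     0.637
     latest_value         3  80       0.212  0.381     0.271     0.496
     latest_value         4  63       0.143  0.431     0.293     0.609
```

Each row is one landmark's test evaluation: `n` eligible test patients,
event `prevalence` in the following year, and AUROC with its 2.5th/97.5th
bootstrap percentiles. The two methods are identical at landmark 0 (there
is nothing to carry yet) and diverge afterwards; at this small n the
intervals are wide — the packaged acceptance run (below) repeats the
comparison at n=4,000 over 10 seeds, where the sequential scheme's
late-landmark advantage is systematic. The bundle also contains per-bin
calibration tables, per-patient risk trajectories with within-landmark
percentiles, the cohort and exclusion reports, and a case-mix table.

The same pipeline runs from the shell:

```bash
landboost simulate --preset time_varying --n-patients 1000 --seed 42 --out events.csv
landboost phenotype --events events.csv --out-cohort cohort.csv --out-exclusions excl.csv
landboost run --preset time_varying --n-patients 1000 --seed 42 --outdir results/
```

`landboost featurize`, `landboost train` and `landboost evaluate` expose
the intermediate stages (design matrices as sparse triplets, model JSON
dumps, metrics from a predictions table).

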