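"""The evaluation protocols at demonstration scale.

Pretreatment comparison (random subset, 2:1 split, repeated) and baseline
hyperparameter selection (CV for k, grid search for the SVM), plus the
repeated-run aggregation used in reports.
"""
import numpy as np

import nirleaf as nl
from nirleaf.preprocess import PipelineStep

cfg = nl.SynthConfig(positions=("upper",), n_per_class=12, n_spots=3,
                     scatter_mult_range=(0.5, 1.5), scatter_add_sd=0.4,
                     baseline_slope_sd=2e-4, noise_sd=0.002, seed=4)
data = nl.simulate_dataset(cfg)
X, y = data.mean_spectra(), data.labels()
step = data.grid.step_nm

pipelines = {
    "raw": None,
    "first_derivative": lambda: nl.PreprocessPipeline(
        [PipelineStep("sg_derivative", {"window": 11, "polyorder": 2,
                                        "deriv": 1, "mode": "valid"})], step_nm=step),
    "snv": lambda: nl.PreprocessPipeline([PipelineStep("snv")]),
}
table = nl.compare_preprocessing(X, y, pipelines, model_names=("knn", "elm"),
                                 n_subset=45, n_repeats=3, seed=0)
print("mean testing accuracy (%) per pretreatment x model:")
print(table.round(2).to_string())
# Scatter dominates the raw spectra here, so derivative/SNV rows should beat
# the raw row - the direction the pretreatment comparison is meant to show.

best = nl.tune_baselines(X, y, seed=0, knn_grid=tuple(range(1, 8)),
                         svm_grid=tuple(2.0**e for e in range(-6, 7, 2)),
                         elm_grid=(40, 80), bpnn_grid=(5, 10),
                         bpnn_params={"epochs": 50, "learning_rate": 0.5},
                         n_folds=5)
print("\nselected hyperparameters:", best)

mean, sd = nl.aggregate_runs([95.86, 95.86, 96.15, 96.45, 95.86,
                              96.15, 96.45, 96.15, 96.45, 96.45])
print(f"\nrepeated-run aggregation: {nl.round_half_up(mean)} ± {nl.round_half_up(sd)}")
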