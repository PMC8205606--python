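"""NER statistic, run aggregation, comparison arithmetic and protocols."""

import numpy as np
import pandas as pd
import pytest

import nirleaf as nl
from nirleaf.errors import ParameterError
from nirleaf.evaluate import round_half_up
from nirleaf.models import TrainConfig
from nirleaf.models.cnn import CNNArchitecture, ConvLayerSpec, PoolLayerSpec
from nirleaf.preprocess import PipelineStep


class TestNER:
    def test_diagonal_matrix_is_perfect(self):
        conf = nl.ConfusionMatrix(np.diag([10, 20, 30]))
        assert nl.ner(conf) == 100.0

    def test_zero_diagonal_is_zero(self):
        conf = nl.ConfusionMatrix(np.array([[0, 5], [5, 0]]))
        assert nl.ner(conf) == 0.0

    def test_trace_326_of_338(self):
        counts = np.diag([66, 65, 65, 65, 65])
        counts[0, 1] = 12  # 12 off-diagonal errors: n = 338, trace = 326
        conf = nl.ConfusionMatrix(counts)
        assert conf.n == 338
        assert round_half_up(nl.ner(conf)) == 96.45

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError, match="empty"):
            nl.ner(nl.ConfusionMatrix(np.zeros((3, 3), dtype=int)))

    def test_matches_direct_label_fraction(self, rng):
        # independent oracle: fraction of agreeing labels
        for _ in range(100):
            n = int(rng.integers(5, 60))
            g = int(rng.integers(2, 6))
            y = rng.integers(0, g, size=n)
            p = rng.integers(0, g, size=n)
            conf = nl.confusion(y, p, g)
            assert nl.ner(conf) == pytest.approx(np.mean(y == p) * 100.0, abs=1e-12)


TABLE_UPPER_TEST = [95.86, 95.86, 96.15, 96.45, 95.86,
                    96.15, 96.45, 96.15, 96.45, 96.45]
TABLE_MIDDLE_TEST = [95.38, 94.77, 94.46, 94.77, 95.69,
                     95.69, 95.38, 95.69, 95.08, 95.08]
TABLE_LOWER_TEST = [96.49, 97.08, 97.37, 98.54, 97.66,
                    97.95, 96.2, 96.49, 97.37, 97.95]


class TestAggregation:
    def test_upper_leaf_runs_reproduce_published_summary(self):
        mean, sd = nl.aggregate_runs(TABLE_UPPER_TEST)
        assert round_half_up(mean) == 96.18
        assert round_half_up(sd) == 0.26

    def test_middle_leaf_runs(self):
        mean, sd = nl.aggregate_runs(TABLE_MIDDLE_TEST)
        assert round_half_up(mean) == 95.2
        assert round_half_up(sd) == 0.44

    def test_identical_values_have_zero_sd(self):
        mean, sd = nl.aggregate_runs([97.0] * 10)
        assert (mean, sd) == (97.0, 0.0)

    def test_single_value_rejected(self):
        with pytest.raises(ParameterError):
            nl.aggregate_runs([96.0])

    def test_matches_two_pass_oracle(self, rng):
        values = rng.uniform(80, 100, size=10)
        mean, sd = nl.aggregate_runs(values)
        m = sum(values) / len(values)
        s = (sum((v - m) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(s, abs=1e-12)

    def test_sample_not_population_sd(self):
        # the published ±0.26 implies the n−1 form; the population form
        # would round to 0.25
        _, sd = nl.aggregate_runs(TABLE_UPPER_TEST)
        pop_sd = np.std(TABLE_UPPER_TEST)
        assert round_half_up(sd) == 0.26
        assert round_half_up(pop_sd) == 0.25


class TestRelativeImprovement:
    @pytest.mark.parametrize("a,b,expected", [
        (96.18, 84.02, 14.47),
        (96.18, 66.39, 44.87),
        (55.0, 55.0, 0.0),
    ])
    def test_relative_percent_change(self, a, b, expected):
        assert round_half_up(nl.relative_improvement(a, b)) == expected

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ParameterError):
            nl.relative_improvement(90.0, 0.0)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (96.175, 96.18), (0.245, 0.25), (96.4497, 96.45), (1.005, 1.01),
    ])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestEvalReport:
    def test_repeated_runs_report(self):
        rep = nl.evaluate_runs(TABLE_UPPER_TEST)
        assert rep.n_runs == 10
        assert rep.formatted() == "96.18 ± 0.26"
        assert min(rep.per_run_values) <= rep.mean <= max(rep.per_run_values)

    def test_single_run_omits_sd(self):
        rep = nl.evaluate_runs([84.02])
        assert rep.sd is None
        assert rep.formatted() == "84.02"


@pytest.fixture(scope="module")
def scatter_dataset():
    """Small scatter-dominated set where raw spectra mislead classifiers."""
    config = nl.SynthConfig(
        positions=("upper",), n_per_class=12, n_spots=3,
        scatter_mult_range=(0.5, 1.5), scatter_add_sd=0.4,
        baseline_slope_sd=2e-4, noise_sd=0.002, seed=4,
    )
    data = nl.simulate_dataset(config)
    return data.mean_spectra(), data.labels(), data.grid.step_nm


class TestComparePreprocessing:
    def test_derivative_beats_raw_on_scatter_corrupted_data(self, scatter_dataset):
        X, y, step_nm = scatter_dataset
        pipelines = {
            "raw": None,
            "first_derivative": lambda: nl.PreprocessPipeline(
                [PipelineStep("sg_derivative",
                              {"window": 11, "polyorder": 2, "deriv": 1,
                               "mode": "valid"})], step_nm=step_nm),
        }
        table = nl.compare_preprocessing(X, y, pipelines, model_names=("knn",),
                                         n_subset=45, n_repeats=3, seed=0)
        assert table.loc["first_derivative", "knn"] >= table.loc["raw", "knn"]

    def test_deterministic_under_fixed_seed(self, scatter_dataset):
        X, y, step_nm = scatter_dataset
        pipelines = {"snv": lambda: nl.PreprocessPipeline([PipelineStep("snv")])}
        tables = [nl.compare_preprocessing(X, y, pipelines, model_names=("knn", "elm"),
                                           n_subset=40, n_repeats=1, seed=5)
                  for _ in range(2)]
        pd.testing.assert_frame_equal(tables[0], tables[1])
        assert tables[0].shape == (1, 2)


def tiny_cnn_factory(kernel_size, input_length, n_classes):
    return CNNArchitecture(
        input_length=input_length, n_classes=n_classes,
        features=[ConvLayerSpec(6, kernel_size), PoolLayerSpec(2, 2)],
        dense_units=(12,),
    )


@pytest.fixture(scope="module")
def tiny_classed_data():
    rng = np.random.default_rng(2)
    n, L = 60, 24
    y = np.tile(np.arange(3), n // 3)
    X = rng.normal(size=(n, L)) * 0.2
    for c in range(3):
        X[y == c, c * 6 : c * 6 + 6] += 1.5
    return X, y


class TestTuneCNN:
    def test_singleton_grids_return_that_config(self, tiny_classed_data):
        X, y = tiny_classed_data
        best, curves = nl.tune_cnn(
            X, y, grids={"kernel": (3,), "batch": (16,), "epochs": (4,)},
            n_val=15, n_repeats=1, seed=0,
            base_train_config=TrainConfig(epochs=4, batch_size=16),
            arch_factory=tiny_cnn_factory)
        assert best == {"kernel": 3, "batch": 16, "epochs": 4}
        for factor, frame in curves.items():
            assert len(frame) == 1

    def test_curves_have_one_entry_per_grid_value(self, tiny_classed_data):
        X, y = tiny_classed_data
        grids = {"kernel": (3, 5), "batch": (16, 32), "epochs": (2, 5)}
        best, curves = nl.tune_cnn(
            X, y, grids=grids, n_val=15, n_repeats=1, seed=0,
            base_train_config=TrainConfig(epochs=3, batch_size=16),
            arch_factory=tiny_cnn_factory)
        for factor, values in grids.items():
            assert list(curves[factor].index) == list(values)
        assert best["kernel"] in grids["kernel"]

    def test_trained_beats_undertrained(self, tiny_classed_data):
        X, y = tiny_classed_data
        _, curves = nl.tune_cnn(
            X, y, grids={"kernel": (3,), "batch": (16,), "epochs": (1, 25)},
            n_val=15, n_repeats=2, seed=1,
            base_train_config=TrainConfig(batch_size=16),
            arch_factory=tiny_cnn_factory)
        vals = curves["epochs"]["validation"]
        assert vals.loc[25] >= vals.loc[1]


class TestTuneBaselines:
    def test_cv_prefers_k_above_one_on_noisy_overlap(self):
        # heavily overlapping classes: the 1-NN rule memorizes noise and
        # cross-validation should select a larger neighborhood
        rng = np.random.default_rng(8)
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1.0, size=(n, 2)) + y[:, None] * 0.8
        best = nl.tune_baselines(X, y, seed=0, knn_grid=tuple(range(1, 12)),
                                 svm_grid=(1.0,), elm_grid=(20,), bpnn_grid=(4,),
                                 bpnn_params={"epochs": 20})
        assert best["knn"]["k"] > 1

    def test_gamma_tracks_data_scale(self):
        # RBF width must shrink as squared distances grow: tuning the same
        # ring-vs-core problem at 4x the radius cannot select a larger gamma
        rng = np.random.default_rng(3)
        n = 90
        r = np.concatenate([rng.uniform(0, 0.8, n // 2), rng.uniform(1.6, 2.4, n // 2)])
        theta = rng.uniform(0, 2 * np.pi, n)
        X1 = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        y = np.repeat([0, 1], n // 2)
        grid = tuple(2.0**e for e in range(-8, 5))
        kw = dict(seed=0, knn_grid=(3,), elm_grid=(20,), bpnn_grid=(4,),
                  bpnn_params={"epochs": 10}, n_folds=5)
        g_small = nl.tune_baselines(X1, y, svm_grid=grid, **kw)["svm"]["gamma"]
        g_large = nl.tune_baselines(4.0 * X1, y, svm_grid=grid, **kw)["svm"]["gamma"]
        assert g_large <= g_small

    def test_deterministic_under_fixed_seed(self, tiny_classed_data):
        X, y = tiny_classed_data
        kw = dict(seed=9, knn_grid=(1, 3, 5), svm_grid=(0.5, 2.0),
                  elm_grid=(10, 30), bpnn_grid=(3, 6),
                  bpnn_params={"epochs": 15}, n_folds=5)
        assert nl.tune_baselines(X, y, **kw) == nl.tune_baselines(X, y, **kw)
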