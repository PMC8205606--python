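"""Evaluation statistics and the three experimental protocols.

The discriminant accuracy NER is the percentage of samples on the diagonal
of the G x G confusion matrix:

    NER = sum_g n_gg / n * 100%

Repeated runs are summarized as mean ± sample (n−1) standard deviation,
reported half-up-rounded to two decimals; model-to-model gains are relative
percent changes, 100·(a − b)/b.

Protocols: ``compare_preprocessing`` (random subset, 2:1 split, repeated,
one mean accuracy per pretreatment x model cell), ``tune_cnn`` (one-factor-
at-a-time sweep of kernel size, batch size and epochs against a held-out
validation subset), and ``tune_baselines`` (k by 10-fold cross-validation,
SVM C/gamma by powers-of-two grid search, ELM/BPNN hidden-layer width by
seeded validation selection).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError
from .models import (
    BPNNClassifier,
    BPNNConfig,
    CNNClassifier,
    ELMClassifier,
    ELMConfig,
    KNNClassifier,
    KNNConfig,
    SVMClassifier,
    SVMConfig,
    TrainConfig,
    default_architecture,
)

__all__ = [
    "round_half_up",
    "ConfusionMatrix",
    "confusion",
    "ner",
    "aggregate_runs",
    "relative_improvement",
    "EvalReport",
    "evaluate_runs",
    "compare_preprocessing",
    "tune_cnn",
    "tune_baselines",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up decimal rounding, the convention used in all reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with true class g on row g, predicted class on the column."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ParameterError(f"confusion matrix must be square, got {c.shape}")
        if (c < 0).any():
            raise ParameterError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def n_categories(self) -> int:
        return int(np.asarray(self.counts).shape[0])


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Count (true, predicted) pairs over a fixed class set 0..n_classes-1."""
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts=counts)


def ner(conf: ConfusionMatrix) -> float:
    """Discriminant accuracy in percent: 100 x trace / n (full precision)."""
    c = np.asarray(conf.counts)
    n = c.sum()
    if n == 0:
        raise ParameterError("empty evaluation: confusion matrix has no samples")
    return float(np.trace(c) / n * 100.0)


def aggregate_runs(values) -> tuple[float, float]:
    """Mean and sample (n−1) standard deviation of repeated-run accuracies."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("need >= 2 run values for a standard deviation")
    return float(values.mean()), float(values.std(ddof=1))


def relative_improvement(a: float, b: float) -> float:
    """Relative percent change of a over baseline b: 100 x (a − b)/b."""
    if b <= 0:
        raise ParameterError(f"baseline must be positive, got {b}")
    return 100.0 * (a - b) / b


@dataclass
class EvalReport:
    """Repeated-run summary for one model on one dataset split."""

    per_run_values: list[float]
    mean: float
    sd: float | None
    n_runs: int

    def formatted(self) -> str:
        m = round_half_up(self.mean)
        if self.sd is None:
            return f"{m:g}"
        return f"{m:g} ± {round_half_up(self.sd):g}"


def evaluate_runs(values) -> EvalReport:
    values = [float(v) for v in values]
    if len(values) == 1:
        return EvalReport(values, values[0], None, 1)
    mean, sd = aggregate_runs(values)
    return EvalReport(values, mean, sd, len(values))


# --------------------------------------------------------------------------
# model registry used by the protocol drivers
# --------------------------------------------------------------------------

def _make_model(name: str, seed: int, n_classes: int, params: dict | None = None):
    params = dict(params or {})
    if name == "knn":
        return KNNClassifier(KNNConfig(n_classes=n_classes, **params))
    if name == "svm":
        return SVMClassifier(SVMConfig(n_classes=n_classes, **params))
    if name == "elm":
        return ELMClassifier(ELMConfig(seed=seed, n_classes=n_classes, **params))
    if name == "bpnn":
        params.setdefault("epochs", 300)
        return BPNNClassifier(BPNNConfig(seed=seed, n_classes=n_classes, **params))
    if name == "cnn":
        arch = params.pop("arch", None) or default_architecture(n_classes=n_classes)
        tc = params.pop("train_config", None) or TrainConfig()
        return CNNClassifier(arch, replace(tc, seed=seed))
    raise ParameterError(f"unknown model {name!r}")


#: deterministic models are single-run in reports (no ± column)
DETERMINISTIC_MODELS = frozenset({"knn", "svm"})


def compare_preprocessing(
    X_raw,
    y,
    pipelines: dict,
    model_names=("knn", "elm"),
    n_subset: int = 450,
    ratio: float = 2 / 3,
    n_repeats: int = 5,
    seed: int = 0,
    model_params: dict | None = None,
) -> pd.DataFrame:
    """Mean accuracy per (pretreatment, model) cell.

    Each repeat draws ``n_subset`` samples without replacement, splits them
    at ``ratio`` (train share, default 2:1), fits each pipeline on the
    training part only, trains each model and scores NER on the held-out
    part.  Returns a pretreatment x model table of repeat-mean accuracies.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X_raw.shape[0]
    if n < n_subset:
        raise ParameterError(f"dataset has {n} rows, fewer than n_subset={n_subset}")
    n_classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(index=list(pipelines), columns=list(model_names), dtype=float)
    accs = {key: {m: [] for m in model_names} for key in pipelines}
    for rep in range(n_repeats):
        subset = rng.choice(n, size=n_subset, replace=False)
        n_train = int(round(n_subset * ratio))
        train_idx, test_idx = subset[:n_train], subset[n_train:]
        for key, make_pipeline in pipelines.items():
            pipe = make_pipeline() if callable(make_pipeline) else make_pipeline
            if pipe is None:
                Xtr, Xte = X_raw[train_idx], X_raw[test_idx]
            else:
                Xtr = pipe.fit_transform(X_raw[train_idx])
                Xte = pipe.transform(X_raw[test_idx])
            for mname in model_names:
                model = _make_model(mname, seed=seed + rep, n_classes=n_classes,
                                    params=(model_params or {}).get(mname))
                model.fit(Xtr, y[train_idx])
                accs[key][mname].append(model.score_ner(Xte, y[test_idx]))
    for key in pipelines:
        for mname in model_names:
            table.loc[key, mname] = float(np.mean(accs[key][mname]))
    return table


DEFAULT_CNN_GRIDS = {
    "kernel": (5, 9, 13, 17, 21),
    "batch": (16, 32, 64, 128, 256),
    "epochs": (50, 100, 150, 200, 300, 500, 750, 1000),
}


def tune_cnn(
    X_train,
    y_train,
    grids: dict | None = None,
    n_val: int = 150,
    n_repeats: int = 5,
    seed: int = 0,
    base_train_config: TrainConfig | None = None,
    input_length: int | None = None,
    arch_factory=default_architecture,
):
    """One-factor-at-a-time sweep: kernel size, then batch size, then epochs.

    For each grid value, ``n_repeats`` random calibration/validation splits
    (``n_val`` held out) are trained and scored; the value with the best
    mean validation accuracy (first on ties) is fixed before the next
    factor is swept.  Returns ``(best_config_dict, curves)`` where curves
    maps factor -> DataFrame with calibration/validation accuracy per value.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    n = X_train.shape[0]
    if n <= n_val:
        raise ParameterError(f"training set of {n} must exceed n_val={n_val}")
    grids = {**DEFAULT_CNN_GRIDS, **(grids or {})}
    base_tc = base_train_config or TrainConfig()
    n_classes = int(y_train.max()) + 1
    length = input_length or X_train.shape[1]

    best = {"kernel": None, "batch": base_tc.batch_size, "epochs": base_tc.epochs}
    curves: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        splits.append((perm[n_val:], perm[:n_val]))

    def run(kernel, batch, epochs, run_seed):
        arch = arch_factory(kernel_size=kernel, input_length=length,
                            n_classes=n_classes)
        tc = replace(base_tc, batch_size=batch, epochs=epochs, seed=run_seed)
        cal_acc, val_acc = [], []
        for rep, (cal, val) in enumerate(splits):
            model = CNNClassifier(arch, replace(tc, seed=run_seed + rep))
            model.fit(X_train[cal], y_train[cal])
            cal_acc.append(model.score_ner(X_train[cal], y_train[cal]))
            val_acc.append(model.score_ner(X_train[val], y_train[val]))
        return float(np.mean(cal_acc)), float(np.mean(val_acc))

    for factor in ("kernel", "batch", "epochs"):
        rows = []
        for value in grids[factor]:
            kernel = value if factor == "kernel" else best["kernel"]
            batch = value if factor == "batch" else best["batch"]
            epochs = value if factor == "epochs" else best["epochs"]
            if kernel is None:  # kernel swept first; never happens afterwards
                kernel = grids["kernel"][0]
            cal, val = run(kernel, batch, epochs, seed)
            rows.append({"value": value, "calibration": cal, "validation": val})
        frame = pd.DataFrame(rows).set_index("value")
        curves[factor] = frame
        best[factor] = frame["validation"].idxmax()  # first index on ties
    return best, curves


def tune_baselines(
    X_train,
    y_train,
    seed: int = 0,
    knn_grid=tuple(range(1, 16)),
    svm_grid=tuple(2.0**e for e in range(-10, 11)),
    elm_grid=tuple(range(50, 201, 25)),
    bpnn_grid=tuple(range(1, 31)),
    bpnn_params: dict | None = None,
    n_folds: int = 10,
    val_fraction: float = 0.25,
) -> dict:
    """Select baseline hyperparameters the way the comparison study did.

    KNN neighbors by ``n_folds``-fold cross-validated accuracy; SVM (C,
    gamma) by grid search over powers of two with the same CV; ELM and BPNN
    hidden-layer widths by accuracy on one seeded validation split.
    Returns ``{model: {param: value, ...}, ...}``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    n = X_train.shape[0]
    if n < n_folds:
        raise ParameterError(f"{n} samples cannot form {n_folds} folds")
    n_classes = int(y_train.max()) + 1
    kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X_train, y_train))

    def cv_score(make_model):
        accs = []
        for tr, te in folds:
            model = make_model()
            model.fit(X_train[tr], y_train[tr])
            accs.append(model.score_ner(X_train[te], y_train[te]))
        return float(np.mean(accs))

    # KNN: k by CV accuracy
    knn_scores = [
        (cv_score(lambda k=k: KNNClassifier(KNNConfig(k=k, n_classes=n_classes))), -k, k)
        for k in knn_grid if k <= min(len(tr) for tr, _ in folds)
    ]
    best_k = max(knn_scores)[2]

    # SVM: (C, gamma) grid; ties resolve to the first grid point scanned
    best_svm, best_svm_acc = None, -np.inf
    for C in svm_grid:
        for gamma in svm_grid:
            acc = cv_score(lambda C=C, g=gamma: SVMClassifier(
                SVMConfig(C=C, gamma=g, n_classes=n_classes)))
            if acc > best_svm_acc:
                best_svm_acc, best_svm = acc, (C, gamma)

    # ELM / BPNN: width by one seeded validation split
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    val, cal = perm[:n_val], perm[n_val:]

    def val_score(make_model):
        model = make_model()
        model.fit(X_train[cal], y_train[cal])
        return model.score_ner(X_train[val], y_train[val])

    elm_scores = [
        (val_score(lambda h=h: ELMClassifier(ELMConfig(n_hidden=h, seed=seed,
                                                       n_classes=n_classes))), -h, h)
        for h in elm_grid
    ]
    bp = dict(bpnn_params or {})
    bpnn_scores = [
        (val_score(lambda h=h: BPNNClassifier(BPNNConfig(n_hidden=h, seed=seed,
                                                         n_classes=n_classes, **bp))), -h, h)
        for h in bpnn_grid
    ]
    return {
        "knn": {"k": best_k},
        "svm": {"C": best_svm[0], "gamma": best_svm[1]},
        "elm": {"n_hidden": max(elm_scores)[2]},
        "bpnn": {"n_hidden": max(bpnn_scores)[2]},
    }
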