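"""Model selection and evaluation machinery.

Covers the experimental protocol used to compare the trainers: constructive
hidden-layer growth (add one neuron at a time, stop when the validation
accuracy plateaus), repeated independent trainings summarised by mean /
population variance / range, confusion matrices, and the per-class
diagnosis-rate metrics used for the benign/malignant breast-tumor task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .datasets import LabeledDataset, SplitSpec, make_blobs_dataset, minmax_scale, split_train_test
from .exceptions import InvalidInputError
from .voting import VotingEnsemble, ensemble_predict, train_ensemble

__all__ = [
    "TrainerConfig",
    "GrowthResult",
    "RunStatistics",
    "ConfusionMatrix",
    "accuracy",
    "fit_predictor",
    "run_growth",
    "grow_hidden_layer",
    "repeated_runs",
    "confusion",
    "diagnosis_metrics",
    "repeated_diagnosis_runs",
    "blob_trend_study",
]


@dataclass(frozen=True)
class TrainerConfig:
    """Everything needed to train one (ensemble of) network(s), except the seed."""

    trainer: str = "dpelm"  # "elm" | "dpelm"
    K: int = 1
    L: int = 10
    activation: str = "tan"
    interval: tuple[float, float] = (-1.0, 1.0)
    clip_eps: float = 1e-6

    def with_L(self, L: int) -> "TrainerConfig":
        return replace(self, L=L)


def fit_predictor(train, config: TrainerConfig, master_seed: int) -> VotingEnsemble:
    """Train a voting ensemble per ``config`` (a single model is the K=1 case)."""
    kwargs = {"clip_eps": config.clip_eps} if config.trainer == "dpelm" else {}
    return train_ensemble(
        train,
        K=config.K,
        base_trainer=config.trainer,
        L=config.L,
        activation=config.activation,
        interval=config.interval,
        master_seed=master_seed,
        **kwargs,
    )


def accuracy(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    return float(np.mean(y_true == y_pred))


# --- hidden-layer growth ---------------------------------------------------


@dataclass
class GrowthResult:
    L_best: int
    history: list[tuple[int, float]]
    stop_reason: str  # "plateau" | "L_max"


def run_growth(
    accuracy_for_L: Callable[[int], float],
    L_max: int,
    threshold: float = 1e-3,
    patience: int = 3,
) -> GrowthResult:
    """The growth stopping rule, independent of any trainer.

    Evaluates L = 1, 2, ... and stops once the improvement of the running
    best accuracy has stayed below ``threshold`` for ``patience`` consecutive
    steps ("plateau"), or at ``L_max``.  ``L_best`` is the smallest L whose
    accuracy equals the best seen.
    """
    if L_max < 1 or patience < 1 or not (0.0 <= threshold < 1.0):
        raise InvalidInputError("require L_max >= 1, patience >= 1, threshold in [0, 1)")
    history: list[tuple[int, float]] = []
    best = -np.inf
    stall = 0
    stop_reason = "L_max"
    for L in range(1, L_max + 1):
        acc = float(accuracy_for_L(L))
        history.append((L, acc))
        if acc - best < threshold:
            stall += 1
        else:
            stall = 0
        best = max(best, acc)
        if stall >= patience:
            stop_reason = "plateau"
            break
    accs = [a for _, a in history]
    L_best = history[int(np.argmax(accs))][0]  # argmax takes the first => smallest L
    return GrowthResult(L_best, history, stop_reason)


def grow_hidden_layer(
    train,
    val,
    trainer_config: TrainerConfig,
    L_max: int = 100,
    threshold: float = 1e-3,
    patience: int = 3,
    seed: int = 0,
    repeats_per_L: int = 1,
) -> GrowthResult:
    """Choose the hidden width by constructive growth on a validation set.

    One seeded model is trained per L (seed = ``seed + L``, so the run is
    deterministic); ``repeats_per_L > 1`` averages the validation accuracy
    over that many seeds for noisy curves.
    """

    def acc_for_L(L: int) -> float:
        cfg = trainer_config.with_L(L)
        accs = [
            accuracy(val.labels, ensemble_predict(fit_predictor(train, cfg, seed + L + 1000 * r), val.X))
            for r in range(repeats_per_L)
        ]
        return float(np.mean(accs))

    return run_growth(acc_for_L, L_max, threshold, patience)


# --- repeated-run stability -------------------------------------------------


@dataclass
class RunStatistics:
    """Per-configuration accuracy summary over repeated independent trainings."""

    accuracies: np.ndarray
    mean: float
    variance: float  # population variance (divide by number of runs)
    range: float  # max - min

    @classmethod
    def from_accuracies(cls, accs: Sequence[float]) -> "RunStatistics":
        accs = np.asarray(accs, dtype=float)
        if accs.size < 1:
            raise InvalidInputError("need at least one run")
        return cls(
            accuracies=accs,
            mean=float(accs.mean()),
            variance=float(accs.var()),
            range=float(accs.max() - accs.min()),
        )


def repeated_runs(
    train,
    test,
    trainer_config: TrainerConfig,
    runs: int,
    master_seed: int = 0,
) -> RunStatistics:
    """Train/evaluate ``runs`` times; run r uses master seed ``master_seed + r``."""
    if runs < 1:
        raise InvalidInputError("runs must be >= 1")
    accs = []
    for r in range(1, runs + 1):
        ens = fit_predictor(train, trainer_config, master_seed + r * 1000)
        accs.append(accuracy(test.labels, ensemble_predict(ens, test.X)))
    return RunStatistics.from_accuracies(accs)


# --- confusion matrix and diagnosis metrics ---------------------------------


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class (1-based labels)."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, n_classes: int | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred must have equal length")
    m = n_classes or int(max(y_true.max(), y_pred.max()))
    if y_true.min() < 1 or y_pred.min() < 1 or y_true.max() > m or y_pred.max() > m:
        raise InvalidInputError(f"labels must lie in 1..{m}")
    counts = np.zeros((m, m), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts)


def diagnosis_metrics(cm: ConfusionMatrix, class_names: Sequence[str] | None = None) -> dict:
    """Class-conditional recalls and overall accuracy from a confusion matrix.

    For a benign/malignant task the per-class rates are exactly the benign
    and malignant diagnosis rates; ``average_accuracy`` is trace / total.
    A class absent from the test set yields a NaN rate plus a warning, never
    a silent zero.
    """
    counts = cm.counts
    row_sums = counts.sum(axis=1)
    rates = np.full(counts.shape[0], np.nan)
    for c in range(counts.shape[0]):
        if row_sums[c] == 0:
            name = class_names[c] if class_names else c + 1
            warnings.warn(f"class {name!r} absent from the test set; its rate is undefined")
        else:
            rates[c] = counts[c, c] / row_sums[c]
    return {
        "per_class_rate": rates,
        "average_accuracy": float(np.trace(counts) / cm.total) if cm.total else float("nan"),
        "class_names": list(class_names) if class_names is not None else None,
    }


def repeated_diagnosis_runs(
    ds: LabeledDataset,
    n_train: int,
    trainer_config: TrainerConfig,
    runs: int = 20,
    master_seed: int = 0,
) -> dict:
    """The full diagnosis protocol: reshuffled stratified split + train + metrics, repeated.

    Each run r draws a fresh stratified split (seed ``master_seed + r``;
    largest-remainder per-class train counts) and a fresh training (same
    seed), then records the test accuracy and per-class diagnosis rates.
    Returns run statistics, mean rates, and the (constant) split composition.
    """
    accs, rate_rows = [], []
    split_counts = None
    for r in range(1, runs + 1):
        train, test = split_train_test(ds, SplitSpec(n_train=n_train, stratified=True, seed=master_seed + r))
        split_counts = {
            "train_per_class": train.class_counts().tolist(),
            "test_per_class": test.class_counts().tolist(),
        }
        ens = fit_predictor(train, trainer_config, master_seed + r * 1000)
        pred = ensemble_predict(ens, test.X)
        metrics = diagnosis_metrics(confusion(test.labels, pred, ds.n_classes), ds.class_names)
        accs.append(metrics["average_accuracy"])
        rate_rows.append(metrics["per_class_rate"])
    stats = RunStatistics.from_accuracies(accs)
    return {
        "run_statistics": stats,
        "mean_per_class_rate": np.nanmean(np.vstack(rate_rows), axis=0),
        "split_composition": split_counts,
        "class_names": list(ds.class_names),
    }


# --- scaled-down trend study -------------------------------------------------


def blob_trend_study(
    n_seeds: int = 20,
    n_features: int = 8,
    m: int = 2,
    N: int = 600,
    separation: float = 2.5,
    noise_sd: float = 1.0,
    K: int = 7,
    runs: int = 20,
    L_max: int = 40,
    threshold: float = 1e-3,
    patience: int = 3,
    master_seed: int = 0,
) -> dict:
    """Compare growth behaviour and run-to-run stability of DPELM vs ELM.

    For each of ``n_seeds`` synthetic Gaussian-cluster datasets: grow a
    single-model DPELM and ELM on a train/validation split and record the
    plateau width ``L_best``; then, at the fixed width L* = median ELM
    ``L_best``, train the K-member voting ensembles ``runs`` times on a
    fixed train/test split and record the accuracy variance.  Reported
    medians across seeds summarise the two trends: the analytic solve
    plateaus at smaller widths, and its ensemble accuracy varies less from
    run to run.

    Features are min-max scaled into [0, 1] before splitting: with the
    circular tangent activation, unscaled features push the random-weight
    trainer's pre-activations across poles of tan, which is a property of
    the activation, not of the trainers being compared.
    """
    L_elm, L_dpelm = [], []
    datasets = []
    for s in range(1, n_seeds + 1):
        seed = master_seed + s
        ds = minmax_scale(make_blobs_dataset(n_features, m, N, separation, noise_sd, seed=seed))
        train_all, test = split_train_test(ds, SplitSpec(n_train=2 * N // 3, seed=seed))
        train, val = split_train_test(train_all, SplitSpec(n_train=3 * train_all.n_samples // 4, seed=seed))
        datasets.append((train_all, test))
        for trainer, sink in (("elm", L_elm), ("dpelm", L_dpelm)):
            res = grow_hidden_layer(
                train, val, TrainerConfig(trainer=trainer, K=1), L_max, threshold, patience, seed=seed
            )
            sink.append(res.L_best)

    L_star = int(np.median(L_elm))
    var_elm, var_dpelm, acc_elm, acc_dpelm = [], [], [], []
    for s, (train_all, test) in enumerate(datasets, start=1):
        for trainer, vsink, asink in (("elm", var_elm, acc_elm), ("dpelm", var_dpelm, acc_dpelm)):
            stats = repeated_runs(
                train_all, test, TrainerConfig(trainer=trainer, K=K, L=L_star), runs, master_seed + s
            )
            vsink.append(stats.variance)
            asink.append(stats.mean)

    return {
        "L_best_elm": L_elm,
        "L_best_dpelm": L_dpelm,
        "median_L_elm": float(np.median(L_elm)),
        "median_L_dpelm": float(np.median(L_dpelm)),
        "L_star": L_star,
        "median_variance_velm": float(np.median(var_elm)),
        "median_variance_vdpelm": float(np.median(var_dpelm)),
        "mean_accuracy_velm": float(np.mean(acc_elm)),
        "mean_accuracy_vdpelm": float(np.mean(acc_dpelm)),
    }
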