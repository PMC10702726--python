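"""Dataset containers, delimited-text loading, splits, and synthetic generators.

Conventions follow the classification-matrix layout used throughout the
package: the feature matrix ``X`` is *features x samples* (n x N) and the
one-hot target matrix ``T`` is *classes x samples* (m x N).  Labels are
1-based integers in ``{1..m}``; ``class_names[c-1]`` names class ``c`` in
order of first appearance.

Two synthetic families make the whole pipeline testable offline:

* *teacher* datasets generated exactly by a known network
  ``T = beta h(Omega X - B)`` — the regime in which the double
  pseudo-inverse solve recovers a zero-residual fit; and
* *Gaussian blob* tasks with controllable cluster separation, a stand-in for
  benchmark tabular classification data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activations import ActivationPair, apply, get_activation
from .exceptions import (
    DegenerateDatasetError,
    InfeasibleParameterError,
    InfeasibleSplitError,
    InvalidInputError,
    MissingDataError,
    ParseError,
)

__all__ = [
    "LabeledDataset",
    "RegressionDataset",
    "SplitSpec",
    "TeacherModel",
    "one_hot",
    "load_csv_dataset",
    "split_train_test",
    "make_teacher_dataset",
    "make_blobs_dataset",
    "minmax_scale",
    "save_dataset",
]

_MAX_REDRAWS = 50


def one_hot(labels: np.ndarray, m: int) -> np.ndarray:
    """m x N indicator matrix with a single 1 per column at row ``labels[j]`` (1-based)."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > m:
        raise InvalidInputError(f"labels must lie in 1..{m}")
    T = np.zeros((m, labels.size))
    T[labels - 1, np.arange(labels.size)] = 1.0
    return T


@dataclass
class LabeledDataset:
    """Classification dataset: features ``X`` (n x N), 1-based ``labels``, one-hot ``T``."""

    X: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    T: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D (features x samples)")
        if not np.isfinite(self.X).all():
            raise InvalidInputError("X contains non-finite entries")
        if self.labels.shape != (self.X.shape[1],):
            raise InvalidInputError("labels length must equal the number of samples")
        m = len(self.class_names)
        if m < 2:
            raise DegenerateDatasetError("a classification dataset needs at least two classes")
        if self.T is None:
            self.T = one_hot(self.labels, m)

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """New dataset over columns ``idx``; the class catalogue is shared unchanged."""
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(self.X[:, idx], self.labels[idx], list(self.class_names))


@dataclass
class RegressionDataset:
    """Feature matrix plus real-valued target matrix — the teacher-network fixture."""

    X: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.X.shape[1] != self.T.shape[1]:
            raise InvalidInputError("X and T must have the same number of columns")


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible train/test split request."""

    n_train: int
    stratified: bool = True
    seed: int = 0


@dataclass
class TeacherModel:
    """The known generating network behind a teacher dataset."""

    Omega_true: np.ndarray
    b_true: np.ndarray
    beta_true: np.ndarray
    activation: ActivationPair

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self.beta_true @ apply(self.activation, self.Omega_true @ X - self.b_true[:, None])


def load_csv_dataset(
    path,
    label_column: int | str = -1,
    delimiter: str = ",",
    header: bool = False,
) -> LabeledDataset:
    """Load a UCI-style delimited table into a :class:`LabeledDataset`.

    The label column may be given by integer position (negative allowed) or,
    with ``header=True``, by column name.  All remaining columns must parse
    as real numbers; missing values raise (no imputation); a single-class
    file raises :class:`DegenerateDatasetError`.  Classes are numbered by
    first appearance in the file.
    """
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None, dtype=str, skipinitialspace=True)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise InvalidInputError(f"{path}: need at least 2 rows and 2 columns")

    if isinstance(label_column, str):
        if label_column not in df.columns:
            raise InvalidInputError(f"label column {label_column!r} not found in header {list(df.columns)}")
        label_pos = df.columns.get_loc(label_column)
    else:
        label_pos = label_column % df.shape[1]

    raw_labels = df.iloc[:, label_pos].astype(str).str.strip()
    feat = df.drop(columns=df.columns[label_pos])
    if feat.isna().any().any() or raw_labels.isna().any():
        rows = np.where(feat.isna().any(axis=1))[0]
        raise MissingDataError(f"{path}: missing values (first offending data row {rows[0] if rows.size else '?'})")

    numeric = feat.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & feat.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{path}: cell at data row {r}, column {feat.columns[c]!r} "
            f"({feat.iat[r, c]!r}) is not a real number"
        )

    class_names = list(dict.fromkeys(raw_labels))
    if len(class_names) < 2:
        raise DegenerateDatasetError(f"{path}: label column is constant ({class_names[0]!r})")
    lab_to_int = {name: i + 1 for i, name in enumerate(class_names)}
    labels = raw_labels.map(lab_to_int).to_numpy()
    X = numeric.to_numpy(dtype=float).T  # n x N orientation
    if not np.isfinite(X).all():
        raise MissingDataError(f"{path}: non-finite feature values")
    return LabeledDataset(X, labels, [str(c) for c in class_names])


def _largest_remainder(counts: np.ndarray, n_train: int, N: int) -> np.ndarray:
    """Apportion n_train across classes proportionally to counts (largest remainder)."""
    quota = counts * n_train / N
    base = np.floor(quota).astype(int)
    rem = quota - base
    leftover = n_train - base.sum()
    # ties: larger remainder first, then smaller class index
    order = sorted(range(len(counts)), key=lambda c: (-rem[c], c))
    for c in order[: int(leftover)]:
        base[c] += 1
    return base


def split_train_test(ds: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic seeded train/test partition of ``ds``.

    With ``stratified=True`` the per-class training counts follow the
    largest-remainder apportionment of ``n_train`` across class frequencies
    (e.g. class counts (357, 212) with ``n_train=450`` give (282, 168)).
    Raises :class:`InfeasibleSplitError` if either partition would miss a class.
    """
    N = ds.n_samples
    if not (0 < spec.n_train < N):
        raise InvalidInputError(f"n_train must lie strictly between 0 and {N}, got {spec.n_train}")
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        counts = ds.class_counts()
        train_counts = _largest_remainder(counts, spec.n_train, N)
        if np.any(train_counts == 0) or np.any(train_counts == counts):
            bad = int(np.argmax((train_counts == 0) | (train_counts == counts))) + 1
            raise InfeasibleSplitError(
                f"stratified split n_train={spec.n_train} leaves class {bad} empty in one partition"
            )
        train_idx = []
        for c in range(1, ds.n_classes + 1):
            members = np.where(ds.labels == c)[0]
            perm = rng.permutation(members)
            train_idx.append(perm[: train_counts[c - 1]])
        train_idx = np.sort(np.concatenate(train_idx))
    else:
        perm = rng.permutation(N)
        train_idx = np.sort(perm[: spec.n_train])

    mask = np.zeros(N, dtype=bool)
    mask[train_idx] = True
    test_idx = np.where(~mask)[0]
    train, test = ds.subset(train_idx), ds.subset(test_idx)
    for part, tag in ((train, "train"), (test, "test")):
        if np.unique(part.labels).size < ds.n_classes:
            raise InfeasibleSplitError(f"{tag} partition is missing at least one class")
    return train, test


def make_teacher_dataset(
    n: int,
    L_true: int,
    m: int,
    N: int,
    activation: str | ActivationPair = "tan",
    interval: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> tuple[RegressionDataset, TeacherModel]:
    """Targets generated exactly by a known network ``T = beta h(Omega X - B)``.

    Requires ``N <= n`` so that ``X`` can have full column rank (the regime
    in which the analytic input-weight solve is exact) and ``m <= L_true`` so
    that ``beta`` can have full row rank.
    """
    a1, a2 = interval
    if a1 >= a2:
        raise InvalidInputError(f"interval must satisfy a1 < a2, got {interval}")
    if m > L_true:
        raise InfeasibleParameterError(f"m={m} > L_true={L_true}: beta cannot have full row rank m")
    if N > n:
        raise InfeasibleParameterError(
            f"N={N} > n={n}: X cannot have full column rank N, breaking the exact-recovery regime"
        )
    act = get_activation(activation)
    rng = np.random.default_rng(seed)

    for _ in range(_MAX_REDRAWS):
        X = rng.uniform(a1, a2, size=(n, N))
        if np.linalg.matrix_rank(X) == N:
            break
    else:  # pragma: no cover - vanishing probability
        raise InfeasibleParameterError("could not draw a full-column-rank X")

    Omega = rng.uniform(a1, a2, size=(L_true, n))
    b = rng.uniform(a1, a2, size=L_true)
    for _ in range(_MAX_REDRAWS):
        beta = rng.uniform(a1, a2, size=(m, L_true))
        if np.linalg.matrix_rank(beta) == m:
            break
    else:  # pragma: no cover
        raise InfeasibleParameterError("could not draw a full-row-rank beta")

    teacher = TeacherModel(Omega, b, beta, act)
    return RegressionDataset(X, teacher.forward(X)), teacher


def make_blobs_dataset(
    n: int,
    m: int,
    N: int,
    separation: float,
    noise_sd: float,
    seed: int = 0,
    class_sizes=None,
) -> LabeledDataset:
    """Gaussian-cluster classification task with controllable separation.

    Class ``c`` is centred at ``separation * u_c`` for ``m`` orthonormal unit
    directions (pairwise 90 degrees, satisfying the >= 60 degree spacing).
    Class sizes are near-equal (differ by at most one) unless ``class_sizes``
    explicitly lists them; sample order is shuffled.  Deterministic per seed.
    """
    if class_sizes is None:
        if N < 4 * m:
            raise InvalidInputError(f"need N >= 4m samples, got N={N}, m={m}")
        base, extra = divmod(N, m)
        sizes = np.array([base + (1 if c < extra else 0) for c in range(m)])
    else:
        sizes = np.asarray(class_sizes, dtype=int)
        if sizes.size != m or np.any(sizes < 2):
            raise InvalidInputError("class_sizes must list m sizes, each >= 2")
        N = int(sizes.sum())
    if m > n:
        raise InfeasibleParameterError(f"m={m} > n={n}: cannot place m orthonormal centres in R^n")
    if noise_sd <= 0:
        raise InvalidInputError("noise_sd must be positive")

    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
    centres = separation * Q  # column c = centre of class c+1

    labels = np.repeat(np.arange(1, m + 1), sizes)
    X = centres[:, labels - 1] + noise_sd * rng.standard_normal((n, labels.size))
    perm = rng.permutation(labels.size)
    return LabeledDataset(X[:, perm], labels[perm], [f"c{c}" for c in range(1, m + 1)])


def minmax_scale(ds: LabeledDataset) -> LabeledDataset:
    """Per-feature min-max scaling into [0, 1]; constant features map to 0."""
    lo = ds.X.min(axis=1, keepdims=True)
    hi = ds.X.max(axis=1, keepdims=True)
    width = np.where(hi > lo, hi - lo, 1.0)
    return LabeledDataset((ds.X - lo) / width, ds.labels, list(ds.class_names))


def save_dataset(ds: LabeledDataset, csv_path, sidecar: dict | None = None) -> None:
    """Write samples as CSV rows (features then class name) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(ds.X.T, columns=[f"f{i+1}" for i in range(ds.n_features)])
    df["label"] = [ds.class_names[c - 1] for c in ds.labels]
    df.to_csv(csv_path, index=False)
    meta = {"class_names": ds.class_names, "n_features": ds.n_features, "n_samples": ds.n_samples}
    if sidecar:
        meta.update(sidecar)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
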