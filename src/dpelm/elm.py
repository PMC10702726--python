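"""Single-hidden-layer network container and the classical ELM trainer.

An extreme learning machine is a single-hidden-layer feedforward network
whose hidden parameters (input weights ``Omega``, biases ``b``) are drawn at
random and never updated; only the output weights ``beta`` are fitted, in
closed form, as the minimum-norm least-squares solution of the linear system
``beta H = T`` with ``H = h(Omega X - b 1^T)``.

With the classes-by-samples target layout used here (``T`` is m x N), the
output-weight solve is ``beta = T H†`` — the transpose of the usual
``H beta = T`` convention.  The pre-activation uses a *minus* bias,
``Omega X - B``, matching the generative form the double pseudo-inverse
derivation inverts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .activations import ActivationPair, apply, get_activation
from .exceptions import InvalidInputError, ShapeError
from .linalg import pinv

__all__ = [
    "SLFNModel",
    "hidden_output",
    "train_elm",
    "predict_scores",
    "predict_labels",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


@dataclass
class SLFNModel:
    """One trained single-hidden-layer network.

    ``Omega`` is L x n, ``b`` length L, ``beta`` m x L.  ``trainer_tag``
    records which trainer produced the model ("elm" or "dpelm").
    """

    Omega: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    activation: ActivationPair
    class_names: list[str] | None = None
    trainer_tag: str = "elm"

    def __post_init__(self) -> None:
        self.Omega = np.asarray(self.Omega, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        L = self.Omega.shape[0]
        if self.b.shape != (L,) or self.beta.shape[1] != L:
            raise ShapeError(
                f"inconsistent hidden width: Omega has {L} rows, b has shape {self.b.shape}, "
                f"beta has {self.beta.shape[1]} columns"
            )
        for name, arr in (("Omega", self.Omega), ("b", self.b), ("beta", self.beta)):
            if not np.isfinite(arr).all():
                raise InvalidInputError(f"{name} contains non-finite entries")

    @property
    def L(self) -> int:
        return self.Omega.shape[0]

    @property
    def n_features(self) -> int:
        return self.Omega.shape[1]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]


def _check_features(model: SLFNModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ShapeError("X must be a 2-D features-by-samples matrix with >= 1 column")
    if X.shape[0] != model.n_features:
        raise ShapeError(f"model expects {model.n_features} features, X has {X.shape[0]}")
    return X


def hidden_output(model: SLFNModel, X) -> np.ndarray:
    """L x N hidden-layer response ``h(Omega X - b 1^T)``."""
    X = _check_features(model, X)
    return apply(model.activation, model.Omega @ X - model.b[:, None])


def predict_scores(model: SLFNModel, X) -> np.ndarray:
    """m x N output-layer scores ``beta h(Omega X - b 1^T)``."""
    return model.beta @ hidden_output(model, X)


def predict_labels(model: SLFNModel, X) -> np.ndarray:
    """Per-column argmax of the scores, 1-based; ties go to the smallest class index."""
    return np.argmax(predict_scores(model, X), axis=0) + 1


def train_elm(
    train,
    L: int,
    activation: str | ActivationPair = "tan",
    interval: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
) -> SLFNModel:
    """Classical ELM: random hidden parameters, pseudo-inverse output weights.

    ``train`` is any object with ``X`` (n x N) and ``T`` (m x N) attributes;
    ``Omega`` and ``b`` are drawn i.i.d. uniform on ``interval`` from the
    seeded generator, then ``beta = T H†``.
    """
    a1, a2 = interval
    if a1 >= a2:
        raise InvalidInputError(f"interval must satisfy a1 < a2, got {interval}")
    if L < 1:
        raise InvalidInputError(f"hidden width L must be >= 1, got {L}")
    X, T = np.asarray(train.X, dtype=float), np.asarray(train.T, dtype=float)
    if X.size == 0 or X.shape[1] < 1:
        raise InvalidInputError("empty training set")
    act = get_activation(activation)
    rng = np.random.default_rng(seed)
    Omega = rng.uniform(a1, a2, size=(L, X.shape[0]))
    b = rng.uniform(a1, a2, size=L)
    H = apply(act, Omega @ X - b[:, None])
    beta = T @ pinv(H)
    return SLFNModel(Omega, b, beta, act, getattr(train, "class_names", None), trainer_tag="elm")


# --- serialization ---------------------------------------------------------
#
# Weights are stored as nested lists of Python floats; json round-trips float
# repr exactly, so a reloaded model predicts bit-identically.


def model_to_dict(model: SLFNModel) -> dict:
    return {
        "format": "dpelm-slfn-v1",
        "trainer_tag": model.trainer_tag,
        "activation": model.activation.name,
        "class_names": model.class_names,
        "Omega": model.Omega.tolist(),
        "b": model.b.tolist(),
        "beta": model.beta.tolist(),
    }


def model_from_dict(doc: dict) -> SLFNModel:
    return SLFNModel(
        np.array(doc["Omega"], dtype=float),
        np.array(doc["b"], dtype=float),
        np.array(doc["beta"], dtype=float),
        get_activation(doc["activation"]),
        doc.get("class_names"),
        trainer_tag=doc.get("trainer_tag", "elm"),
    )


def save_model(model: SLFNModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path) -> SLFNModel:
    return model_from_dict(json.loads(Path(path).read_text()))
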