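"""Double pseudo-inverse weight determination (DPELM).

Instead of drawing the *input* weights at random, DPELM draws the *output*
weights ``beta0`` and biases ``b`` at random, then solves the network
equation ``T = beta0 h(Omega X - B)`` analytically for the input weights:

    Omega = (h^{-1}(beta0† T) + B) X†

and finally refits the output weights with a second pseudo-inverse,

    beta = T (h(Omega X - B))†.

When ``X`` has full column rank (N <= n), ``X† X = I`` makes the first solve
exact, and with a full-row-rank ``beta0`` the training residual is zero for
*any* target matrix — the exact-interpolation property the construction is
built on.  In the common tall-data regime (N >> n) the solve is the
least-squares solution of ``Omega X = h^{-1}(beta0† T) + B`` and the second
pseudo-inverse does the heavy lifting; the refit can never do worse than
keeping ``beta0``.
"""

from __future__ import annotations

import numpy as np

from .activations import DEFAULT_CLIP_EPS, ActivationPair, apply, apply_inverse, get_activation
from .elm import SLFNModel, predict_scores
from .exceptions import DegenerateDrawError, InvalidInputError, NumericError
from .linalg import pinv

__all__ = ["solve_input_weights", "train_dpelm", "training_residual"]

_RANK_RTOL = 1e-10
_MAX_RETRIES = 50


def solve_input_weights(
    T,
    beta0,
    b,
    X,
    activation: str | ActivationPair = "tan",
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> np.ndarray:
    """Analytic input-weight solve ``Omega = (h^{-1}(beta0† T) + b 1^T) X†``.

    ``T`` is m x N, ``beta0`` m x L, ``b`` length L, ``X`` n x N; returns the
    L x n input-weight matrix.  For bounded-range activations, ``beta0† T``
    is clipped into the open range before inversion (see
    :func:`dpelm.activations.apply_inverse`).
    """
    act = get_activation(activation)
    T = np.asarray(T, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    b = np.asarray(b, dtype=float)
    X = np.asarray(X, dtype=float)
    if T.shape[0] != beta0.shape[0]:
        raise InvalidInputError(f"T has {T.shape[0]} classes but beta0 has {beta0.shape[0]} rows")
    if T.shape[1] != X.shape[1]:
        raise InvalidInputError("T and X must have the same number of sample columns")
    if b.shape != (beta0.shape[1],):
        raise InvalidInputError(f"b must have length L={beta0.shape[1]}, got shape {b.shape}")

    Z = pinv(beta0) @ T
    try:
        pre = apply_inverse(act, Z, clip_eps)
    except Exception as exc:
        raise NumericError(f"inverse-activation stage failed: {exc}") from exc
    Omega = (pre + b[:, None]) @ pinv(X)
    if not np.isfinite(Omega).all():
        raise NumericError("pseudo-inverse stage produced non-finite input weights")
    return Omega


def _draw_full_row_rank(rng: np.random.Generator, m: int, L: int, a1: float, a2: float) -> np.ndarray:
    """Uniform m x L draw, re-drawn (bounded retries) until rank m when m <= L."""
    for _ in range(_MAX_RETRIES):
        beta0 = rng.uniform(a1, a2, size=(m, L))
        if m > L:
            return beta0  # full row rank unattainable; proceed with the draw
        s = np.linalg.svd(beta0, compute_uv=False)
        if s[-1] > _RANK_RTOL * s[0]:
            return beta0
    raise DegenerateDrawError(f"no rank-{m} output-weight draw in {_MAX_RETRIES} retries")


def train_dpelm(
    train,
    L: int,
    activation: str | ActivationPair = "tan",
    interval: tuple[float, float] = (-1.0, 1.0),
    seed: int = 0,
    clip_eps: float = DEFAULT_CLIP_EPS,
    return_initial: bool = False,
):
    """Train a DPELM network.

    Steps: (i) draw ``beta0`` (m x L, re-drawn until full row rank when
    m <= L) and biases ``b`` uniform on ``interval``; (ii) solve the input
    weights analytically; (iii) refit the output weights as
    ``beta = T (h(Omega X - b 1^T))†``.  Deterministic given ``seed``.

    With ``return_initial=True``, also returns the random draw ``beta0`` so
    callers can compare the refit residual against the pre-refit one.
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

    beta0 = _draw_full_row_rank(rng, T.shape[0], L, a1, a2)
    b = rng.uniform(a1, a2, size=L)
    Omega = solve_input_weights(T, beta0, b, X, act, clip_eps)
    H = apply(act, Omega @ X - b[:, None])
    beta = T @ pinv(H)
    model = SLFNModel(Omega, b, beta, act, getattr(train, "class_names", None), trainer_tag="dpelm")
    if return_initial:
        return model, beta0
    return model


def training_residual(model: SLFNModel, train) -> float:
    """Frobenius norm of the training error ``|| beta h(Omega X - B) - T ||_F``."""
    scores = predict_scores(model, np.asarray(train.X, dtype=float))
    return float(np.linalg.norm(scores - np.asarray(train.T, dtype=float)))
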