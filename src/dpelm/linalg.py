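"""Moore-Penrose pseudo-inverse, the single linear-algebra kernel of the package.

Every trainer here — the classical extreme learning machine and the double
pseudo-inverse variant — reduces to one or more applications of the dagger
operator :math:`A^\\dagger`.  It is computed by singular value decomposition
with a cutoff *relative* to the largest singular value, so behaviour is
invariant to overall data scaling and rank-deficient matrices (which arise
whenever the hidden layer is wider than the sample count) are handled
gracefully.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError, ShapeError

__all__ = ["pinv", "mp_condition_errors", "default_rtol"]


def default_rtol(shape: tuple[int, int]) -> float:
    """Relative singular-value cutoff used when none is given: 1e-12 x max(rows, cols)."""
    return 1e-12 * max(shape)


def _as_matrix(A, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ShapeError(f"{name} must be a 2-D matrix with at least one row and column, got shape {A.shape}")
    if not np.isfinite(A).all():
        raise InvalidInputError(f"{name} contains non-finite entries (NaN or Inf)")
    return A


def pinv(A, rtol: float | None = None) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of ``A``.

    Parameters
    ----------
    A
        Real matrix, shape ``(rows, cols)``, all entries finite.
    rtol
        Relative cutoff in ``(0, 1)``: singular values below
        ``rtol * sigma_max`` are treated as zero.  Defaults to
        ``1e-12 * max(rows, cols)``.

    Returns
    -------
    numpy.ndarray
        ``A``:sup:`†` of shape ``(cols, rows)`` satisfying the four
        Moore-Penrose conditions to numerical tolerance.
    """
    A = _as_matrix(A)
    if rtol is None:
        rtol = default_rtol(A.shape)
    if not (0.0 < rtol < 1.0):
        raise InvalidInputError(f"rtol must lie in (0, 1), got {rtol}")
    return np.linalg.pinv(A, rcond=rtol)


def mp_condition_errors(A, A_pinv) -> dict[str, float]:
    """Relative Frobenius-norm violations of the four Moore-Penrose conditions.

    Returns a mapping with keys ``AXA`` (A A† A = A), ``XAX`` (A† A A† = A†),
    ``AX_sym`` ((A A†)ᵀ = A A†) and ``XA_sym`` ((A† A)ᵀ = A† A).  Each value is
    normalised by the Frobenius norm of the quantity on the right-hand side
    (or left unnormalised when that norm is zero), so a perfect pseudo-inverse
    scores ~1e-15 on all four.
    """
    A = _as_matrix(A)
    X = _as_matrix(A_pinv, "A_pinv")

    def rel(err: np.ndarray, ref: np.ndarray) -> float:
        scale = np.linalg.norm(ref)
        d = np.linalg.norm(err)
        return float(d / scale) if scale > 0 else float(d)

    AX = A @ X
    XA = X @ A
    return {
        "AXA": rel(AX @ A - A, A),
        "XAX": rel(XA @ X - X, X) if np.linalg.norm(X) > 0 else 0.0,
        "AX_sym": rel(AX.T - AX, AX) if np.linalg.norm(AX) > 0 else 0.0,
        "XA_sym": rel(XA.T - XA, XA) if np.linalg.norm(XA) > 0 else 0.0,
    }
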