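"""Registry of invertible elementwise activations.

The double pseudo-inverse trainer solves for input weights by *inverting* the
activation: given targets T and a random output weight draw beta0, it needs
h^{-1}(beta0† T).  Every registered activation therefore ships with its
inverse and a description of its range, so values outside the image of h can
be projected back inside before inversion.

The default is the circular tangent with the arctangent inverse — an unusual
neural activation, but the one whose inverse is defined on all of R, so the
analytic solve never needs clipping.  Bounded-range pairs (sigmoid, tanh,
sine) clip into the open range first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, logit

from .exceptions import DomainError, InvalidInputError, UnsupportedActivationError

__all__ = ["ActivationPair", "apply", "apply_inverse", "get_activation", "available_activations"]

DEFAULT_CLIP_EPS = 1e-6
_POLE_TOL = 1e-8


@dataclass(frozen=True)
class ActivationPair:
    """An elementwise map, its inverse, and its range.

    ``range_low``/``range_high`` bound the open image of ``forward``;
    ``-inf``/``inf`` mark an unbounded side.  ``pole_distance``, when set,
    returns the elementwise distance from each input to the nearest pole of
    the forward map (only the circular tangent has poles).
    """

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    range_low: float
    range_high: float
    strictly_monotonic: bool = True
    pole_distance: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def bounded(self) -> bool:
        return np.isfinite(self.range_low) and np.isfinite(self.range_high)


def _tan_pole_distance(Z: np.ndarray) -> np.ndarray:
    # poles of tan at odd multiples of pi/2
    k = np.round((Z - np.pi / 2) / np.pi)
    return np.abs(Z - (np.pi / 2 + k * np.pi))


_REGISTRY: dict[str, ActivationPair] = {}


def _register(pair: ActivationPair, *aliases: str) -> None:
    _REGISTRY[pair.name] = pair
    for a in aliases:
        _REGISTRY[a] = pair


_register(
    ActivationPair("tan", np.tan, np.arctan, -np.inf, np.inf, pole_distance=_tan_pole_distance),
    "tangent",
)
_register(ActivationPair("sigmoid", expit, logit, 0.0, 1.0), "logistic")
_register(ActivationPair("tanh", np.tanh, np.arctanh, -1.0, 1.0))
_register(ActivationPair("sin", np.sin, np.arcsin, -1.0, 1.0), "sine")


def available_activations() -> list[str]:
    return sorted({p.name for p in _REGISTRY.values()})


def get_activation(name: str | ActivationPair) -> ActivationPair:
    """Look an activation up by name (``"tan"``, ``"sigmoid"``, ``"tanh"``, ``"sin"``)."""
    if isinstance(name, ActivationPair):
        return name
    try:
        return _REGISTRY[name.lower()]
    except (KeyError, AttributeError):
        raise UnsupportedActivationError(
            f"unknown activation {name!r}; available: {available_activations()}"
        ) from None


def apply(act: str | ActivationPair, Z) -> np.ndarray:
    """Elementwise forward image ``h(Z)``, same shape as ``Z``.

    Raises :class:`DomainError` naming the offending entry if any value lies
    within 1e-8 of a pole of the forward map.
    """
    act = get_activation(act)
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise InvalidInputError("activation input contains non-finite entries")
    if act.pole_distance is not None:
        d = act.pole_distance(Z)
        if np.any(d < _POLE_TOL):
            idx = np.unravel_index(int(np.argmin(d)), Z.shape)
            raise DomainError(
                f"entry {Z[idx]!r} at index {tuple(int(i) for i in idx)} lies within "
                f"{_POLE_TOL} of a pole of {act.name!r}"
            )
    out = act.forward(Z)
    if not np.isfinite(out).all():
        raise DomainError(f"forward map {act.name!r} produced non-finite output")
    return out


def apply_inverse(act: str | ActivationPair, Z, clip_eps: float = DEFAULT_CLIP_EPS) -> np.ndarray:
    """Elementwise ``h^{-1}(Z)`` after projecting ``Z`` into the open range of ``h``.

    For a bounded range ``(lo, hi)`` with ``width = hi - lo``, entries are
    clipped into ``[lo + clip_eps*width, hi - clip_eps*width]`` before
    inversion; unbounded ranges (tangent) pass through unchanged.
    """
    act = get_activation(act)
    if act.inverse is None:
        raise UnsupportedActivationError(f"activation {act.name!r} has no registered inverse")
    if not (0.0 < clip_eps < 0.1):
        raise InvalidInputError(f"clip_eps must lie in (0, 0.1), got {clip_eps}")
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise InvalidInputError("inverse-activation input contains non-finite entries")
    if act.bounded:
        width = act.range_high - act.range_low
        Z = np.clip(Z, act.range_low + clip_eps * width, act.range_high - clip_eps * width)
    out = act.inverse(Z)
    if not np.isfinite(out).all():
        raise DomainError(f"inverse map of {act.name!r} produced non-finite output")
    return out
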