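"""Majority-voting ensembles of independently trained networks.

Random initialization makes a single ELM or DPELM a high-variance classifier;
the voting ensemble trains K members with independent seeds and classifies a
sample by the class that receives the most hard votes (one vote per member).
Vote ties break to the smallest class index, the same deterministic rule the
single-model argmax uses, so a K=1 ensemble reduces exactly to its member.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dpelm import train_dpelm
from .elm import SLFNModel, model_from_dict, model_to_dict, predict_labels, train_elm
from .exceptions import ConfigurationError, InvalidInputError, ShapeError

__all__ = [
    "VotingEnsemble",
    "VoteTally",
    "train_ensemble",
    "tally_votes",
    "ensemble_predict",
    "save_ensemble",
    "load_ensemble",
]

TRAINERS = {"elm": train_elm, "dpelm": train_dpelm}


@dataclass
class VotingEnsemble:
    """K independently trained networks sharing one class catalogue.

    Member ``i`` (1-based) was trained with seed ``master_seed + i``.
    """

    members: list[SLFNModel]
    base_trainer: str
    master_seed: int

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def class_names(self) -> list[str] | None:
        return self.members[0].class_names

    @property
    def n_classes(self) -> int:
        return self.members[0].n_classes


@dataclass
class VoteTally:
    """m x N matrix of per-class vote counts; every column sums to K."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        if np.any(self.S < 0):
            raise InvalidInputError("vote counts must be nonnegative")


def train_ensemble(
    train,
    K: int,
    base_trainer: str = "dpelm",
    L: int = 10,
    activation: str = "tan",
    interval: tuple[float, float] = (-1.0, 1.0),
    master_seed: int = 0,
    **trainer_kwargs,
) -> VotingEnsemble:
    """Train K members with derived seeds ``master_seed + 1 .. master_seed + K``."""
    if K < 1:
        raise InvalidInputError(f"ensemble size K must be >= 1, got {K}")
    if base_trainer not in TRAINERS:
        raise ConfigurationError(f"unknown base trainer {base_trainer!r}; expected one of {sorted(TRAINERS)}")
    fit = TRAINERS[base_trainer]
    members = [
        fit(train, L, activation=activation, interval=interval, seed=master_seed + i, **trainer_kwargs)
        for i in range(1, K + 1)
    ]
    return VotingEnsemble(members, base_trainer, master_seed)


def tally_votes(per_member_labels, m: int) -> VoteTally:
    """Count votes: ``S[c-1, j]`` = number of members predicting class c for sample j."""
    labels = np.asarray(per_member_labels, dtype=int)
    if labels.ndim != 2:
        raise ShapeError("per_member_labels must be K vectors of equal length")
    if labels.size and (labels.min() < 1 or labels.max() > m):
        bad = labels[(labels < 1) | (labels > m)][0]
        raise InvalidInputError(f"vote label {bad} outside class catalogue 1..{m}")
    K, N = labels.shape
    S = np.zeros((m, N), dtype=int)
    for c in range(1, m + 1):
        S[c - 1] = (labels == c).sum(axis=0)
    assert (S.sum(axis=0) == K).all()
    return VoteTally(S)


def ensemble_predict(ens: VotingEnsemble, X) -> np.ndarray:
    """Majority-vote label per column; ties break to the smallest class index."""
    votes = np.stack([predict_labels(mem, X) for mem in ens.members])
    tally = tally_votes(votes, ens.n_classes)
    if not (tally.S.sum(axis=0) == ens.K).all():  # conservation check on every call
        raise InvalidInputError("vote tally columns do not sum to K")
    return np.argmax(tally.S, axis=0) + 1


def save_ensemble(ens: VotingEnsemble, path) -> None:
    doc = {
        "format": "dpelm-ensemble-v1",
        "K": ens.K,
        "base_trainer": ens.base_trainer,
        "master_seed": ens.master_seed,
        "members": [model_to_dict(m) for m in ens.members],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path) -> VotingEnsemble:
    doc = json.loads(Path(path).read_text())
    return VotingEnsemble(
        [model_from_dict(d) for d in doc["members"]],
        doc["base_trainer"],
        doc["master_seed"],
    )
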