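"""Frequency-weighted cohort prediction of the next phoneme, and its error.

Given a prefix, the cohort is the set of lexicon entries that begin with the
prefix and continue past it.  The predicted distribution over the next
phoneme weights each continuation phoneme by the summed frequency of the
cohort entries supporting it.  Prediction error against a presented phoneme
is the summed absolute difference between the predicted distribution and the
one-hot input vector, which for a normalized prediction equals
``2 * (1 - probs[observed])`` and is therefore bounded in ``[0, 2]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lexicon import LexicalEntry, Lexicon

__all__ = [
    "PredictionConfig",
    "PhonemePrediction",
    "ErrorTrajectory",
    "cohort",
    "predict_next",
    "prediction_error",
    "error_trajectory",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Model options.

    ``empty_cohort_fallback``: distribution used when no entry continues the
    prefix — ``"uniform"`` (1/|inventory| everywhere; error stays in [0, 2])
    or ``"zero"`` (all-zero; error is exactly 1).  The fallback only arises
    for nonword prefixes past the divergence point and is flagged on the
    prediction.

    ``freq_transform``: ``"raw"`` uses frequencies as-is, ``"log1p"``
    weights by ``log(1 + f)``.
    """

    empty_cohort_fallback: str = "uniform"
    freq_transform: str = "raw"

    def __post_init__(self) -> None:
        if self.empty_cohort_fallback not in ("uniform", "zero"):
            raise ValueError(
                f"unknown fallback: {self.empty_cohort_fallback!r}"
            )
        if self.freq_transform not in ("raw", "log1p"):
            raise ValueError(f"unknown freq_transform: {self.freq_transform!r}")

    def weight(self, frequency: float) -> float:
        if self.freq_transform == "log1p":
            return math.log1p(frequency)
        return frequency


@dataclass(frozen=True)
class PhonemePrediction:
    """By-position distribution over the inventory given a prefix.

    ``position`` is the 1-based position being predicted.  ``cohort_mass``
    is the summed (transformed) frequency of the supporting cohort.
    """

    position: int
    probs: np.ndarray
    cohort_mass: float
    empty_cohort: bool
    inventory: "object" = field(repr=False)

    def prob(self, symbol: str) -> float:
        return float(self.probs[self.inventory.index(symbol)])


@dataclass(frozen=True)
class ErrorTrajectory:
    """Per-position prediction errors (and the predictions used) for one item."""

    item: tuple[str, ...]
    per_position_error: np.ndarray
    per_position_prediction: tuple[PhonemePrediction, ...]


def cohort(lex: Lexicon, prefix: Sequence[str]) -> list[LexicalEntry]:
    """Entries that begin with ``prefix`` and actually continue past it.

    Word-final entries (form identical to the prefix) are excluded: they
    have no next phoneme.  The empty prefix returns every entry.
    """
    p = tuple(prefix)
    n = len(p)
    return [e for e in lex if len(e.form) > n and e.form[:n] == p]


def predict_next(
    lex: Lexicon,
    prefix: Sequence[str],
    config: PredictionConfig = PredictionConfig(),
) -> PhonemePrediction:
    """Frequency-weighted distribution of the next phoneme given ``prefix``."""
    inv = lex.inventory
    n = len(prefix)
    probs = np.zeros(len(inv))
    mass = 0.0
    for e in cohort(lex, prefix):
        w = config.weight(e.frequency)
        probs[inv.index(e.form[n])] += w
        mass += w
    if mass > 0:
        probs /= mass
        empty = False
    else:
        empty = True
        if config.empty_cohort_fallback == "uniform":
            probs[:] = 1.0 / len(inv)
        else:
            probs[:] = 0.0
    return PhonemePrediction(
        position=n + 1,
        probs=probs,
        cohort_mass=mass,
        empty_cohort=empty,
        inventory=inv,
    )


def prediction_error(pred: PhonemePrediction, observed: str) -> float:
    """Summed absolute difference between prediction and one-hot input."""
    onehot = np.zeros_like(pred.probs)
    onehot[pred.inventory.index(observed)] = 1.0
    return float(np.abs(pred.probs - onehot).sum())


def error_trajectory(
    lex: Lexicon,
    item: Sequence[str],
    config: PredictionConfig = PredictionConfig(),
) -> ErrorTrajectory:
    """By-position predictions and errors over a whole item.

    Position 1 is predicted from the empty prefix (the whole-lexicon
    first-phoneme distribution).
    """
    form = tuple(item)
    if len(form) == 0:
        raise ValueError("item must be non-empty")
    preds = []
    errors = []
    for i, observed in enumerate(form):
        pred = predict_next(lex, form[:i], config)
        preds.append(pred)
        errors.append(prediction_error(pred, observed))
    return ErrorTrajectory(form, np.asarray(errors), tuple(preds))
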