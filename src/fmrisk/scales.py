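"""TG-100-style ten-point Occurrence and Detectability scales.

Each scale maps integer scores 1-10 to anchor probabilities: for Occurrence,
the probability that a given treatment plan exhibits the failure mode; for
Detectability, the probability that an occurred failure mode escapes *all*
quality-control layers undetected (higher score = harder to detect).
Continuous scores are obtained by linear interpolation in probability between
adjacent integer anchors, so empirical rates can be placed on the scale
without rounding and scale values with one decimal (as published consensus
tables use) can be converted back to probabilities.

The top scale category is open-ended in the source tables (">5%" occurrence,
">20%" undetected).  A finite representative probability is stored for score
10 so the inverse lookup is total; any probability at or above it maps to
exactly 10.0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScaleAnchor",
    "ScaleTable",
    "ScaleConfigError",
    "default_occurrence_table",
    "default_detectability_table",
    "prob_to_score",
    "score_to_prob",
    "round_half_away",
]


class ScaleConfigError(ValueError):
    """Raised when a scale table violates its structural invariants."""


@dataclass(frozen=True)
class ScaleAnchor:
    """One integer score and the probability anchored to it."""

    score: int
    probability: float

    def __post_init__(self) -> None:
        if not (1 <= int(self.score) <= 10) or int(self.score) != self.score:
            raise ScaleConfigError(f"anchor score must be an integer in 1..10, got {self.score!r}")
        if not (0.0 < self.probability <= 1.0):
            raise ScaleConfigError(
                f"anchor probability must be in (0, 1], got {self.probability!r}"
            )


# Reconstructed defaults: probability a plan has the FM (occurrence) and
# probability the FM escapes all checks (detectability).  Score-10 entries are
# representative values for the open-ended top category.
_DEFAULT_OCCURRENCE = (
    0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.10,
)
_DEFAULT_DETECTABILITY = (
    0.0001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.40,
)

_KINDS = ("occurrence", "detectability")


@dataclass(frozen=True)
class ScaleTable:
    """An ordered set of ten anchors for one scale kind.

    Parameters
    ----------
    kind:
        ``"occurrence"`` or ``"detectability"``.
    anchors:
        Exactly one :class:`ScaleAnchor` per score 1..10, with strictly
        increasing probabilities.
    """

    kind: str
    anchors: tuple[ScaleAnchor, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ScaleConfigError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        anchors = tuple(sorted(self.anchors, key=lambda a: a.score))
        object.__setattr__(self, "anchors", anchors)
        scores = [a.score for a in anchors]
        if scores != list(range(1, 11)):
            raise ScaleConfigError(f"scores must be exactly 1..10 each once, got {scores}")
        probs = [a.probability for a in anchors]
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ScaleConfigError("anchor probabilities must strictly increase with score")

    # -- convenience -------------------------------------------------------

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([a.probability for a in self.anchors], dtype=float)

    @classmethod
    def from_probabilities(cls, kind: str, probs: Sequence[float]) -> "ScaleTable":
        return cls(kind, tuple(ScaleAnchor(s, p) for s, p in zip(range(1, 11), probs)))

    # -- JSON interchange --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "anchors": [
                {"score": a.score, "probability": a.probability} for a in self.anchors
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScaleTable":
        try:
            anchors = tuple(
                ScaleAnchor(int(a["score"]), float(a["probability"]))
                for a in data["anchors"]
            )
            kind = data["kind"]
        except (KeyError, TypeError) as exc:
            raise ScaleConfigError(f"malformed scale table: {exc}") from exc
        return cls(kind, anchors)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScaleTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def checksum(self) -> str:
        """Stable digest of the anchor values, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def default_occurrence_table() -> ScaleTable:
    return ScaleTable.from_probabilities("occurrence", _DEFAULT_OCCURRENCE)


def default_detectability_table() -> ScaleTable:
    return ScaleTable.from_probabilities("detectability", _DEFAULT_DETECTABILITY)


def prob_to_score(p: float, table: ScaleTable) -> float:
    """Continuous scale score for a probability.

    Linear interpolation between the bracketing anchors; probabilities below
    the score-1 anchor clamp to 1.0 and probabilities at or above the score-10
    representative anchor clamp to 10.0 (the top category is open-ended).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p!r}")
    probs = table.probabilities
    if p <= probs[0]:
        return 1.0
    if p >= probs[-1]:
        return 10.0
    return float(np.interp(p, probs, np.arange(1.0, 11.0)))


def score_to_prob(s: float, table: ScaleTable) -> float:
    """Probability for a (possibly fractional) scale score in [1, 10]."""
    if not (1.0 <= s <= 10.0):
        raise ValueError(f"score must be in [1, 10], got {s!r}")
    probs = table.probabilities
    return float(np.interp(s, np.arange(1.0, 11.0), probs))


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (10.5 -> 11)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))
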