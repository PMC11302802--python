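"""Closed-form occurrence/detectability estimation from two-layer QC counts.

A failure mode (FM) checked for by two sequential, equally effective QC
layers yields observable counts N1 (caught at the first check) and N2 (caught
at the second).  Writing CE for the per-check catch probability and N0 for the
true number of occurrences,

    N1 = N0 * CE            (first check sees everything)
    N2 = (N0 - N1) * CE     (second check sees what the first missed)

which solve to CE = 1 - N2/N1 and N0 = N1^2 / (N1 - N2) — the two-sample
capture-recapture logic applied to sequential inspections.  From these,
N0 / n_plans is an occurrence fraction to place on the Occurrence scale, and
(1 - CE)^n is the probability an occurred FM slips past all n layers, placed
on the Detectability scale.  The risk priority number is RPN = O x S x D with
Severity supplied externally.

The estimate breaks down when N2 >= N1 (implied CE <= 0): such counts are
reported per-FM as :class:`EstimatorBreakdownError` rather than propagating
NaNs, since with small samples an FM can by chance be recorded more often at
the second check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .scales import (
    ScaleTable,
    default_detectability_table,
    default_occurrence_table,
    prob_to_score,
    round_half_away,
)

__all__ = [
    "CheckCounts",
    "RiskEstimate",
    "InsufficientDataError",
    "EstimatorBreakdownError",
    "check_efficacy",
    "total_occurrences",
    "occurrence_fraction",
    "undetected_probability",
    "estimate_risk",
    "rpn",
]


class InsufficientDataError(ValueError):
    """No first-check catches recorded; nothing can be estimated."""


class EstimatorBreakdownError(ValueError):
    """Counts with N2 >= N1 imply CE <= 0; the closed form breaks down."""

    def __init__(self, fm_id, n1: int, n2: int):
        self.fm_id = fm_id
        super().__init__(
            f"FM {fm_id!r}: N2={n2} >= N1={n1}; check efficacy would be <= 0 "
            "(sample too small or model violated)"
        )


@dataclass(frozen=True)
class CheckCounts:
    """Observed catch counts for one failure mode.

    Parameters
    ----------
    fm_id:
        Failure-mode identifier.
    n1, n2:
        Catches at the first and second QC layer.
    n_plans:
        Number of plans the log covers (supplied externally, never inferred).
    n_layers:
        Number of QC layers in place for this FM; the detectability score is
        computed for this many layers.  Default 2 (initial + first weekly
        physics check).
    """

    fm_id: str
    n1: int
    n2: int
    n_plans: int
    n_layers: int = 2

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError(f"FM {self.fm_id!r}: counts must be non-negative")
        if self.n_plans < 1:
            raise ValueError(f"FM {self.fm_id!r}: n_plans must be >= 1")
        if self.n_layers < 1:
            raise ValueError(f"FM {self.fm_id!r}: n_layers must be >= 1")

    @property
    def estimable(self) -> bool:
        return self.n1 > 0 and self.n1 > self.n2


@dataclass(frozen=True)
class RiskEstimate:
    """All estimator outputs for one failure mode."""

    fm_id: str
    ce: float
    n0_continuous: float
    n0_rounded: int
    undetected_count: float
    occurrence_fraction: float
    undetected_prob: float
    o_continuous: float
    d_continuous: float
    o_score: int
    d_score: int
    severity: Optional[float] = None
    rpn: Optional[float] = None
    rpn_continuous: Optional[float] = None


def _require_estimable(counts: CheckCounts) -> None:
    if counts.n1 == 0:
        raise InsufficientDataError(
            f"FM {counts.fm_id!r}: no first-check catches recorded (N1 = 0)"
        )
    if counts.n2 >= counts.n1:
        raise EstimatorBreakdownError(counts.fm_id, counts.n1, counts.n2)


def check_efficacy(counts: CheckCounts) -> float:
    """Per-check catch probability CE = 1 - N2/N1, in (0, 1]."""
    _require_estimable(counts)
    return 1.0 - counts.n2 / counts.n1


def total_occurrences(counts: CheckCounts) -> tuple[float, int, float]:
    """Estimated true occurrences N0 = N1^2 / (N1 - N2).

    Returns ``(n0_continuous, n0_rounded, undetected_count)`` where the
    undetected count N0 - N1 - N2 = N2^2/(N1 - N2) is the estimated number of
    occurrences that slipped past both recorded checks.
    """
    _require_estimable(counts)
    n1, n2 = counts.n1, counts.n2
    n0 = n1 * n1 / (n1 - n2)
    undetected = n2 * n2 / (n1 - n2)
    return n0, round_half_away(n0), undetected


def occurrence_fraction(counts: CheckCounts) -> float:
    """Estimated per-plan occurrence probability, continuous N0 / n_plans."""
    n0, _, _ = total_occurrences(counts)
    if n0 > counts.n_plans:
        warnings.warn(
            f"FM {counts.fm_id!r}: estimated N0 ({n0:.1f}) exceeds the number of "
            f"plans ({counts.n_plans}); occurrence fraction > 1",
            stacklevel=2,
        )
    return n0 / counts.n_plans


def undetected_probability(ce: float, n_layers: int) -> float:
    """Probability an occurred FM escapes all ``n_layers`` checks: (1-CE)^n."""
    if not (0.0 <= ce <= 1.0):
        raise ValueError(f"check efficacy must be in [0, 1], got {ce!r}")
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers!r}")
    return (1.0 - ce) ** n_layers


def rpn(o: float, s: float, d: float) -> float:
    """Risk priority number O x S x D (any mix of integer or continuous scores)."""
    for name, v in (("O", o), ("S", s), ("D", d)):
        if not (1.0 <= v <= 10.0):
            raise ValueError(f"{name} must be in [1, 10], got {v!r}")
    return o * s * d


def estimate_risk(
    counts: CheckCounts,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
    severity: Optional[float] = None,
) -> RiskEstimate:
    """Full pipeline: counts -> CE, N0, occurrence fraction, O, D (and RPN).

    All downstream quantities use the continuous (unrounded) N0.  RPN is
    computed with integer scores by default; a continuous-score RPN is also
    reported since published consensus tables carry one-decimal scores.
    """
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    ce = check_efficacy(counts)
    n0, n0_rounded, undetected = total_occurrences(counts)
    occ_frac = occurrence_fraction(counts)
    undet_prob = undetected_probability(ce, counts.n_layers)
    o_cont = prob_to_score(min(occ_frac, 1.0), o_table)
    d_cont = prob_to_score(undet_prob, d_table)
    o_score = round_half_away(o_cont)
    d_score = round_half_away(d_cont)
    rpn_int = rpn_cont = None
    if severity is not None:
        rpn_int = rpn(o_score, severity, d_score)
        rpn_cont = rpn(o_cont, severity, d_cont)
    return RiskEstimate(
        fm_id=counts.fm_id,
        ce=ce,
        n0_continuous=n0,
        n0_rounded=n0_rounded,
        undetected_count=undetected,
        occurrence_fraction=occ_frac,
        undetected_prob=undet_prob,
        o_continuous=o_cont,
        d_continuous=d_cont,
        o_score=o_score,
        d_score=d_score,
        severity=severity,
        rpn=rpn_int,
        rpn_continuous=rpn_cont,
    )
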