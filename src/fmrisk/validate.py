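"""Consistency checks between observed QC counts and consensus (O, D) scores.

Published consensus tables give one-decimal O and D scores per failure mode.
Given a clinic's observed counts, these routines quantify whether the
consensus values could plausibly have produced the data:

* :func:`expected_counts` — the (N1, N2) expectation values implied by
  consensus scores, for direct comparison with the observed counts.
* :func:`tail_probability` — a seeded Monte-Carlo plausibility probability for
  the observed counts under the consensus-implied generative model.
* :func:`occurrence_ratio` — the fold difference between the clinic's
  estimated occurrence count and the count implied by consensus O.
* :func:`bootstrap_intervals` — parametric-bootstrap percentile intervals for
  the clinic's own estimates, to show how much data-driven precision is
  available.

Consensus D is read as the probability of escaping *all* existing layers, so
the implied per-check efficacy is recovered via the n-th root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .estimator import (
    CheckCounts,
    EstimatorBreakdownError,
    InsufficientDataError,
    estimate_risk,
)
from .scales import (
    ScaleTable,
    default_detectability_table,
    default_occurrence_table,
    prob_to_score,
    score_to_prob,
)

__all__ = [
    "ConsensusEntry",
    "ValidationReport",
    "BootstrapResult",
    "expected_counts",
    "tail_probability",
    "occurrence_ratio",
    "implied_o",
    "bootstrap_intervals",
    "validate_consensus",
]


@dataclass(frozen=True)
class ConsensusEntry:
    """Consensus (O, S, D) scores for one failure mode; S optional."""

    fm_id: str
    o: float
    d: float
    s: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in (("O", self.o), ("D", self.d)):
            if not (1.0 <= v <= 10.0):
                raise ValueError(f"FM {self.fm_id!r}: {name} must be in [1, 10], got {v!r}")
        if self.s is not None and not (1.0 <= self.s <= 10.0):
            raise ValueError(f"FM {self.fm_id!r}: S must be in [1, 10], got {self.s!r}")


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile intervals from a parametric bootstrap of the estimator."""

    level: float
    n_boot: int
    n_breakdown: int
    intervals: dict  # param -> (lower, upper)
    indeterminate: bool


@dataclass(frozen=True)
class ValidationReport:
    """Full consensus-consistency diagnostics for one failure mode."""

    fm_id: str
    expected_n1: float
    expected_n2: float
    observed_n1: int
    observed_n2: int
    tail_prob: float
    occurrence_ratio: float
    implied_o: Optional[float]
    bootstrap: Optional[BootstrapResult]
    verdict: str  # consistent | inconsistent | indeterminate


def _implied_model(
    entry: ConsensusEntry,
    n_layers: int,
    o_table: ScaleTable,
    d_table: ScaleTable,
) -> tuple[float, float]:
    """(p_occ, ce) implied by consensus scores for an n-layer clinic."""
    p_occ = score_to_prob(entry.o, o_table)
    p_undet = score_to_prob(entry.d, d_table)
    ce = 1.0 - p_undet ** (1.0 / n_layers)
    return p_occ, ce


def expected_counts(
    entry: ConsensusEntry,
    n_plans: int,
    n_layers: int = 2,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
) -> tuple[float, float]:
    """Expectation values of (N1, N2) if the consensus scores were true.

    N0 = p_occ * n_plans; E[N1] = N0 * CE; E[N2] = (N0 - E[N1]) * CE, with CE
    recovered from consensus D as 1 - p_undetected^(1/n_layers).
    """
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    p_occ, ce = _implied_model(entry, n_layers, o_table, d_table)
    n0 = p_occ * n_plans
    e_n1 = n0 * ce
    e_n2 = (n0 - e_n1) * ce
    return e_n1, e_n2


def tail_probability(
    entry: ConsensusEntry,
    counts: CheckCounts,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
    n_reps: int = 100_000,
    seed: int = 0,
    statistic: str = "total",
) -> float:
    """Monte-Carlo probability of counts at least as extreme as observed.

    Under the consensus-implied model each plan independently lands in one of
    three cells — caught at layer 1 (p_occ*CE), caught at layer 2
    (p_occ*(1-CE)*CE), or unobserved — so (N1, N2) is multinomial; sampling
    that multinomial is the per-plan Bernoulli model, marginalized exactly.

    ``statistic="total"`` (default) orders outcomes by the distance of the
    total catches N1+N2 from its expectation (two-sided).
    ``statistic="likelihood"`` orders jointly by multinomial likelihood:
    outcomes with pmf <= pmf(observed) count as at least as extreme.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000")
    if statistic not in ("total", "likelihood"):
        raise ValueError(f"unknown statistic {statistic!r}")
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    p_occ, ce = _implied_model(entry, counts.n_layers, o_table, d_table)
    p1 = p_occ * ce
    p2 = p_occ * (1.0 - ce) * ce
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(counts.n_plans, [p1, p2, 1.0 - p1 - p2], size=n_reps)
    if statistic == "total":
        total = draws[:, 0] + draws[:, 1]
        mu = counts.n_plans * (p1 + p2)
        obs_dist = abs(counts.n1 + counts.n2 - mu)
        extreme = np.abs(total - mu) >= obs_dist - 1e-12
    else:
        from scipy.stats import multinomial as sp_multinomial

        dist = sp_multinomial(counts.n_plans, [p1, p2, 1.0 - p1 - p2])
        obs = [counts.n1, counts.n2, counts.n_plans - counts.n1 - counts.n2]
        obs_pmf = dist.pmf(obs)
        extreme = dist.pmf(draws) <= obs_pmf * (1 + 1e-9)
    return float(np.mean(extreme))


def occurrence_ratio(
    entry: ConsensusEntry,
    counts: CheckCounts,
    o_table: Optional[ScaleTable] = None,
) -> float:
    """Clinic's estimated N0 divided by the count implied by consensus O."""
    o_table = o_table or default_occurrence_table()
    est = estimate_risk(counts, o_table=o_table)
    implied_n0 = score_to_prob(entry.o, o_table) * counts.n_plans
    return est.n0_continuous / implied_n0


def implied_o(
    entry: ConsensusEntry,
    counts: CheckCounts,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
) -> float:
    """Occurrence score required for consensus D to explain the observed total.

    Taking the consensus D at face value fixes the per-check efficacy; the
    occurrence probability is then chosen so that the expected total recorded
    catches N0*(1 - p_undetected) equals the observed N1+N2, and mapped back
    to an O score.
    """
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    p_undet = score_to_prob(entry.d, d_table)
    total = counts.n1 + counts.n2
    p_occ = total / (counts.n_plans * (1.0 - p_undet))
    return prob_to_score(min(p_occ, 1.0), o_table)


def bootstrap_intervals(
    counts: CheckCounts,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
) -> BootstrapResult:
    """Parametric-bootstrap percentile intervals for CE, N0, O and D.

    Occurrences are resampled as Binomial(n_plans, p_occ_hat); each resampled
    occurrence is caught at layer 1 with probability CE_hat, else offered to
    layer 2 with the same CE_hat.  Each replicate is re-estimated with the
    closed form; replicates where the estimate breaks down are counted and
    excluded (more than 50% breakdowns marks the result indeterminate).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    est = estimate_risk(counts, o_table=o_table, d_table=d_table)
    p_occ_hat = min(est.occurrence_fraction, 1.0)
    rng = np.random.default_rng(seed)
    occ = rng.binomial(counts.n_plans, p_occ_hat, size=n_boot)
    n1b = rng.binomial(occ, est.ce)
    n2b = rng.binomial(occ - n1b, est.ce)
    valid = (n1b > n2b) & (n1b > 0)
    n_breakdown = int(n_boot - valid.sum())
    n1v = n1b[valid].astype(float)
    n2v = n2b[valid].astype(float)
    ce_b = 1.0 - n2v / n1v
    n0_b = n1v**2 / (n1v - n2v)
    occ_frac_b = np.minimum(n0_b / counts.n_plans, 1.0)
    undet_b = (1.0 - ce_b) ** counts.n_layers
    o_b = np.array([prob_to_score(p, o_table) for p in occ_frac_b])
    d_b = np.array([prob_to_score(p, d_table) for p in undet_b])
    alpha = (1.0 - level) / 2.0
    indeterminate = n_breakdown > n_boot / 2
    intervals = {}
    for name, arr in (("ce", ce_b), ("n0", n0_b), ("o", o_b), ("d", d_b)):
        if arr.size == 0:
            intervals[name] = (np.nan, np.nan)
        else:
            lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
            intervals[name] = (float(lo), float(hi))
    return BootstrapResult(
        level=level,
        n_boot=n_boot,
        n_breakdown=n_breakdown,
        intervals=intervals,
        indeterminate=indeterminate,
    )


def validate_consensus(
    entry: ConsensusEntry,
    counts: CheckCounts,
    o_table: Optional[ScaleTable] = None,
    d_table: Optional[ScaleTable] = None,
    n_reps: int = 100_000,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    threshold: float = 0.05,
) -> ValidationReport:
    """Assemble the full per-FM validation report.

    Verdict: ``inconsistent`` when the Monte-Carlo tail probability falls
    below ``threshold``, ``consistent`` otherwise, ``indeterminate`` when the
    observed counts are not estimable or the bootstrap mostly breaks down.
    """
    o_table = o_table or default_occurrence_table()
    d_table = d_table or default_detectability_table()
    e_n1, e_n2 = expected_counts(entry, counts.n_plans, counts.n_layers, o_table, d_table)
    tail = tail_probability(entry, counts, o_table, d_table, n_reps=n_reps, seed=seed)
    try:
        ratio = occurrence_ratio(entry, counts, o_table)
        boot = bootstrap_intervals(
            counts, n_boot=n_boot, level=level, seed=seed, o_table=o_table, d_table=d_table
        )
        imp_o = implied_o(entry, counts, o_table, d_table)
    except (EstimatorBreakdownError, InsufficientDataError):
        return ValidationReport(
            fm_id=counts.fm_id,
            expected_n1=e_n1,
            expected_n2=e_n2,
            observed_n1=counts.n1,
            observed_n2=counts.n2,
            tail_prob=tail,
            occurrence_ratio=float("nan"),
            implied_o=None,
            bootstrap=None,
            verdict="indeterminate",
        )
    if boot.indeterminate:
        verdict = "indeterminate"
    elif tail < threshold:
        verdict = "inconsistent"
    else:
        verdict = "consistent"
    return ValidationReport(
        fm_id=counts.fm_id,
        expected_n1=e_n1,
        expected_n2=e_n2,
        observed_n1=counts.n1,
        observed_n2=counts.n2,
        tail_prob=tail,
        occurrence_ratio=ratio,
        implied_o=imp_o,
        bootstrap=boot,
        verdict=verdict,
    )
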