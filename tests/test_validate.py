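"""Consensus-consistency diagnostics: expected counts, tail probabilities,
occurrence ratios and parametric-bootstrap intervals."""

import pytest
from scipy import stats

from fmrisk import (
    CheckCounts,
    ConsensusEntry,
    bootstrap_intervals,
    estimate_risk,
    expected_counts,
    implied_o,
    occurrence_ratio,
    score_to_prob,
    tail_probability,
    validate_consensus,
)


def test_expected_counts_for_consensus_scores(o_table, d_table):
    """Consensus O=5.7, D=4.7 over 2358 plans implies ~8.4 first-check and
    ~1.1 second-check catches (computed, not matched to any rounding)."""
    entry = ConsensusEntry("fm36", o=5.7, d=4.7)
    e_n1, e_n2 = expected_counts(entry, n_plans=2358, n_layers=2)
    assert e_n2 == pytest.approx(1.1, abs=0.05)
    assert e_n1 == pytest.approx(8.41, abs=0.05)


def test_expected_counts_back_compose_through_estimator(o_table, d_table):
    """Feeding the expectation values back through the closed form recovers
    the consensus-implied CE and N0 exactly."""
    entry = ConsensusEntry("fm", o=6.3, d=5.1)
    n_plans = 10_000
    e_n1, e_n2 = expected_counts(entry, n_plans, n_layers=2)
    p_occ = score_to_prob(entry.o, o_table)
    p_undet = score_to_prob(entry.d, d_table)
    ce_implied = 1.0 - p_undet**0.5
    assert e_n1 > e_n2
    ce_hat = 1.0 - e_n2 / e_n1
    n0_hat = e_n1**2 / (e_n1 - e_n2)
    assert ce_hat == pytest.approx(ce_implied, abs=1e-9)
    assert n0_hat == pytest.approx(p_occ * n_plans, abs=1e-9)


def test_tail_probability_flags_too_low_consensus_occurrence(dose_calc_counts):
    """Under consensus O=4.4/D=4.7 the expected total catches are ~3.2, so
    observing 10 is far in the upper tail."""
    entry = ConsensusEntry("fm36", o=4.4, d=4.7)
    tail = tail_probability(entry, dose_calc_counts, n_reps=100_000, seed=11)
    assert tail < 0.05


def test_tail_probability_near_one_at_self_consistent_scores(dose_calc_counts):
    est = estimate_risk(dose_calc_counts)
    entry = ConsensusEntry("fm36", o=est.o_continuous, d=est.d_continuous)
    tail = tail_probability(entry, dose_calc_counts, n_reps=50_000, seed=11)
    assert tail > 0.5


def test_tail_probability_matches_exact_binomial_oracle(o_table, d_table):
    """On a 20-plan toy problem the total-catches statistic has an exactly
    enumerable binomial distribution; Monte Carlo must agree to +/-0.01."""
    entry = ConsensusEntry("toy", o=9.0, d=6.0)
    counts = CheckCounts("toy", n1=4, n2=1, n_plans=20, n_layers=2)
    p_occ = score_to_prob(entry.o, o_table)
    p_undet = score_to_prob(entry.d, d_table)
    p_catch = p_occ * (1 - p_undet)
    mu = 20 * p_catch
    obs_dist = abs(counts.n1 + counts.n2 - mu)
    exact = sum(
        stats.binom.pmf(t, 20, p_catch)
        for t in range(21)
        if abs(t - mu) >= obs_dist - 1e-12
    )
    mc = tail_probability(entry, counts, n_reps=200_000, seed=5)
    assert mc == pytest.approx(exact, abs=0.01)


def test_tail_probability_poisson_oracle(dose_calc_counts, o_table, d_table):
    """At low per-plan rates the catch total is near-Poisson; the upper-tail
    Poisson probability reproduces the Monte-Carlo answer."""
    entry = ConsensusEntry("fm36", o=4.4, d=4.7)
    p_occ = score_to_prob(4.4, o_table)
    p_undet = score_to_prob(4.7, d_table)
    mu = 2358 * p_occ * (1 - p_undet)
    poisson_tail = float(stats.poisson.sf(9, mu))  # P(T >= 10); lower arm is empty
    mc = tail_probability(entry, dose_calc_counts, n_reps=200_000, seed=2)
    assert mc == pytest.approx(poisson_tail, abs=0.003)


def test_tail_probability_seed_reproducible(dose_calc_counts):
    entry = ConsensusEntry("fm36", o=4.4, d=4.7)
    a = tail_probability(entry, dose_calc_counts, n_reps=20_000, seed=7)
    b = tail_probability(entry, dose_calc_counts, n_reps=20_000, seed=7)
    c = tail_probability(entry, dose_calc_counts, n_reps=20_000, seed=8)
    assert a == b
    assert abs(a - c) < 0.01


def test_tail_probability_likelihood_ordering_mode(dose_calc_counts):
    entry = ConsensusEntry("fm36", o=4.4, d=4.7)
    tail = tail_probability(
        entry, dose_calc_counts, n_reps=20_000, seed=3, statistic="likelihood"
    )
    assert 0.0 <= tail < 0.05
    with pytest.raises(ValueError):
        tail_probability(entry, dose_calc_counts, n_reps=20_000, statistic="median")


def test_tail_probability_rejects_tiny_rep_counts(dose_calc_counts):
    with pytest.raises(ValueError):
        tail_probability(ConsensusEntry("x", 5, 5), dose_calc_counts, n_reps=10)


def test_occurrence_ratio(dose_calc_counts, o_table):
    """The clinic recorded ~3x more instances than consensus O=4.4 implies."""
    assert occurrence_ratio(
        ConsensusEntry("fm36", o=4.4, d=4.7), dose_calc_counts
    ) == pytest.approx(3.23, abs=0.01)
    est = estimate_risk(dose_calc_counts)
    assert occurrence_ratio(
        ConsensusEntry("fm36", o=est.o_continuous, d=4.7), dose_calc_counts
    ) == pytest.approx(1.0, abs=1e-9)
    assert occurrence_ratio(
        ConsensusEntry("fm36", o=1.0, d=4.7), dose_calc_counts
    ) == pytest.approx(45.3, abs=0.1)


def test_occurrence_ratio_scale_invariance(o_table):
    """Scaling counts and plans together leaves the fold-ratio unchanged."""
    entry = ConsensusEntry("fm", o=4.4, d=4.7)
    small = CheckCounts("fm", 8, 2, 2358)
    big = CheckCounts("fm", 80, 20, 23580)
    assert occurrence_ratio(entry, small) == pytest.approx(
        occurrence_ratio(entry, big), rel=1e-12
    )


def test_implied_o_close_to_observed_score(dose_calc_counts):
    """Taking consensus D at face value, explaining the observed 10 catches
    needs O ~ 5.8 -- essentially the clinic's own occurrence score."""
    val = implied_o(ConsensusEntry("fm36", o=4.4, d=4.7), dose_calc_counts)
    assert val == pytest.approx(5.77, abs=0.02)


def test_bootstrap_contains_point_estimate_and_tightens(dose_calc_counts):
    boot = bootstrap_intervals(dose_calc_counts, n_boot=1000, level=0.95, seed=9)
    lo, hi = boot.intervals["ce"]
    assert lo <= 0.75 <= hi
    assert not boot.indeterminate
    big = CheckCounts("fm36", 800, 200, 235_800)
    boot_big = bootstrap_intervals(big, n_boot=1000, level=0.95, seed=9)
    lo_b, hi_b = boot_big.intervals["ce"]
    assert (hi_b - lo_b) < (hi - lo)
    for name in ("ce", "n0", "o", "d"):
        assert boot.intervals[name][0] <= boot.intervals[name][1]


def test_bootstrap_counts_breakdown_replicates():
    """Tiny counts produce many N2 >= N1 resamples; they are reported, and a
    majority of them makes the result indeterminate."""
    boot = bootstrap_intervals(
        CheckCounts("fm", 2, 1, 500), n_boot=500, level=0.95, seed=4
    )
    assert boot.n_breakdown > 0
    assert boot.indeterminate == (boot.n_breakdown > 250)


def test_bootstrap_parameter_validation(dose_calc_counts):
    with pytest.raises(ValueError):
        bootstrap_intervals(dose_calc_counts, n_boot=50)
    with pytest.raises(ValueError):
        bootstrap_intervals(dose_calc_counts, level=1.5)


def test_validate_consensus_verdicts(dose_calc_counts):
    bad = validate_consensus(
        ConsensusEntry("fm36", o=4.4, d=4.7),
        dose_calc_counts,
        n_reps=50_000,
        n_boot=500,
        seed=13,
    )
    assert bad.verdict == "inconsistent"
    assert bad.expected_n2 < dose_calc_counts.n2
    est = estimate_risk(dose_calc_counts)
    good = validate_consensus(
        ConsensusEntry("fm36", o=est.o_continuous, d=est.d_continuous),
        dose_calc_counts,
        n_reps=50_000,
        n_boot=500,
        seed=13,
    )
    assert good.verdict == "consistent"
    assert good.occurrence_ratio == pytest.approx(1.0, abs=1e-9)


def test_validate_consensus_indeterminate_when_not_estimable():
    report = validate_consensus(
        ConsensusEntry("fm", o=5.0, d=5.0),
        CheckCounts("fm", 2, 2, 1000),
        n_reps=5_000,
        n_boot=500,
        seed=1,
    )
    assert report.verdict == "indeterminate"
    assert report.bootstrap is None


def test_consensus_entry_validation():
    with pytest.raises(ValueError):
        ConsensusEntry("fm", o=0.5, d=5)
    with pytest.raises(ValueError):
        ConsensusEntry("fm", o=5, d=11)
    with pytest.raises(ValueError):
        ConsensusEntry("fm", o=5, d=5, s=0.0)
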