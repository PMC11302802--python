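# Methods

## Model

An FM either occurs in a plan or it does not (Bernoulli per plan, at most one
instance per plan — at the ≤1% per-plan rates of interest the distinction
from a Poisson count is negligible, but fixing it keeps the simulator
reproducible). QC layers are applied in order; a layer is attempted only if
all earlier layers missed, and each attempt catches the FM independently
with the layer's check efficacy CE. The estimator assumes the first two
layers share one CE and that every catch is logged.

Under these assumptions E[N1] = N0·CE and E[N2] = (N0 − N1)·CE, giving the
closed-form moment estimators CE = 1 − N2/N1 and N0 = N1²/(N1 − N2). The
undetected remainder N0 − N1 − N2 = N2²/(N1 − N2) is reported alongside, and
the identity N0 = N1 + N2 + N2²/(N1 − N2) is asserted in tests to 1e-9.

Degenerate inputs: N1 = 0 raises an insufficient-data error; N2 ≥ N1 (implied
CE ≤ 0) raises a distinct breakdown error carrying the FM id, so a batch run
reports the row with a status flag instead of aborting or propagating NaN.
N2 = 0 is valid and yields CE = 1, zero escape probability, D = 1.

## Scales

Scores 1–10 are anchored to probabilities: for Occurrence the per-plan
occurrence probability, for Detectability the probability of escaping all
layers. Interpolation between integer anchors is **linear in probability**;
log-linear interpolation does not reproduce the standard worked conversions
(e.g. 0.45% → 5.8, 16% → 8.2). Continuous scores are reported alongside
nearest-integer scores (ties round half away from zero), since published
tables use one-decimal scores.

The anchor tables are data, not code (JSON, overridable per clinic). The
defaults are reconstructed from the worked conversions the method is known
to produce and should be confirmed against the authoritative task-group
table before clinical use:

| score | occurrence | detectability |
|------:|-----------:|--------------:|
| 1 | 0.0001 | 0.0001 |
| 2 | 0.0002 | 0.002 |
| 3 | 0.0005 | 0.005 |
| 4 | 0.001 | 0.01 |
| 5 | 0.002 | 0.02 |
| 6 | 0.005 | 0.05 |
| 7 | 0.01 | 0.10 |
| 8 | 0.02 | 0.15 |
| 9 | 0.05 | 0.20 |
| 10 | 0.10* | 0.40* |

\* The top category is open-ended (">5%", ">20%"); the starred values are
representative probabilities stored so the inverse lookup is total. Any
probability at or above them maps to exactly 10.0; anything below the score-1
anchor maps to 1.0.

## Consensus validation

Consensus D is read as the escape probability across **all** existing layers,
so the implied per-check efficacy is CE = 1 − p_undetected^(1/n). Expected
counts follow by plugging the consensus-implied (p_occ, CE) into the model.

The tail probability asks: if the consensus scores were true, how often would
counts at least as extreme as the observed ones arise? Per plan, the outcome
is one of {caught at layer 1, caught at layer 2, unobserved} with
probabilities (p_occ·CE, p_occ·(1−CE)·CE, rest), so (N1, N2) is multinomial;
the Monte Carlo samples that multinomial directly — the per-plan Bernoulli
model marginalized exactly, not an approximation. Extremity is ordered by
the distance of total catches N1+N2 from its expectation (two-sided); a
joint likelihood ordering on (N1, N2) is available as an optional mode. A
Poisson upper-tail closed form is used only as an independent oracle in the
tests. The default verdict threshold is a tail probability of 0.05
(configurable; the judgment is inherently qualitative).

`implied_o` answers "what occurrence score would the consensus D need to
explain the data": taking the consensus D's CE at face value, O is chosen so
the expected total recorded catches N0·(1 − p_undetected) equals the observed
N1+N2. On the worked example this computes to 5.77.

Bootstrap intervals are parametric percentile intervals: occurrences are
resampled as Binomial(n_plans, p̂_occ), catches by sequential
Binomial(·, ĈE) thinning, and each replicate re-estimated with the closed
form. Replicates that break down are counted and reported, never silently
dropped; more than 50% breakdowns marks the interval indeterminate. With
roughly ten events (the worked example's scale) count discreteness degrades
percentile coverage somewhat below nominal; the coverage study in the test
suite therefore runs at 20 000 plans (~100 expected events, ≥50 being the
usual regime where percentile intervals are meaningful) where measured
coverage of the 95% interval is ~0.96. Precision at small clinics is
honestly wide — that is the estimator's actual state of knowledge.

## Simulator

The generator emulates exactly the model above plus two controlled
violations used for bias studies: per-layer efficacies may differ, and a
caught event is logged only with probability `p_record` (an unlogged catch
is lost entirely, modelling incident-learning-system underreporting).
Defaults used in the calibration studies: 2×10⁵ plans (recovery), 2×10⁴
plans × 150 replicates (bias directions), per-plan occurrence 0.005–0.01 and
CE 0.6–0.9 — the regime the method targets. One global seed yields per-FM
substreams keyed by a hash of the FM id, so adding an FM never perturbs the
draws of the others, and identical seeds are bit-reproducible.

Expected bias directions, confirmed by the experiments: with a weaker second
check (CE₂ < CE₁) the ratio N2/N1 underestimates 1 − CE₁, so CE is
overestimated and both N0 and the escape probability (hence O and D) are
underestimated; with underreporting, N1 and N2 are thinned equally, leaving
CE unbiased while occurrence is low by the recording deficit (~20% at
p_record = 0.8).

What passing these simulations does **not** show about real data: the
simulator cannot detect catches made outside the designated QCs (upstream
detection), correlated misses between checkers, drift in check rigor over
time, or FM-definition ambiguity — all of which affect real logs.

## Limitations

* Severity is never estimated; it is supplied externally per FM.
* The equal-CE assumption is structural; no correction is attempted when the
  two checks differ (the bias direction is characterized instead).
* With counts of order ten, all interval statements are wide and the
  integer O/D scores absorb much of the uncertainty; a larger sample is the
  only remedy.
* The default scale anchors reproduce the standard worked conversions but
  are reconstructions; clinics should load their authoritative table via the
  JSON interface.
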