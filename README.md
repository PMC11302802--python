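# fmrisk

Empirical estimation of the **Occurrence (O)** and **Detectability (D)**
components of FMEA risk priority numbers from routine physics QC data in a
radiation-oncology clinic.

In failure modes and effects analysis, each failure mode (FM) is scored for
occurrence, severity and detectability, and ranked by the risk priority
number RPN = O × S × D. These scores are usually set by expert consensus.
When an FM is checked for **twice** — e.g. at the initial physics chart check
and again at the first weekly check — and every catch is logged with the
layer that caught it, O and D can instead be *measured*. `fmrisk` implements
that estimator, the ten-point scale lookups, a consensus-validation analysis,
and a synthetic clinic-QC simulator for calibration studies.

## The estimator

Let N0 be the true number of occurrences of an FM, N1 and N2 the counts
caught at the first and second check, and CE the probability a single check
catches the FM when present. Assuming the two checks are independent with
equal efficacy,

```
N1 = N0 · CE                 N2 = (N0 − N1) · CE
```

which solve in closed form to

```
CE = 1 − N2/N1               N0 = N1² / (N1 − N2)
```

— the two-sample capture-recapture (Lincoln–Petersen) logic applied to
sequential inspections. Then

* `N0 / n_plans` is the per-plan occurrence probability, placed on the
  ten-point Occurrence scale by linear interpolation between anchors;
* `(1 − CE)^n` is the probability an occurred FM escapes all `n` QC layers
  (the Swiss-cheese layered-defense model), placed on the Detectability
  scale the same way.

The estimate breaks down when N2 ≥ N1 (implied CE ≤ 0, a small-sample
accident); such FMs are flagged per-row rather than aborting a batch.

The package also quantifies whether published consensus (O, D) scores are
consistent with a clinic's observed counts: expected (N1, N2) under the
consensus scores, a seeded Monte-Carlo tail probability for the observed
counts, the fold-ratio of estimated to consensus-implied occurrences, and
parametric-bootstrap confidence intervals.

## Worked example

A clinic logs "dose calculation error" caught 8 times at the initial chart
check and 2 times at the first weekly check over 2358 plans:

```python
from fmrisk import CheckCounts, estimate_risk

counts = CheckCounts(fm_id="fm36", n1=8, n2=2, n_plans=2358, n_layers=2)
est = estimate_risk(counts)
print(f"CE = {est.ce:.0%}, N0 = {est.n0_rounded}")
print(f"occurrence fraction = {est.occurrence_fraction:.2%}  ->  O = {est.o_continuous:.1f} (integer {est.o_score})")
print(f"undetected prob     = {est.undetected_prob:.2%}  ->  D = {est.d_continuous:.2f} (integer {est.d_score})")
```

prints

```
CE = 75%, N0 = 11
occurrence fraction = 0.45%  ->  O = 5.8 (integer 6)
undetected prob     = 6.25%  ->  D = 6.25 (integer 6)
```

That is: each check catches this FM 75% of the time, an estimated 11
occurrences happened (one escaped both checks), the FM arises in about 0.5%
of plans (occurrence score 6), and with two layers it escapes about 6% of
the time (detectability score 6).

Checking a published consensus value against the same data:

```python
from fmrisk import ConsensusEntry, validate_consensus

report = validate_consensus(ConsensusEntry("fm36", o=4.4, d=4.7), counts, seed=1)
print(report.verdict, round(report.occurrence_ratio, 1), round(report.tail_prob, 4))
```

```
inconsistent 3.2 0.002
```

A consensus occurrence score of 4.4 implies ~3× fewer occurrences than the
clinic recorded; counts this large would arise with probability ~0.002 if
that score were correct.

The same machinery is available from the shell:

```
fmrisk estimate --counts counts.csv --plans 2358 --consensus tg275.csv --seed 1
fmrisk simulate --config sim.yaml --out log.csv --truth-out truth.json
```

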