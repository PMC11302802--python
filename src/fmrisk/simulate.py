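"""Synthetic clinic-QC generator with known ground truth.

Emulates the generative model the estimator assumes, plus the two violations
discussed as bias sources: unequal per-layer check efficacy and
under-recording of caught events.  Per plan and failure mode, occurrence is
Bernoulli(p_occ) (at most one instance per plan); an occurred FM passes
through the QC layers in order and each layer independently catches it with
that layer's efficacy; the first catching layer logs it with probability
``p_record`` (an unrecorded catch is lost entirely, modelling incident-system
underreporting).

Randomness uses one global seed with a per-FM substream derived from a hash
of the FM id, so adding or removing an FM leaves the other FMs' draws intact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimator import CheckCounts, EstimatorBreakdownError, InsufficientDataError, estimate_risk

__all__ = [
    "FailureModeSpec",
    "SimConfig",
    "EventRecord",
    "TruthSummary",
    "simulate_clinic",
    "aggregate",
    "bias_experiment",
]

UNDETECTED = "undetected"


@dataclass(frozen=True)
class FailureModeSpec:
    """Truth parameters for one simulated failure mode."""

    fm_id: str
    p_occ: float
    severity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_occ <= 1.0):
            raise ValueError(f"p_occ must be in [0, 1], got {self.p_occ!r}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated clinic.

    ``layer_efficacies`` has one per-check catch probability per QC layer, in
    the order the checks are performed; ``p_record`` is the probability that a
    caught FM actually makes it into the log (1.0 = perfect recording).
    """

    n_plans: int
    fm_specs: tuple[FailureModeSpec, ...]
    layer_efficacies: tuple[float, ...]
    p_record: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fm_specs", tuple(self.fm_specs))
        object.__setattr__(self, "layer_efficacies", tuple(self.layer_efficacies))
        if self.n_plans < 1:
            raise ValueError("n_plans must be >= 1")
        if len(self.layer_efficacies) < 1:
            raise ValueError("at least one QC layer is required")
        if any(not (0.0 <= e <= 1.0) for e in self.layer_efficacies):
            raise ValueError("layer efficacies must be in [0, 1]")
        if not (0.0 <= self.p_record <= 1.0):
            raise ValueError("p_record must be in [0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.layer_efficacies)


@dataclass(frozen=True)
class EventRecord:
    """One occurrence of a failure mode in one plan.

    ``layer_caught`` is the 1-based layer that caught it, or the sentinel
    ``"undetected"`` if every layer missed.  ``recorded`` is False for catches
    lost to under-recording and for undetected occurrences; only recorded
    catches are observable in a real clinic log.
    """

    plan_id: int
    fm_id: str
    layer_caught: int | str
    recorded: bool


@dataclass
class TruthSummary:
    """Ground truth per FM: true N0, catches per layer, undetected count."""

    n0: dict[str, int] = field(default_factory=dict)
    layer_catches: dict[str, list[int]] = field(default_factory=dict)
    undetected: dict[str, int] = field(default_factory=dict)


def _fm_rng(seed: int, fm_id: str) -> np.random.Generator:
    # substream keyed by (seed, hash(fm_id)) — independent of FM ordering
    digest = hashlib.sha256(fm_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_clinic(config: SimConfig) -> tuple[list[EventRecord], TruthSummary]:
    """Generate the event log and ground truth for one simulated clinic."""
    effs = np.asarray(config.layer_efficacies, dtype=float)
    n_layers = config.n_layers
    events: list[EventRecord] = []
    truth = TruthSummary()
    for spec in config.fm_specs:
        rng = _fm_rng(config.seed, spec.fm_id)
        occurred = np.flatnonzero(rng.random(config.n_plans) < spec.p_occ)
        n_occ = occurred.size
        # sequential layers: layer l is attempted only if all earlier missed
        u = rng.random((n_occ, n_layers))
        caught_at = np.full(n_occ, -1, dtype=int)  # 0-based layer, -1 = missed all
        remaining = np.ones(n_occ, dtype=bool)
        for layer in range(n_layers):
            hit = remaining & (u[:, layer] < effs[layer])
            caught_at[hit] = layer
            remaining &= ~hit
        recorded = np.zeros(n_occ, dtype=bool)
        caught_mask = caught_at >= 0
        recorded[caught_mask] = rng.random(int(caught_mask.sum())) < config.p_record
        layer_counts = [int(np.sum(caught_at == l)) for l in range(n_layers)]
        truth.n0[spec.fm_id] = int(n_occ)
        truth.layer_catches[spec.fm_id] = layer_counts
        truth.undetected[spec.fm_id] = int(np.sum(~caught_mask))
        for i in range(n_occ):
            events.append(
                EventRecord(
                    plan_id=int(occurred[i]),
                    fm_id=spec.fm_id,
                    layer_caught=int(caught_at[i]) + 1 if caught_at[i] >= 0 else UNDETECTED,
                    recorded=bool(recorded[i]),
                )
            )
    return events, truth


def aggregate(
    events: Sequence[EventRecord], n_plans: int, n_layers: int = 2
) -> list[CheckCounts]:
    """Collapse an event log to per-FM (N1, N2) counts of *recorded* catches.

    Undetected and unrecorded events contribute nothing — they are
    unobservable in a real log.  Catches at layers beyond the second are
    likewise not part of the two-count estimator input (the method uses the
    first two layers), but a layer index above ``n_layers`` is a
    malformed record and raises.
    """
    counts: dict[str, list[int]] = {}
    for row, ev in enumerate(events):
        if ev.layer_caught != UNDETECTED:
            layer = ev.layer_caught
            if not isinstance(layer, (int, np.integer)) or layer < 1:
                raise ValueError(f"record {row}: invalid layer {layer!r}")
            if layer > n_layers:
                raise ValueError(
                    f"record {row}: layer {layer} exceeds n_layers={n_layers}"
                )
        if not ev.recorded or ev.layer_caught == UNDETECTED:
            continue
        bucket = counts.setdefault(ev.fm_id, [0, 0])
        if ev.layer_caught == 1:
            bucket[0] += 1
        elif ev.layer_caught == 2:
            bucket[1] += 1
    return [
        CheckCounts(fm_id=fm, n1=c[0], n2=c[1], n_plans=n_plans, n_layers=n_layers)
        for fm, c in sorted(counts.items())
    ]


def bias_experiment(
    config_grid: Sequence[SimConfig], n_reps: int, seed: int
) -> pd.DataFrame:
    """Monte-Carlo bias table across simulation scenarios.

    Each scenario in ``config_grid`` is replicated ``n_reps`` times (scenario
    seeds are derived from ``seed``; the seeds stored in the configs are
    ignored).  For each the estimator runs on the aggregated recorded counts
    and the mean estimate is compared with the scenario truth.  Replicates
    where the estimate breaks down (N2 >= N1 or N1 = 0) are counted and
    excluded from the means.

    Returns a DataFrame with one row per (scenario, FM): truth and mean
    estimates of N0, CE and the all-layer undetected probability, plus their
    biases and the breakdown count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    seed_root = np.random.SeedSequence(seed)
    scenario_seeds = seed_root.generate_state(len(config_grid)) % (2**31)
    for s_idx, config in enumerate(config_grid):
        effs = np.asarray(config.layer_efficacies, dtype=float)
        true_undet_prob = float(np.prod(1.0 - effs))
        rep_seeds = (
            np.random.SeedSequence(int(scenario_seeds[s_idx])).generate_state(n_reps)
            % (2**31)
        )
        acc: dict[str, dict[str, list[float]]] = {
            spec.fm_id: {"n0": [], "ce": [], "undet": []} for spec in config.fm_specs
        }
        breakdowns = {spec.fm_id: 0 for spec in config.fm_specs}
        for r in range(n_reps):
            rep_cfg = SimConfig(
                n_plans=config.n_plans,
                fm_specs=config.fm_specs,
                layer_efficacies=config.layer_efficacies,
                p_record=config.p_record,
                seed=int(rep_seeds[r]),
            )
            events, _ = simulate_clinic(rep_cfg)
            agg = {c.fm_id: c for c in aggregate(events, config.n_plans, config.n_layers)}
            for spec in config.fm_specs:
                counts = agg.get(
                    spec.fm_id,
                    CheckCounts(spec.fm_id, 0, 0, config.n_plans, config.n_layers),
                )
                try:
                    est = estimate_risk(counts)
                except (EstimatorBreakdownError, InsufficientDataError):
                    breakdowns[spec.fm_id] += 1
                    continue
                acc[spec.fm_id]["n0"].append(est.n0_continuous)
                acc[spec.fm_id]["ce"].append(est.ce)
                acc[spec.fm_id]["undet"].append(est.undetected_prob)
        for spec in config.fm_specs:
            true_n0 = config.n_plans * spec.p_occ
            vals = acc[spec.fm_id]
            mean_n0 = float(np.mean(vals["n0"])) if vals["n0"] else np.nan
            mean_ce = float(np.mean(vals["ce"])) if vals["ce"] else np.nan
            mean_undet = float(np.mean(vals["undet"])) if vals["undet"] else np.nan
            rows.append(
                {
                    "scenario": s_idx,
                    "fm_id": spec.fm_id,
                    "n_plans": config.n_plans,
                    "p_record": config.p_record,
                    "layer_efficacies": tuple(config.layer_efficacies),
                    "true_n0": true_n0,
                    "true_ce_layer1": float(effs[0]),
                    "true_undetected_prob": true_undet_prob,
                    "mean_n0_hat": mean_n0,
                    "mean_ce_hat": mean_ce,
                    "mean_undetected_prob_hat": mean_undet,
                    "bias_n0": mean_n0 - true_n0,
                    "bias_ce": mean_ce - float(effs[0]),
                    "bias_undetected_prob": mean_undet - true_undet_prob,
                    "n_breakdown": breakdowns[spec.fm_id],
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
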