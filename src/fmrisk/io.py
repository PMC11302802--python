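"""Readers/writers for event logs, counts, consensus tables and scale files,
plus the end-to-end ``run_estimate`` report builder used by the CLI.

File conventions (all UTF-8, comma-separated, header required):

* event log:   ``plan_id,fm_id,check_layer`` — one row per recorded catch,
  ``check_layer`` 1-based; a given FM is caught at most once per plan.
* counts:      ``fm_id,n1,n2`` — pre-aggregated catches per FM; the number of
  plans is always supplied separately, never inferred from the file.
* consensus:   ``fm_id,O,S,D`` — one-decimal scores; S may be blank.
* scale table: JSON, ``{"kind": ..., "anchors": [{"score", "probability"}]}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .estimator import (
    CheckCounts,
    EstimatorBreakdownError,
    InsufficientDataError,
    estimate_risk,
)
from .scales import ScaleTable, default_detectability_table, default_occurrence_table
from .simulate import UNDETECTED, EventRecord, aggregate
from .validate import ConsensusEntry, validate_consensus

__all__ = [
    "ParseError",
    "RunConfig",
    "read_event_log",
    "write_event_log",
    "read_counts",
    "read_consensus",
    "read_severity",
    "run_estimate",
]

logger = logging.getLogger("fmrisk")


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


@dataclass
class RunConfig:
    """Everything one ``estimate``/``validate`` run needs.

    Exactly one of ``events_path`` or ``counts_path`` must be given.
    """

    n_plans: int
    events_path: Optional[str] = None
    counts_path: Optional[str] = None
    consensus_path: Optional[str] = None
    severity_path: Optional[str] = None
    o_scale_path: Optional[str] = None
    d_scale_path: Optional[str] = None
    n_layers: int = 2
    n_boot: int = 1000
    n_reps: int = 100_000
    level: float = 0.95
    seed: int = 0
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if (self.events_path is None) == (self.counts_path is None):
            raise ValueError("exactly one of events_path or counts_path must be supplied")
        if self.n_plans < 1:
            raise ValueError("n_plans must be >= 1")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_event_log(path) -> list[EventRecord]:
    """Read a clinic event log; every row is a recorded catch."""
    df = _read_csv(path, ["plan_id", "fm_id", "check_layer"])
    dup = df.duplicated(subset=["plan_id", "fm_id"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise ParseError(
            f"{path}: duplicate (plan_id, fm_id) pairs at rows {rows}; "
            "an FM is caught at most once per plan"
        )
    records = []
    for i, row in df.iterrows():
        try:
            layer = int(row["check_layer"])
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {i + 2}: non-integer check_layer {row['check_layer']!r}"
            ) from exc
        if layer < 1:
            raise ParseError(f"{path}: row {i + 2}: check_layer must be >= 1 (1-based)")
        records.append(
            EventRecord(
                plan_id=row["plan_id"], fm_id=row["fm_id"], layer_caught=layer, recorded=True
            )
        )
    return records


def write_event_log(events: Sequence[EventRecord], path) -> int:
    """Write recorded catches to CSV; returns the number of rows written."""
    rows = [
        {"plan_id": ev.plan_id, "fm_id": ev.fm_id, "check_layer": ev.layer_caught}
        for ev in events
        if ev.recorded and ev.layer_caught != UNDETECTED
    ]
    pd.DataFrame(rows, columns=["plan_id", "fm_id", "check_layer"]).to_csv(path, index=False)
    return len(rows)


def read_counts(path, n_plans: int, n_layers: int = 2) -> list[CheckCounts]:
    """Read pre-aggregated per-FM counts."""
    df = _read_csv(path, ["fm_id", "n1", "n2"])
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CheckCounts(
                    fm_id=row["fm_id"],
                    n1=int(row["n1"]),
                    n2=int(row["n2"]),
                    n_plans=n_plans,
                    n_layers=n_layers,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def read_consensus(path) -> dict[str, ConsensusEntry]:
    """Read a consensus table keyed by FM id; the S column may be blank."""
    df = _read_csv(path, ["fm_id", "O", "D"])
    entries = {}
    for i, row in df.iterrows():
        try:
            s = float(row["S"]) if "S" in df.columns and row["S"] != "" else None
            entries[row["fm_id"]] = ConsensusEntry(
                fm_id=row["fm_id"], o=float(row["O"]), d=float(row["D"]), s=s
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return entries


def read_severity(path) -> dict[str, float]:
    """Read an ``fm_id,S`` severity table."""
    df = _read_csv(path, ["fm_id", "S"])
    try:
        return {row["fm_id"]: float(row["S"]) for _, row in df.iterrows()}
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _load_tables(config: RunConfig) -> tuple[ScaleTable, ScaleTable]:
    o_table = (
        ScaleTable.from_json(config.o_scale_path)
        if config.o_scale_path
        else default_occurrence_table()
    )
    d_table = (
        ScaleTable.from_json(config.d_scale_path)
        if config.d_scale_path
        else default_detectability_table()
    )
    return o_table, d_table


def run_estimate(config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline and return one report row per failure mode.

    FMs whose counts are not estimable appear with a ``status`` flag instead
    of being dropped.  When a consensus table is supplied, validation columns
    (expected counts, tail probability, verdict, bootstrap intervals) are
    appended for FMs present in it.  Rows are sorted by fm_id.
    """
    o_table, d_table = _load_tables(config)
    if config.events_path is not None:
        events = read_event_log(config.events_path)
        counts_list = aggregate(events, config.n_plans, config.n_layers)
        if not events:
            logger.warning("event log %s is empty", config.events_path)
    else:
        counts_list = read_counts(config.counts_path, config.n_plans, config.n_layers)
    severities = read_severity(config.severity_path) if config.severity_path else {}
    consensus = read_consensus(config.consensus_path) if config.consensus_path else {}
    logger.info(
        "estimating %d FM(s) over %d plans, %d layers, seed=%d, scales o=%s d=%s",
        len(counts_list),
        config.n_plans,
        config.n_layers,
        config.seed,
        o_table.checksum(),
        d_table.checksum(),
    )
    rows = []
    for counts in sorted(counts_list, key=lambda c: c.fm_id):
        row: dict = {
            "fm_id": counts.fm_id,
            "n1": counts.n1,
            "n2": counts.n2,
            "n_plans": counts.n_plans,
            "n_layers": counts.n_layers,
            "seed": config.seed,
        }
        try:
            est = estimate_risk(
                counts, o_table, d_table, severity=severities.get(counts.fm_id)
            )
        except InsufficientDataError:
            row["status"] = "insufficient_data"
            rows.append(row)
            continue
        except EstimatorBreakdownError:
            row["status"] = "breakdown"
            rows.append(row)
            continue
        row.update(
            status="ok",
            ce=est.ce,
            n0=est.n0_rounded,
            n0_continuous=est.n0_continuous,
            undetected_count=est.undetected_count,
            occurrence_fraction=est.occurrence_fraction,
            undetected_prob=est.undetected_prob,
            o_continuous=est.o_continuous,
            d_continuous=est.d_continuous,
            o_score=est.o_score,
            d_score=est.d_score,
            severity=est.severity,
            rpn=est.rpn,
            rpn_continuous=est.rpn_continuous,
        )
        entry = consensus.get(counts.fm_id)
        if entry is not None:
            report = validate_consensus(
                entry,
                counts,
                o_table,
                d_table,
                n_reps=config.n_reps,
                n_boot=config.n_boot,
                level=config.level,
                seed=config.seed,
                threshold=config.threshold,
            )
            row.update(
                consensus_o=entry.o,
                consensus_d=entry.d,
                expected_n1=report.expected_n1,
                expected_n2=report.expected_n2,
                tail_prob=report.tail_prob,
                occurrence_ratio=report.occurrence_ratio,
                implied_o=report.implied_o,
                verdict=report.verdict,
            )
            if report.bootstrap is not None:
                for name, (lo, hi) in report.bootstrap.intervals.items():
                    row[f"{name}_ci_lower"] = lo
                    row[f"{name}_ci_upper"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
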