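"""Exon exclusion-ratio metrics for alternative-splicing quantification.

For one splicing event the exclusion ratio is
``exclusion / (inclusion + exclusion)`` where the operands are non-negative
band intensities or counts.  The ratio is scale-invariant, so whether the
underlying quantification was normalized does not affect it.  Replicate
ratios are averaged per condition (ratio-of-each-replicate, not pooled
counts — the semantics of per-lane gel quantification) and dispersion is the
standard error of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import GenomicDataError, PipelineUsageError

__all__ = ["SpliceCounts", "exclusion_ratio", "ratio_table", "read_splice_counts",
           "write_ratio_table"]


@dataclass(frozen=True, slots=True)
class SpliceCounts:
    """Inclusion/exclusion quantities for one event in one replicate."""

    event_id: str
    inclusion: float
    exclusion: float

    def __post_init__(self) -> None:
        if self.inclusion < 0 or self.exclusion < 0:
            raise GenomicDataError(
                f"{self.event_id}: splice quantities must be >= 0"
            )


def exclusion_ratio(c: SpliceCounts) -> float:
    """exclusion / (inclusion + exclusion), in [0, 1].

    Undefined (raises) when both operands are zero — callers report such
    events as missing, never as 0.
    """
    total = c.inclusion + c.exclusion
    if total == 0:
        raise PipelineUsageError(
            f"{c.event_id}: exclusion ratio undefined (inclusion + exclusion = 0)"
        )
    return c.exclusion / total


def ratio_table(
    conditions: Mapping[str, Sequence[SpliceCounts]],
) -> pd.DataFrame:
    """Per-event, per-condition mean exclusion ratio with SEM over replicates.

    Returns a DataFrame with columns event_id, condition, mean_ratio, sem, n.
    SEM is sample sd (ddof=1) / sqrt(n); with a single replicate the mean is
    the value and SEM is missing (NaN).  Replicates whose ratio is undefined
    (0/0) are excluded from that cell; an event present in only some
    conditions appears with rows only for the conditions that measured it.
    """
    if not conditions:
        raise PipelineUsageError("ratio_table: no conditions given")
    rows = []
    for condition in sorted(conditions):
        per_event: dict[str, list[float]] = {}
        for c in conditions[condition]:
            if c.inclusion + c.exclusion == 0:
                continue
            per_event.setdefault(c.event_id, []).append(exclusion_ratio(c))
        for event_id in sorted(per_event):
            ratios = per_event[event_id]
            n = len(ratios)
            mean = math.fsum(ratios) / n
            if n == 1:
                sem = float("nan")
            elif max(ratios) == min(ratios):
                sem = 0.0  # identical replicates: exactly zero dispersion
            else:
                var = math.fsum((r - mean) ** 2 for r in ratios) / (n - 1)
                sem = math.sqrt(var) / math.sqrt(n)
            rows.append(
                {
                    "event_id": event_id,
                    "condition": condition,
                    "mean_ratio": mean,
                    "sem": sem,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "condition", "mean_ratio", "sem", "n"])


def read_splice_counts(path: str | Path) -> dict[str, list[SpliceCounts]]:
    """Read a TSV with columns event_id, condition, replicate, inclusion,
    exclusion into a condition -> replicates mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"event_id", "condition", "inclusion", "exclusion"}
    missing = required - set(df.columns)
    if missing:
        raise GenomicDataError(
            f"{path}: missing splice-count columns: {', '.join(sorted(missing))}"
        )
    out: dict[str, list[SpliceCounts]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.condition), []).append(
            SpliceCounts(
                event_id=str(row.event_id),
                inclusion=float(row.inclusion),
                exclusion=float(row.exclusion),
            )
        )
    return out


def write_ratio_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
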