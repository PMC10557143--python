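"""The co-localization screen: per-protein overlap percentages against two
structure peak sets (R-loop and G-quadruplex loci), the cross-protein
correlation of those percentages, and candidate ranking.

The overlap percentage for a protein is
``100 * (number of its peaks overlapping the structure set) / (total peaks)``,
computed with exact rational arithmetic before the final float conversion.
The correlation across proteins is the Pearson product-moment ``r`` of the
(pct_g4, pct_rloop) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import IntervalIndex, intersect_report_a, three_way_cooccupancy
from .types import Peak, PipelineUsageError

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenRecord",
    "ScreenTable",
    "overlap_percentage",
    "pearson_r",
    "run_screen",
    "rank_candidates",
    "write_screen_table",
    "read_screen_table",
]


@dataclass(frozen=True, slots=True)
class ScreenRecord:
    protein: str
    n_peaks: int
    n_overlap_rloop: int
    n_overlap_g4: int
    n_overlap_both: int
    pct_rloop: float
    pct_g4: float

    def __post_init__(self) -> None:
        assert self.n_peaks > 0
        assert self.n_overlap_both <= min(self.n_overlap_rloop, self.n_overlap_g4)
        assert max(self.n_overlap_rloop, self.n_overlap_g4) <= self.n_peaks


@dataclass(frozen=True)
class ScreenTable:
    """Per-protein screen records plus the cross-protein correlation.

    ``pearson_r`` is None when undefined (< 3 records, or a percentage
    column with zero variance).  ``skipped`` lists proteins dropped because
    their peak set was empty.
    """

    records: list[ScreenRecord]
    pearson_r: float | None
    skipped: list[str]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, protein: str) -> ScreenRecord:
        for r in self.records:
            if r.protein == protein:
                return r
        raise KeyError(protein)


def overlap_percentage(A: Sequence[Peak], B: Sequence[Peak] | IntervalIndex) -> float:
    """100 * |A peaks overlapping >= 1 B peak| / |A|, exact before float."""
    if len(A) == 0:
        raise PipelineUsageError("overlap percentage is undefined for an empty peak set")
    n_overlap = len(intersect_report_a(A, B))
    return float(Fraction(100 * n_overlap, len(A)))


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length samples.

    Raises :class:`PipelineUsageError` for n < 3 or zero variance rather than
    propagating NaN.
    """
    x = np.asarray(xs, dtype=np.float64)
    y = np.asarray(ys, dtype=np.float64)
    if x.shape != y.shape:
        raise PipelineUsageError("pearson_r: inputs must have equal length")
    if len(x) < 3:
        raise PipelineUsageError("pearson_r: need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PipelineUsageError("pearson_r: zero variance in an input")
    return float(stats.pearsonr(x, y).statistic)


def run_screen(
    tf_sets: Mapping[str, Sequence[Peak]],
    rloop: Sequence[Peak],
    g4: Sequence[Peak],
) -> ScreenTable:
    """Screen every protein's peak set against the two structure peak sets.

    Produces one :class:`ScreenRecord` per protein in name-sorted order
    (insertion order never matters).  Proteins with zero peaks are skipped
    with a warning and recorded in ``skipped`` — their statistic is
    undefined, never imputed.  Empty structure sets are allowed and yield
    all-zero percentages.
    """
    if not tf_sets:
        raise PipelineUsageError("run_screen: no TF peak sets given")
    r_index = IntervalIndex.from_peaks(rloop)
    g_index = IntervalIndex.from_peaks(g4)
    records: list[ScreenRecord] = []
    skipped: list[str] = []
    for protein in sorted(tf_sets):
        peaks = tf_sets[protein]
        if len(peaks) == 0:
            logger.warning("protein %s has zero peaks; skipped", protein)
            skipped.append(protein)
            continue
        co = three_way_cooccupancy(peaks, r_index, g_index)
        records.append(
            ScreenRecord(
                protein=protein,
                n_peaks=co.n_total,
                n_overlap_rloop=co.n_rloop,
                n_overlap_g4=co.n_g4,
                n_overlap_both=co.n_both,
                pct_rloop=float(Fraction(100 * co.n_rloop, co.n_total)),
                pct_g4=float(Fraction(100 * co.n_g4, co.n_total)),
            )
        )
    r: float | None = None
    if len(records) >= 3:
        g = [rec.pct_g4 for rec in records]
        rl = [rec.pct_rloop for rec in records]
        if max(g) > min(g) and max(rl) > min(rl):
            r = pearson_r(g, rl)
    return ScreenTable(records=records, pearson_r=r, skipped=skipped)


def rank_candidates(table: ScreenTable, min_pct: float = 25.0) -> list[str]:
    """Proteins with both percentages >= min_pct, best first.

    The ranking statistic is ``min(pct_rloop, pct_g4)`` (descending); ties
    are broken by protein name.  The statistic is a package choice — any
    scalar summary of "high overlap with both" would do.
    """
    if not table.records:
        raise PipelineUsageError("rank_candidates: empty screen table")
    kept = [
        r
        for r in table.records
        if r.pct_rloop >= min_pct and r.pct_g4 >= min_pct
    ]
    kept.sort(key=lambda r: (-min(r.pct_rloop, r.pct_g4), r.protein))
    return [r.protein for r in kept]


_COLUMNS = ["protein", "n_peaks", "n_rloop", "pct_rloop", "n_g4", "pct_g4", "n_both"]


def write_screen_table(
    path: str | Path, table: ScreenTable, metadata: Mapping[str, str] | None = None
) -> None:
    """Write the screen table as TSV with '#'-prefixed metadata lines.

    Percentages are printed to 4 decimal places; full precision is retained
    in memory.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# colocscreen screen table\n")
        r_text = "NA" if table.pearson_r is None else repr(table.pearson_r)
        fh.write(f"# pearson_r\t{r_text}\n")
        fh.write(f"# n_records\t{len(table.records)}\n")
        if table.skipped:
            fh.write(f"# skipped_empty\t{','.join(table.skipped)}\n")
        for key in sorted(metadata or {}):
            fh.write(f"# {key}\t{metadata[key]}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                f"{r.protein}\t{r.n_peaks}\t{r.n_overlap_rloop}\t{r.pct_rloop:.4f}"
                f"\t{r.n_overlap_g4}\t{r.pct_g4:.4f}\t{r.n_overlap_both}\n"
            )


def read_screen_table(path: str | Path) -> ScreenTable:
    """Read back a TSV written by :func:`write_screen_table`."""
    records: list[ScreenRecord] = []
    r_value: float | None = None
    skipped: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = line[2:].split("\t")
                if fields[0] == "pearson_r" and len(fields) > 1 and fields[1] != "NA":
                    r_value = float(fields[1])
                if fields[0] == "skipped_empty" and len(fields) > 1:
                    skipped = fields[1].split(",")
                continue
            f = line.split("\t")
            if f[0] == "protein":
                continue
            n = int(f[1])
            records.append(
                ScreenRecord(
                    protein=f[0],
                    n_peaks=n,
                    n_overlap_rloop=int(f[2]),
                    n_overlap_g4=int(f[4]),
                    n_overlap_both=int(f[6]),
                    pct_rloop=float(Fraction(100 * int(f[2]), n)),
                    pct_g4=float(Fraction(100 * int(f[4]), n)),
                )
            )
    return ScreenTable(records=records, pearson_r=r_value, skipped=skipped)
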