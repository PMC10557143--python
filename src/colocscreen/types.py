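"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; conversion to 1-based happens only in human-readable report text,
if ever.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicDataError",
    "ParseError",
    "PipelineUsageError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
]


class GenomicDataError(ValueError):
    """A data file or in-memory record violates an invariant."""


class ParseError(GenomicDataError):
    """A text record could not be parsed; carries file path and line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:" if line is None else f"{path}:{line}:"
        super().__init__(f"{loc} {message}" if loc else message)
        self.path = path
        self.line = line


class PipelineUsageError(Exception):
    """The caller asked for something undefined (bad flag, empty input set)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A located span on a chromosome, 0-based half-open.

    The unit of all overlap logic: ``[start, end)`` with ``start < end``.
    Zero-length intervals are rejected at construction.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GenomicDataError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise GenomicDataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Peak:
    """A narrowPeak-style record: an interval plus name, score and summit.

    ``summit_offset`` is the offset of the point of highest enrichment from
    ``interval.start``; ``-1`` means the summit is undefined (plain BED input).
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.score < 0:
            raise GenomicDataError(f"peak score must be >= 0, got {self.score}")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise GenomicDataError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A transcript span with strand, the anchor for promoter/metagene logic."""

    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomicDataError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise GenomicDataError(
                f"gene {self.gene_id}: invalid span {self.tx_start}-{self.tx_end}"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)


class CoverageTrack:
    """A per-chromosome non-overlapping step function of signal density.

    Steps are sorted, non-overlapping, with finite values >= 0; gaps between
    steps mean value 0.  Internally each chromosome holds three aligned numpy
    arrays (starts, ends, values) plus a cumulative integral so that the exact
    integral of the step function over any span is an O(log n) lookup.
    """

    def __init__(
        self,
        steps: Iterable[tuple[str, int, int, float]],
        chrom_sizes: Mapping[str, int] | None = None,
    ):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            if not (0 <= start < end):
                raise GenomicDataError(f"bad step {chrom}:{start}-{end}")
            if not math.isfinite(value) or value < 0:
                raise GenomicDataError(
                    f"step value must be finite and >= 0, got {value} at "
                    f"{chrom}:{start}-{end}"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise GenomicDataError(f"step on unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise GenomicDataError(
                        f"step {chrom}:{start}-{end} exceeds chromosome length "
                        f"{chrom_sizes[chrom]}"
                    )
            per_chrom.setdefault(chrom, []).append((start, end, value))

        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in per_chrom.items():
            triples.sort(key=lambda t: t[0])
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise GenomicDataError(
                    f"overlapping steps on {chrom}: "
                    f"({starts[i]},{ends[i]}) and ({starts[i + 1]},{ends[i + 1]})"
                )
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def n_steps(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._data[chrom][0]) if chrom in self._data else 0
        return sum(len(v[0]) for v in self._data.values())

    def iter_steps(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values, _ = self._data[chrom]
            for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
                yield chrom, s, e, v

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._data:
            empty_i = np.empty(0, dtype=np.int64)
            return empty_i, empty_i.copy(), np.empty(0, dtype=np.float64)
        starts, ends, values, _ = self._data[chrom]
        return starts, ends, values

    def _cumulative(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, x) for an array of positions."""
        if chrom not in self._data:
            return np.zeros(len(x), dtype=np.float64)
        starts, ends, values, cum = self._data[chrom]
        idx = np.searchsorted(starts, x, side="right") - 1
        safe = np.maximum(idx, 0)
        inside = np.clip(x - starts[safe], 0, ends[safe] - starts[safe])
        out = cum[safe] + values[safe] * inside
        return np.where(idx >= 0, out, 0.0)

    def integral(self, chrom: str, start, end) -> float | np.ndarray:
        """Exact integral (signal x length) of the track over [start, end)."""
        a = np.atleast_1d(np.asarray(start, dtype=np.float64))
        b = np.atleast_1d(np.asarray(end, dtype=np.float64))
        res = self._cumulative(chrom, b) - self._cumulative(chrom, a)
        if np.isscalar(start) or np.ndim(start) == 0:
            return float(res[0])
        return res

    def mean(self, chrom: str, start, end):
        """Length-weighted mean of the track over [start, end); gaps count as 0."""
        a = np.asarray(start, dtype=np.float64)
        b = np.asarray(end, dtype=np.float64)
        return self.integral(chrom, start, end) / (b - a)

    def total_signal(self) -> float:
        """Sum of value x length over every step of every chromosome."""
        return float(sum(self._data[c][3][-1] for c in self._data))
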