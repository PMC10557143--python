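"""Exact interval-overlap primitives underlying the co-occupancy screen.

The reporting convention throughout is *record-level*: a query peak is
reported (once, in input order) iff it shares at least one base with at
least one peak of the reference set, mirroring ``bedtools intersect -wa -u``
with its default 1 bp minimum overlap.  Duplicate identical peaks in the
query are independent records and are reported independently.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .types import GenomicInterval, Peak

__all__ = [
    "IntervalIndex",
    "overlaps",
    "intersect_report_a",
    "three_way_cooccupancy",
    "CoOccupancy",
]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b are on the same chromosome and share >= 1 base.

    Half-open semantics: abutting intervals ([100,200) vs [200,300)) do not
    overlap.
    """
    return a.overlaps(b)


class IntervalIndex:
    """Per-chromosome interval tree supporting overlap/stabbing queries.

    ``query(q)`` returns exactly the stored intervals ``i`` with
    ``i.start < q.end and q.start < i.end``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def __len__(self) -> int:
        return self._n

    def add(self, iv: GenomicInterval) -> None:
        self._trees[iv.chrom].addi(iv.start, iv.end, iv)
        self._n += 1

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlaps(iv.start, iv.end))

    def query(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda g: (g.start, g.end))
        return hits

    @classmethod
    def from_peaks(cls, peaks: Iterable[Peak]) -> "IntervalIndex":
        return cls(p.interval for p in peaks)


def intersect_report_a(
    A: Sequence[Peak], B: Sequence[Peak] | IntervalIndex
) -> list[Peak]:
    """Peaks of A (each at most once, in A's order) overlapping >= 1 peak of B.

    An A peak overlapping many B peaks still appears exactly once; the result
    is a subset of A and the operation is idempotent.
    """
    index = B if isinstance(B, IntervalIndex) else IntervalIndex.from_peaks(B)
    return [p for p in A if index.any_overlap(p.interval)]


@dataclass(frozen=True, slots=True)
class CoOccupancy:
    """Record-level co-occupancy counts of a peak set against two others."""

    n_total: int
    n_rloop: int
    n_g4: int
    n_both: int

    def __post_init__(self) -> None:
        assert self.n_both <= min(self.n_rloop, self.n_g4) <= self.n_total


def three_way_cooccupancy(
    A: Sequence[Peak],
    R: Sequence[Peak] | IntervalIndex,
    G: Sequence[Peak] | IntervalIndex,
) -> CoOccupancy:
    """Count A peaks overlapping R, G, and both, by record-level membership.

    Membership in each class is determined against R and G independently with
    :func:`intersect_report_a` semantics; ``n_both`` counts peaks in both
    classes.
    """
    r_index = R if isinstance(R, IntervalIndex) else IntervalIndex.from_peaks(R)
    g_index = G if isinstance(G, IntervalIndex) else IntervalIndex.from_peaks(G)
    n_r = n_g = n_both = 0
    for p in A:
        in_r = r_index.any_overlap(p.interval)
        in_g = g_index.any_overlap(p.interval)
        n_r += in_r
        n_g += in_g
        n_both += in_r and in_g
    return CoOccupancy(n_total=len(A), n_rloop=n_r, n_g4=n_g, n_both=n_both)
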