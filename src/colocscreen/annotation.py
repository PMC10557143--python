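"""Strand-aware promoter windows and promoter/genic/intergenic peak classes.

A promoter window is the interval around the transcription start site (TSS):
for a + strand gene ``[tx_start - upstream, tx_start + downstream)``, for a
- strand gene ``[tx_end - downstream, tx_end + upstream)``, clipped to
chromosome bounds.  The default window (-1000/+500 bp) is a common
convention, configurable because published promoter-localization fractions
depend heavily on the (often unstated) window definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .intervals import IntervalIndex
from .types import (
    GeneModel,
    GenomicDataError,
    GenomicInterval,
    Peak,
    PipelineUsageError,
)

__all__ = [
    "PromoterWindow",
    "promoter_regions",
    "classify_peaks",
    "promoter_fraction",
    "DEFAULT_UPSTREAM",
    "DEFAULT_DOWNSTREAM",
]

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 500


@dataclass(frozen=True, slots=True)
class PromoterWindow:
    interval: GenomicInterval
    gene_id: str
    strand: str


def promoter_regions(
    genes: Sequence[GeneModel],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """Strand-aware TSS windows for every gene, clipped to chromosome bounds.

    Windows that clip to nothing (possible only for a gene flush against a
    chromosome end with ``downstream=0``) are dropped.  Overlapping windows
    from different genes are kept separate: classification membership is
    existential, and unmerged windows keep their gene attribution.
    """
    if upstream < 0 or downstream < 0:
        raise PipelineUsageError("promoter window extents must be >= 0")
    if upstream == 0 and downstream == 0:
        raise PipelineUsageError("promoter window cannot be empty (0 up, 0 down)")
    if chrom_sizes is not None:
        unknown = sorted({g.chrom for g in genes} - set(chrom_sizes))
        if unknown:
            raise GenomicDataError(
                f"genes on chromosomes absent from chrom.sizes: {', '.join(unknown)}"
            )
    windows: list[PromoterWindow] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tx_start - upstream, g.tx_start + downstream
        else:
            start, end = g.tx_end - downstream, g.tx_end + upstream
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        if start >= end:
            continue
        windows.append(
            PromoterWindow(GenomicInterval(g.chrom, start, end), g.gene_id, g.strand)
        )
    return windows


def _query_interval(peak: Peak, by_summit: bool) -> GenomicInterval:
    if by_summit:
        center = (
            peak.start + peak.summit_offset
            if peak.summit_offset >= 0
            else (peak.start + peak.end) // 2
        )
        return GenomicInterval(peak.chrom, center, center + 1)
    return peak.interval


def classify_peaks(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterWindow],
    genes: Sequence[GeneModel],
    by_summit: bool = False,
) -> list[tuple[str, str]]:
    """Assign each peak a (class, gene_id) pair; class precedence is
    promoter > genic > intergenic.

    A peak overlapping any promoter window (>= 1 bp of the full peak span,
    or the summit point when ``by_summit``) is "promoter" regardless of
    gene-body overlap; otherwise a peak overlapping any transcript span is
    "genic"; the rest are "intergenic".  ``gene_id`` is the id of the
    leftmost-starting overlapping promoter window (or gene span for genic
    peaks); intergenic peaks get ".".  Output is aligned with ``peaks``.
    """
    prom_index = IntervalIndex()
    prom_by_key: dict[tuple[str, int, int], list[str]] = {}
    for w in promoters:
        prom_index.add(w.interval)
        prom_by_key.setdefault(
            (w.interval.chrom, w.interval.start, w.interval.end), []
        ).append(w.gene_id)
    gene_index = IntervalIndex()
    gene_by_key: dict[tuple[str, int, int], list[str]] = {}
    for g in genes:
        gene_index.add(g.interval)
        gene_by_key.setdefault((g.chrom, g.tx_start, g.tx_end), []).append(g.gene_id)

    out: list[tuple[str, str]] = []
    for p in peaks:
        q = _query_interval(p, by_summit)
        hits = prom_index.query(q)
        if hits:
            best = hits[0]
            gid = sorted(prom_by_key[(best.chrom, best.start, best.end)])[0]
            out.append(("promoter", gid))
            continue
        hits = gene_index.query(q)
        if hits:
            best = hits[0]
            gid = sorted(gene_by_key[(best.chrom, best.start, best.end)])[0]
            out.append(("genic", gid))
            continue
        out.append(("intergenic", "."))
    return out


def promoter_fraction(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterWindow],
    by_summit: bool = False,
) -> float:
    """Percentage of peaks overlapping >= 1 promoter window (exact rational
    arithmetic before the final float)."""
    if len(peaks) == 0:
        raise PipelineUsageError("promoter fraction is undefined for an empty peak set")
    index = IntervalIndex(w.interval for w in promoters)
    n_prom = sum(index.any_overlap(_query_interval(p, by_summit)) for p in peaks)
    return float(Fraction(100 * n_prom, len(peaks)))
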