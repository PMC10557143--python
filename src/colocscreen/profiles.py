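"""Signal aggregation around anchors, scaled-gene metagene profiles, region
densities and RPKM-style coverage normalization.

Bin values are always *length-weighted means* of the underlying coverage
step function, never sums: this makes a constant track map to a constant
profile exactly, independent of bin size, and makes the operations linear in
the track.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .types import (
    CoverageTrack,
    GenomicDataError,
    GenomicInterval,
    Peak,
    PipelineUsageError,
)

__all__ = [
    "peak_center",
    "ProfileMatrix",
    "aggregate_profile",
    "MetageneProfile",
    "metagene_profile",
    "RegionDensity",
    "region_density",
    "rpkm_normalize",
]


def peak_center(p: Peak) -> int:
    """The summit position when defined, else the floor midpoint."""
    if p.summit_offset >= 0:
        return p.start + p.summit_offset
    return (p.start + p.end) // 2


@dataclass(frozen=True)
class ProfileMatrix:
    """anchors x bins matrix of mean signal per bin around anchor centers.

    Bin j of an anchor at position c covers
    ``[c - window + j*bin_size, c - window + (j+1)*bin_size)``.
    ``mean_curve`` is the per-bin arithmetic mean over anchors.
    """

    window: int
    bin_size: int
    values: np.ndarray  # shape (anchors, bins)
    n_dropped: int

    @property
    def n_anchors(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_offsets(self) -> np.ndarray:
        """Offset of each bin's left edge from the anchor center."""
        return -self.window + self.bin_size * np.arange(self.n_bins)

    @property
    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)


def aggregate_profile(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int]],
    window: int = 2000,
    bin_size: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Mean signal in fixed bins tiling [center - window, center + window).

    Anchors whose window would extend past a chromosome end are dropped
    entirely (never zero-padded, which would bias the means toward zero) and
    counted in ``n_dropped``.  Anchors on chromosomes absent from
    ``chrom_sizes`` are an error.
    """
    if window <= 0 or bin_size <= 0 or window % bin_size != 0:
        raise PipelineUsageError("window must be a positive multiple of bin_size")
    sizes = chrom_sizes if chrom_sizes is not None else track.chrom_sizes
    if sizes is None:
        raise PipelineUsageError("aggregate_profile needs chromosome sizes")
    unknown = sorted({c for c, _ in anchors} - set(sizes))
    if unknown:
        raise GenomicDataError(f"anchors on unknown chromosomes: {', '.join(unknown)}")

    n_bins = 2 * window // bin_size
    rows: list[np.ndarray] = []
    n_dropped = 0
    offsets = -window + bin_size * np.arange(n_bins + 1, dtype=np.int64)
    for chrom, center in anchors:
        if center - window < 0 or center + window > sizes[chrom]:
            n_dropped += 1
            continue
        edges = center + offsets
        integ = track.integral(chrom, edges[:-1], edges[1:])
        rows.append(integ / bin_size)
    if not rows:
        raise PipelineUsageError("no usable anchors (all dropped or none given)")
    return ProfileMatrix(
        window=window,
        bin_size=bin_size,
        values=np.vstack(rows),
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class MetageneProfile:
    """Mean signal over (upstream flank | scaled gene body | downstream flank),
    on a TSS->TES axis for every gene regardless of strand."""

    flank: int
    flank_bin: int
    body_bins: int
    curve: np.ndarray
    n_genes: int
    n_dropped: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    def split(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(upstream flank, body, downstream flank) slices of the curve."""
        k = self.n_flank_bins
        return self.curve[:k], self.curve[k : k + self.body_bins], self.curve[k + self.body_bins :]


def _exact_bin_means(
    starts: list[int],
    ends: list[int],
    values: list[float],
    edges: list,  # ints or Fractions, ascending
) -> list[float]:
    """Length-weighted mean of a step function over each [edges[i], edges[i+1]).

    Uses exact rational edge arithmetic and ``math.fsum`` so the result is
    invariant under coordinate reflection: a gene and its mirror image on a
    mirrored track produce bitwise-identical curves.
    """
    out: list[float] = []
    for a, b in zip(edges[:-1], edges[1:]):
        lo = bisect_right(ends, a)  # first step with end > a
        hi = bisect_left(starts, b)  # steps with start < b are [0, hi)
        parts: list[float] = []
        for j in range(lo, hi):
            ov = min(ends[j], b) - max(starts[j], a)
            if ov > 0:
                parts.append(values[j] * float(ov))
        width = b - a
        out.append(math.fsum(parts) / float(width))
    return out


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence,  # GeneModel
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Scaled-gene mean profile: fixed-length flanks, equal-occupancy body bins.

    Each gene body is divided into ``body_bins`` equal coordinate slices
    (exact rational boundaries, so bodies need not be multiples of the bin
    count); - strand genes are traversed TES->TSS and reversed so the axis is
    TSS->TES for every gene.  Genes shorter than ``body_bins`` bases or whose
    flanks leave the chromosome are dropped and counted.
    """
    if flank <= 0 or flank_bin <= 0 or flank % flank_bin != 0:
        raise PipelineUsageError("flank must be a positive multiple of flank_bin")
    if body_bins < 1:
        raise PipelineUsageError("body_bins must be >= 1")
    sizes = chrom_sizes if chrom_sizes is not None else track.chrom_sizes
    if sizes is None:
        raise PipelineUsageError("metagene_profile needs chromosome sizes")

    n_flank = flank // flank_bin
    step_cache: dict[str, tuple[list[int], list[int], list[float]]] = {}

    def chrom_steps(chrom: str):
        if chrom not in step_cache:
            s, e, v = track.steps(chrom)
            step_cache[chrom] = (s.tolist(), e.tolist(), v.tolist())
        return step_cache[chrom]

    per_gene: list[list[float]] = []
    n_dropped = 0
    for g in genes:
        if g.chrom not in sizes:
            raise GenomicDataError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        length = g.tx_end - g.tx_start
        lo5 = g.tx_start - flank  # genomic extent including flanks
        hi3 = g.tx_end + flank
        if length < body_bins or lo5 < 0 or hi3 > sizes[g.chrom]:
            n_dropped += 1
            continue
        starts, ends, values = chrom_steps(g.chrom)
        # Edges along the genome, 5'->3' in genomic orientation.
        up_edges = [g.tx_start - flank + k * flank_bin for k in range(n_flank + 1)]
        body_edges = [
            g.tx_start + Fraction(length * k, body_bins) for k in range(body_bins + 1)
        ]
        down_edges = [g.tx_end + k * flank_bin for k in range(n_flank + 1)]
        row = (
            _exact_bin_means(starts, ends, values, up_edges)
            + _exact_bin_means(starts, ends, values, body_edges)
            + _exact_bin_means(starts, ends, values, down_edges)
        )
        if g.strand == "-":
            row.reverse()
        per_gene.append(row)
    if not per_gene:
        raise PipelineUsageError("no usable genes for metagene profile")
    n_bins = 2 * n_flank + body_bins
    n_genes = len(per_gene)
    curve = np.array(
        [
            math.fsum(row[j] for row in per_gene) / n_genes
            for j in range(n_bins)
        ],
        dtype=np.float64,
    )
    return MetageneProfile(
        flank=flank,
        flank_bin=flank_bin,
        body_bins=body_bins,
        curve=curve,
        n_genes=n_genes,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True, slots=True)
class RegionDensity:
    """Signal per kilobase per million total signal units in one region."""

    region_id: str
    region_class: str
    density: float


def region_density(
    track: CoverageTrack,
    regions: Sequence[tuple[str, str, GenomicInterval]],
    total_signal: float,
) -> list[RegionDensity]:
    """Depth- and length-normalized signal density per region:
    ``(sum of track over region) / (length in kb) / (total_signal / 1e6)``."""
    if total_signal <= 0:
        raise PipelineUsageError("region_density needs total_signal > 0")
    out = []
    for region_id, region_class, iv in regions:
        total = track.integral(iv.chrom, iv.start, iv.end)
        density = total / (iv.length / 1000.0) / (total_signal / 1e6)
        out.append(RegionDensity(region_id, region_class, density))
    return out


def rpkm_normalize(
    read_intervals: Sequence[GenomicInterval],
    bin_size: int,
    chrom_sizes: Mapping[str, int],
) -> CoverageTrack:
    """Reads-per-kilobase-per-million coverage over fixed genomic bins.

    Each bin's value is ``(#reads overlapping the bin) / (bin length in kb) /
    (total reads / 1e6)``; a truncated final bin uses its actual length.
    Runs of equal-valued adjacent bins are merged into single steps.
    """
    if bin_size < 1:
        raise PipelineUsageError("bin_size must be >= 1")
    if len(read_intervals) == 0:
        raise PipelineUsageError("rpkm_normalize needs at least one read")
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in read_intervals:
        if iv.chrom not in chrom_sizes:
            raise GenomicDataError(f"read on unknown chromosome {iv.chrom!r}")
        per_chrom.setdefault(iv.chrom, []).append(iv)
    n_total = len(read_intervals)
    depth_factor = n_total / 1e6

    steps: list[tuple[str, int, int, float]] = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        edges = np.arange(0, length + bin_size, bin_size, dtype=np.int64)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        reads = per_chrom.get(chrom, [])
        r_starts = np.sort(np.array([r.start for r in reads], dtype=np.int64))
        r_ends = np.sort(np.array([r.end for r in reads], dtype=np.int64))
        # reads overlapping [a, b) = #(start < b) - #(end <= a)
        counts = np.searchsorted(r_starts, edges[1:], side="left") - np.searchsorted(
            r_ends, edges[:-1], side="right"
        )
        bin_lengths = edges[1:] - edges[:-1]
        values = counts / (bin_lengths / 1000.0) / depth_factor
        # run-length compress equal adjacent values
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[start]:
                if values[start] != 0.0:
                    steps.append((chrom, int(edges[start]), int(edges[i]), float(values[start])))
                start = i
    return CoverageTrack(steps, chrom_sizes=chrom_sizes)
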