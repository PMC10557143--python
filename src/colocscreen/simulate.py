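"""Seeded generator of a toy genome with exactly planted overlap structure.

This is the statistical stand-in for the real inputs of a co-localization
screen: many transcription-factor (TF) peak sets with heterogeneous,
mutually correlated overlap fractions against two "structure" peak sets
(R-loop and G-quadruplex loci), structure peaks enriched in strand-aware
promoter windows, and coverage tracks with localized enrichment at peak
centers and at promoters versus gene bodies.

Planting is by *exact counts* (``round(n * fraction)``), not per-peak
Bernoulli draws, and placement maintains exclusion masks so that background
peaks can never accidentally overlap a structure: every planted count is an
exact ground truth.  The generator re-derives every planted quantity from
the finished peak sets with the package's own interval engine before
returning, and records everything in a ledger.  One integer seed fixes
every byte of every emitted file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as gio
from .annotation import PromoterWindow, promoter_fraction, promoter_regions
from .intervals import IntervalIndex, intersect_report_a, three_way_cooccupancy
from .profiles import aggregate_profile, peak_center
from .screen import pearson_r
from .types import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    PipelineUsageError,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "make_genome",
    "make_genes",
    "make_structure_peaks",
    "make_tf_sets",
    "make_bump_track",
    "make_region_track",
    "generate_scenario",
    "write_scenario",
]

# ---------------------------------------------------------------------------
# segment algebra (sorted, disjoint [start, end) arrays per chromosome)

Segments = dict[str, np.ndarray]  # chrom -> (k, 2) int64 array


def _merge(intervals) -> Segments:
    per: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: Segments = {}
    for chrom in sorted(per):
        spans = sorted(per[chrom])
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _complement(segs: Segments, bounds: Mapping[str, tuple[int, int]]) -> Segments:
    out: Segments = {}
    for chrom in sorted(bounds):
        lo, hi = bounds[chrom]
        gaps: list[tuple[int, int]] = []
        pos = lo
        for s, e in segs.get(chrom, np.empty((0, 2), dtype=np.int64)):
            s, e = int(s), int(e)
            if s > pos:
                gaps.append((pos, min(s, hi)))
            pos = max(pos, e)
            if pos >= hi:
                break
        if pos < hi:
            gaps.append((pos, hi))
        out[chrom] = np.array([g for g in gaps if g[0] < g[1]], dtype=np.int64).reshape(-1, 2)
    return out


def _intersect(a: Segments, b: Segments) -> Segments:
    out: Segments = {}
    for chrom in sorted(set(a) & set(b)):
        res: list[tuple[int, int]] = []
        i = j = 0
        sa, sb = a[chrom], b[chrom]
        while i < len(sa) and j < len(sb):
            lo = max(sa[i, 0], sb[j, 0])
            hi = min(sa[i, 1], sb[j, 1])
            if lo < hi:
                res.append((int(lo), int(hi)))
            if sa[i, 1] <= sb[j, 1]:
                i += 1
            else:
                j += 1
        out[chrom] = np.array(res, dtype=np.int64).reshape(-1, 2)
    return out


def _subtract(a: Segments, b: Segments) -> Segments:
    bounds = {c: (0, int(2**62)) for c in a}
    return _intersect(a, _complement(b, bounds))


def _union(a: Segments, b: Segments) -> Segments:
    ivs = []
    for segs in (a, b):
        for chrom, arr in segs.items():
            for s, e in arr:
                ivs.append(GenomicInterval(chrom, int(s), int(e)))
    return _merge(ivs)


def _place_fully_inside(
    segs: Segments, width: int, count: int, rng: np.random.Generator, what: str
) -> list[tuple[str, int]]:
    """Uniformly draw ``count`` start positions of ``width``-long spans fully
    contained in the given segments (position-uniform across all segments)."""
    if count == 0:
        return []
    chroms: list[str] = []
    starts: list[int] = []
    weights: list[int] = []
    for chrom in sorted(segs):
        for s, e in segs[chrom]:
            w = int(e) - int(s) - width + 1
            if w > 0:
                chroms.append(chrom)
                starts.append(int(s))
                weights.append(w)
    if not weights:
        raise PipelineUsageError(
            f"infeasible placement: no segment can hold a {width} bp span ({what})"
        )
    cum = np.cumsum(np.array(weights, dtype=np.int64))
    total = int(cum[-1])
    t = rng.integers(0, total, size=count)
    seg_idx = np.searchsorted(cum, t, side="right")
    offset = t - np.where(seg_idx > 0, cum[seg_idx - 1], 0)
    return [(chroms[i], starts[i] + int(o)) for i, o in zip(seg_idx, offset)]


# ---------------------------------------------------------------------------
# generator configuration

EDGE_MARGIN = 4000  # keep placements this far from chromosome ends


@dataclass(frozen=True)
class ScenarioConfig:
    """Default study conditions for one synthetic scenario.

    The defaults emulate a screen of 50 proteins with 500 peaks each against
    two structure peak sets of 1,000 peaks, 70% of which sit in promoter
    windows, with the per-protein G4 overlap fraction linearly related to
    the R-loop fraction (slope 0.8, intercept 0.05, Gaussian noise sd 0.05).
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 500
    gene_len_range: tuple[int, int] = (4000, 8000)
    gene_spacing: int = 2500
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    n_structure: int = 1000
    structure_promoter_frac: float = 0.7
    structure_width_median: int = 300
    structure_width_sigma: float = 0.25
    cooccur_rho: float = 0.5
    n_proteins: int = 50
    n_peaks_per_protein: int = 500
    tf_peak_width: int = 150
    relation_slope: float = 0.8
    relation_intercept: float = 0.05
    relation_noise_sd: float = 0.05
    frac_rloop_range: tuple[float, float] = (0.05, 0.9)
    window: int = 2000
    bin_size: int = 50
    bump_amplitude: float = 10.0
    bump_sigma: float = 150.0
    background: float = 2.0
    noise_sd: float = 1.0
    promoter_level: float = 3.0
    body_level: float = 1.0


@dataclass
class Scenario:
    """One generated scenario plus its ground-truth ledger."""

    seed: int
    config: ScenarioConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    promoters: list[PromoterWindow]
    rloop: list[Peak]
    g4: list[Peak]
    tf_sets: dict[str, list[Peak]]
    signal_track: CoverageTrack
    signal_noiseless: CoverageTrack
    rnapii_track: CoverageTrack
    anchors: list[tuple[str, int]]
    ledger: dict


# ---------------------------------------------------------------------------
# building blocks


def make_genome(n_chroms: int, chrom_length: int) -> dict[str, int]:
    """Deterministic toy genome: chromosomes chrS1..chrSn of equal length."""
    if n_chroms < 1:
        raise PipelineUsageError("need at least one chromosome")
    if chrom_length < 100_000:
        raise PipelineUsageError("chromosomes must be at least 100 kb")
    return {f"chrS{i + 1}": int(chrom_length) for i in range(n_chroms)}


def make_genes(
    chrom_sizes: Mapping[str, int],
    n: int,
    len_range: tuple[int, int],
    rng: np.random.Generator,
    spacing: int = 2500,
    margin: int = 6000,
) -> list[GeneModel]:
    """n non-overlapping genes (separated by >= spacing), uniform lengths,
    fair-coin strands, placed by rejection sampling; sorted by coordinate."""
    lo, hi = len_range
    total_len = n * hi
    genome = sum(chrom_sizes.values())
    if total_len > 0.5 * genome:
        raise PipelineUsageError(
            f"infeasible gene density: {total_len} bp of genes in {genome} bp genome"
        )
    chroms = sorted(chrom_sizes)
    chrom_weights = np.array(
        [max(chrom_sizes[c] - 2 * margin, 0) for c in chroms], dtype=np.float64
    )
    if chrom_weights.sum() <= 0:
        raise PipelineUsageError("chromosomes too short for the placement margin")
    chrom_weights /= chrom_weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placed: list[tuple[str, int, int, str]] = []
    attempts = 0
    max_attempts = max(1000, 200 * n)
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PipelineUsageError(
                f"gene placement failed after {max_attempts} attempts"
            )
        ci = int(rng.choice(len(chroms), p=chrom_weights))
        chrom = chroms[ci]
        glen = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(margin, chrom_sizes[chrom] - margin - glen + 1))
        end = start + glen
        clash = any(
            start - spacing < e and s < end + spacing for s, e in occupied[chrom]
        )
        if clash:
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append((chrom, start, end, strand))
    placed.sort(key=lambda t: (t[0], t[1]))
    return [
        GeneModel(chrom, s, e, strand, f"g{i + 1:04d}")
        for i, (chrom, s, e, strand) in enumerate(placed)
    ]


def _draw_widths(
    n: int, median: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Discretized lognormal widths, rounded to 10 bp, clipped to [60, 600]."""
    raw = median * np.exp(sigma * rng.standard_normal(n))
    return np.clip(np.round(raw / 10) * 10, 60, 600).astype(np.int64)


def _assemble_peaks(
    spans: list[tuple[str, int, int]], prefix: str, rng: np.random.Generator
) -> list[Peak]:
    spans = sorted(spans)
    peaks = []
    scores = np.round(rng.uniform(100, 1000, size=len(spans)), 1)
    for i, (chrom, start, end) in enumerate(spans):
        w = end - start
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                name=f"{prefix}_{i + 1:05d}",
                score=float(scores[i]),
                summit_offset=w // 2,
            )
        )
    return peaks


def make_structure_peaks(
    promoters: Sequence[PromoterWindow],
    chrom_sizes: Mapping[str, int],
    n: int,
    promoter_frac: float,
    rng: np.random.Generator,
    width_median: int = 300,
    width_sigma: float = 0.25,
    cooccur_with: Sequence[Peak] | None = None,
    rho: float = 0.0,
    name_prefix: str = "peak",
) -> tuple[list[Peak], dict]:
    """Structure peaks enriched in promoter windows, optionally co-occurring
    with an existing target set.

    ``round(n * rho)`` peaks (when a target set is given) are centered inside
    a randomly chosen target peak, guaranteeing overlap; of the remainder,
    ``round(m * promoter_frac)`` are placed fully inside promoter windows
    (minus any target overlap, so co-occurrence stays exact) and the rest
    fully inside space free of promoters and targets.  Without a target set
    the realized promoter fraction is therefore exactly the planted one.
    """
    if not (0 <= promoter_frac <= 1 and 0 <= rho <= 1):
        raise PipelineUsageError("promoter_frac and rho must be in [0, 1]")
    prom_segs = _merge(w.interval for w in promoters)
    bounds = {c: (EDGE_MARGIN, chrom_sizes[c] - EDGE_MARGIN) for c in sorted(chrom_sizes)}

    spans: list[tuple[str, int, int]] = []
    n_co = int(round(n * rho)) if cooccur_with else 0
    if n_co:
        widths = _draw_widths(n_co, width_median, width_sigma, rng)
        target_idx = rng.integers(0, len(cooccur_with), size=n_co)
        for w, ti in zip(widths, target_idx):
            t = cooccur_with[int(ti)]
            center = int(rng.integers(t.start, t.end))
            start = center - int(w) // 2
            spans.append((t.chrom, start, start + int(w)))

    if cooccur_with:
        target_union = _merge(p.interval for p in cooccur_with)
        prom_place = _subtract(prom_segs, target_union)
        blocked = _union(prom_segs, target_union)
    else:
        prom_place = prom_segs
        blocked = prom_segs
    free_place = _complement(blocked, bounds)

    n_prom = int(round((n - n_co) * promoter_frac))
    n_free = n - n_co - n_prom
    for group_n, group_segs, what in (
        (n_prom, prom_place, f"{name_prefix} promoter placement"),
        (n_free, free_place, f"{name_prefix} background placement"),
    ):
        if group_n == 0:
            continue
        widths = _draw_widths(group_n, width_median, width_sigma, rng)
        for w in np.sort(np.unique(widths)):
            k = int(np.sum(widths == w))
            for chrom, start in _place_fully_inside(group_segs, int(w), k, rng, what):
                spans.append((chrom, start, start + int(w)))

    peaks = _assemble_peaks(spans, name_prefix, rng)
    info = {
        "n": n,
        "n_promoter_planted": n_prom,
        "n_cooccur_planted": n_co,
        "promoter_fraction_exact": cooccur_with is None,
    }
    return peaks, info


def make_tf_sets(
    rloop: Sequence[Peak],
    g4: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    n_proteins: int,
    n_peaks: int,
    rng: np.random.Generator,
    slope: float = 0.8,
    intercept: float = 0.05,
    noise_sd: float = 0.05,
    frac_range: tuple[float, float] = (0.05, 0.9),
    tf_width: int = 150,
) -> tuple[dict[str, list[Peak]], dict]:
    """TF peak sets with exactly planted overlap counts against both
    structure sets.

    Per protein i, the target R-loop overlap fraction is drawn uniformly
    from ``frac_range`` and the G4 fraction is
    ``clamp(slope * f_R + intercept + Normal(0, noise_sd), 0, 1)``.  Exact
    counts ``round(n_peaks * f)`` are realized by placing peaks fully inside
    a four-way decomposition of the genome (R-and-G, R-only, G-only,
    neither), so the screen must recover the planted counts exactly.
    """
    if n_peaks < 20:
        raise PipelineUsageError("need at least 20 peaks per protein")
    union_r = _merge(p.interval for p in rloop)
    union_g = _merge(p.interval for p in g4)
    seg_both = _intersect(union_r, union_g)
    seg_r_only = _subtract(union_r, union_g)
    seg_g_only = _subtract(union_g, union_r)
    bounds = {c: (EDGE_MARGIN, chrom_sizes[c] - EDGE_MARGIN) for c in sorted(chrom_sizes)}
    seg_neither = _complement(_union(union_r, union_g), bounds)

    tf_sets: dict[str, list[Peak]] = {}
    per_protein: dict[str, dict] = {}
    for i in range(n_proteins):
        protein = f"TF{i + 1:03d}"
        f_r = float(rng.uniform(*frac_range))
        f_g = float(np.clip(slope * f_r + intercept + rng.normal(0, noise_sd), 0, 1))
        n_r = int(round(n_peaks * f_r))
        n_g = int(round(n_peaks * f_g))
        n_b = int(round(n_peaks * f_r * f_g))
        n_b = max(n_b, n_r + n_g - n_peaks, 0)
        n_b = min(n_b, n_r, n_g)
        groups = (
            (n_b, seg_both, f"{protein} R+G4 placement"),
            (n_r - n_b, seg_r_only, f"{protein} R-only placement"),
            (n_g - n_b, seg_g_only, f"{protein} G4-only placement"),
            (n_peaks - n_r - n_g + n_b, seg_neither, f"{protein} background"),
        )
        spans: list[tuple[str, int, int]] = []
        for group_n, segs, what in groups:
            for chrom, start in _place_fully_inside(segs, tf_width, group_n, rng, what):
                spans.append((chrom, start, start + tf_width))
        tf_sets[protein] = _assemble_peaks(spans, protein, rng)
        per_protein[protein] = {
            "n_peaks": n_peaks,
            "n_rloop": n_r,
            "n_g4": n_g,
            "n_both": n_b,
            "f_rloop_target": f_r,
            "f_g4_target": f_g,
            "f_g4_noiseless": slope * f_r + intercept,
        }
    return tf_sets, per_protein


def make_bump_track(
    anchors: Sequence[tuple[str, int]],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    amplitude: float = 10.0,
    sigma: float = 150.0,
    background: float = 2.0,
    noise_sd: float = 1.0,
    bin_size: int = 50,
    window: int = 2000,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Coverage with Gaussian bumps at anchor centers over a flat background.

    The track is discretized to ``bin_size`` bins; each bin takes the bump
    value at its midpoint, summed over all anchors within ``window``.
    Truncated-Gaussian noise (clipped at 0) is added when ``noise_sd > 0``.
    Returns (noisy track, exact noiseless track) — the noiseless track is
    the ground truth for aggregation-profile recovery.
    """
    if amplitude < 0 or background < 0 or bin_size < 1:
        raise PipelineUsageError("amplitude, background >= 0 and bin_size >= 1 required")
    fields: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        n_bins = math.ceil(chrom_sizes[chrom] / bin_size)
        fields[chrom] = np.full(n_bins, background, dtype=np.float64)
    two_sig2 = 2.0 * sigma * sigma
    for chrom, center in anchors:
        arr = fields[chrom]
        i0 = max(0, (center - window) // bin_size)
        i1 = min(len(arr), -((center + window) // -bin_size))
        mids = (np.arange(i0, i1, dtype=np.float64) + 0.5) * bin_size
        arr[i0:i1] += amplitude * np.exp(-((mids - center) ** 2) / two_sig2)

    def to_track(per_chrom: dict[str, np.ndarray]) -> CoverageTrack:
        steps: list[tuple[str, int, int, float]] = []
        for chrom in sorted(per_chrom):
            vals = per_chrom[chrom]
            length = chrom_sizes[chrom]
            run_start = 0
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != vals[run_start]:
                    if vals[run_start] != 0.0:
                        steps.append(
                            (
                                chrom,
                                run_start * bin_size,
                                min(i * bin_size, length),
                                float(vals[run_start]),
                            )
                        )
                    run_start = i
        return CoverageTrack(steps, chrom_sizes=chrom_sizes)

    noiseless = to_track(fields)
    if noise_sd > 0:
        noisy_fields = {
            chrom: np.maximum(
                vals + rng.normal(0.0, noise_sd, size=len(vals)), 0.0
            )
            for chrom, vals in sorted(fields.items())
        }
        return to_track(noisy_fields), noiseless
    return noiseless, noiseless


def make_region_track(
    promoters: Sequence[PromoterWindow],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    promoter_level: float = 3.0,
    body_level: float = 1.0,
    background: float = 0.0,
) -> CoverageTrack:
    """Plateau coverage: one level over merged promoter windows, another over
    gene bodies minus promoter overlap, optional background elsewhere.

    Emitted as an exact step function cut at region boundaries, so planted
    promoter:body ratios are exact ground truth for metagene and density
    recovery.
    """
    prom_segs = _merge(w.interval for w in promoters)
    body_segs = _subtract(_merge(g.interval for g in genes), prom_segs)
    steps: list[tuple[str, int, int, float]] = []
    for segs, level in ((prom_segs, promoter_level), (body_segs, body_level)):
        if level == 0:
            continue
        for chrom in sorted(segs):
            for s, e in segs[chrom]:
                steps.append((chrom, int(s), int(e), float(level)))
    if background > 0:
        covered = _union(prom_segs, body_segs)
        rest = _complement(covered, {c: (0, chrom_sizes[c]) for c in sorted(chrom_sizes)})
        for chrom in sorted(rest):
            for s, e in rest[chrom]:
                steps.append((chrom, int(s), int(e), float(background)))
    return CoverageTrack(steps, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# the full scenario


def generate_scenario(seed: int, config: ScenarioConfig | None = None) -> Scenario:
    """Generate one complete scenario and self-verify every planted quantity.

    The ledger records the exact planted counts and the truth curves; the
    generator re-derives each planted count from the finished peak sets with
    the interval engine and raises if anything disagrees.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    chrom_sizes = make_genome(cfg.n_chroms, cfg.chrom_length)
    genes = make_genes(
        chrom_sizes, cfg.n_genes, cfg.gene_len_range, rng, spacing=cfg.gene_spacing
    )
    promoters = promoter_regions(
        genes, cfg.promoter_upstream, cfg.promoter_downstream, chrom_sizes
    )
    rloop, rloop_info = make_structure_peaks(
        promoters,
        chrom_sizes,
        cfg.n_structure,
        cfg.structure_promoter_frac,
        rng,
        width_median=cfg.structure_width_median,
        width_sigma=cfg.structure_width_sigma,
        name_prefix="rloop",
    )
    g4, g4_info = make_structure_peaks(
        promoters,
        chrom_sizes,
        cfg.n_structure,
        cfg.structure_promoter_frac,
        rng,
        width_median=cfg.structure_width_median,
        width_sigma=cfg.structure_width_sigma,
        cooccur_with=rloop,
        rho=cfg.cooccur_rho,
        name_prefix="g4",
    )
    tf_sets, tf_ledger = make_tf_sets(
        rloop,
        g4,
        chrom_sizes,
        cfg.n_proteins,
        cfg.n_peaks_per_protein,
        rng,
        slope=cfg.relation_slope,
        intercept=cfg.relation_intercept,
        noise_sd=cfg.relation_noise_sd,
        frac_range=cfg.frac_rloop_range,
        tf_width=cfg.tf_peak_width,
    )

    anchors = [(p.chrom, peak_center(p)) for p in rloop]
    signal_track, signal_noiseless = make_bump_track(
        anchors,
        chrom_sizes,
        rng,
        amplitude=cfg.bump_amplitude,
        sigma=cfg.bump_sigma,
        background=cfg.background,
        noise_sd=cfg.noise_sd,
        bin_size=cfg.bin_size,
        window=cfg.window,
    )
    rnapii_track = make_region_track(
        promoters,
        genes,
        chrom_sizes,
        promoter_level=cfg.promoter_level,
        body_level=cfg.body_level,
    )

    # --- self-verification against the interval engine -------------------
    r_index = IntervalIndex.from_peaks(rloop)
    g_index = IntervalIndex.from_peaks(g4)
    for protein, planted in tf_ledger.items():
        co = three_way_cooccupancy(tf_sets[protein], r_index, g_index)
        if (co.n_rloop, co.n_g4, co.n_both) != (
            planted["n_rloop"],
            planted["n_g4"],
            planted["n_both"],
        ):
            raise RuntimeError(
                f"generator self-check failed for {protein}: realized "
                f"({co.n_rloop},{co.n_g4},{co.n_both}) != planted "
                f"({planted['n_rloop']},{planted['n_g4']},{planted['n_both']})"
            )
    realized_prom_frac = promoter_fraction(rloop, promoters)
    expected_prom_frac = 100.0 * rloop_info["n_promoter_planted"] / cfg.n_structure
    if realized_prom_frac != expected_prom_frac:
        raise RuntimeError(
            f"generator self-check failed: rloop promoter fraction "
            f"{realized_prom_frac} != planted {expected_prom_frac}"
        )
    n_cooccur_realized = len(intersect_report_a(g4, r_index))
    if n_cooccur_realized != g4_info["n_cooccur_planted"]:
        raise RuntimeError(
            f"generator self-check failed: g4 co-occurrence "
            f"{n_cooccur_realized} != planted {g4_info['n_cooccur_planted']}"
        )

    proteins = sorted(tf_ledger)
    pct_r = [100.0 * tf_ledger[p]["n_rloop"] / cfg.n_peaks_per_protein for p in proteins]
    pct_g = [100.0 * tf_ledger[p]["n_g4"] / cfg.n_peaks_per_protein for p in proteins]
    realized_r = pearson_r(pct_g, pct_r) if len(proteins) >= 3 else None

    truth_profile = aggregate_profile(
        signal_noiseless, anchors, cfg.window, cfg.bin_size, chrom_sizes
    )
    if truth_profile.n_dropped:
        raise RuntimeError("generator placed anchors too close to chromosome ends")

    ledger = {
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "structure": {
            "rloop": {
                **rloop_info,
                "promoter_fraction_pct": realized_prom_frac,
            },
            "g4": {**g4_info, "n_cooccur_realized": n_cooccur_realized},
        },
        "proteins": tf_ledger,
        "realized_pearson_r": realized_r,
        "coverage": {
            "n_anchors": len(anchors),
            "window": cfg.window,
            "bin_size": cfg.bin_size,
            "truth_mean_curve": truth_profile.mean_curve.tolist(),
        },
        "regions": {
            "promoter_level": cfg.promoter_level,
            "body_level": cfg.body_level,
            "expected_ratio": cfg.promoter_level / cfg.body_level,
        },
    }
    return Scenario(
        seed=seed,
        config=cfg,
        chrom_sizes=chrom_sizes,
        genes=genes,
        promoters=promoters,
        rloop=rloop,
        g4=g4,
        tf_sets=tf_sets,
        signal_track=signal_track,
        signal_noiseless=signal_noiseless,
        rnapii_track=rnapii_track,
        anchors=anchors,
        ledger=ledger,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> Path:
    """Write every scenario file (valid inputs for the io module) plus the
    ground-truth ledger.  Same seed => byte-identical tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"colocscreen simulate seed={scenario.seed}"]
    gio.write_chrom_sizes(outdir / "chrom.sizes", scenario.chrom_sizes, header=header)
    gio.write_gene_models(outdir / "genes.bed", scenario.genes, header=header)
    gio.write_peaks(outdir / "rloop.narrowPeak", scenario.rloop, "narrowPeak", header)
    gio.write_peaks(outdir / "g4.narrowPeak", scenario.g4, "narrowPeak", header)
    tf_dir = outdir / "tf"
    tf_dir.mkdir(exist_ok=True)
    for protein in sorted(scenario.tf_sets):
        gio.write_peaks(
            tf_dir / f"{protein}.narrowPeak", scenario.tf_sets[protein], "narrowPeak", header
        )
    gio.write_bedgraph(outdir / "signal.bedgraph", scenario.signal_track, header)
    gio.write_bedgraph(outdir / "rnapii.bedgraph", scenario.rnapii_track, header)
    with open(outdir / "ledger.json", "wt", encoding="utf-8") as fh:
        json.dump(scenario.ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
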