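"""End-to-end orchestration: simulate -> screen -> annotate -> profile ->
metagene -> density, with every stage result checked against the generator's
ground-truth ledger, plus a report-only input validator.

Every stage is a pure function of (inputs, config, seed): repeated runs with
the same seed produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as gio
from .annotation import promoter_fraction, promoter_regions
from .profiles import aggregate_profile, metagene_profile, peak_center, region_density
from .screen import run_screen, write_screen_table
from .simulate import Scenario, ScenarioConfig, _merge, _subtract, generate_scenario, write_scenario
from .types import GenomicInterval, ParseError, PipelineUsageError

logger = logging.getLogger(__name__)

__all__ = ["run_end_to_end", "validate_inputs", "LedgerCheck"]


@dataclasses.dataclass(frozen=True)
class LedgerCheck:
    name: str
    expected: float
    observed: float
    tolerance: float
    passed: bool


def _check(name: str, expected: float, observed: float, tolerance: float) -> LedgerCheck:
    return LedgerCheck(
        name=name,
        expected=expected,
        observed=observed,
        tolerance=tolerance,
        passed=abs(observed - expected) <= tolerance,
    )


def run_end_to_end(
    outdir: str | Path, seed: int, config: ScenarioConfig | None = None
) -> tuple[list[LedgerCheck], int]:
    """Generate a scenario, re-read every emitted file, run every analysis
    stage, and compare each result with the ledger truth.

    Returns (checks, exit_code); exit code is 0 iff every check passed its
    tolerance, else 3.  Stage outputs and ``report.tsv`` land in ``outdir``.
    """
    outdir = Path(outdir)
    cfg = config or ScenarioConfig()
    scenario = generate_scenario(seed, cfg)
    data_dir = write_scenario(scenario, outdir / "data")

    # Re-read everything through the io layer so the files themselves are
    # what gets analyzed, not the in-memory objects.
    chrom_sizes = gio.read_chrom_sizes(data_dir / "chrom.sizes")
    genes = gio.read_gene_models(data_dir / "genes.bed")
    rloop = gio.read_peaks(data_dir / "rloop.narrowPeak", "narrowPeak")
    g4 = gio.read_peaks(data_dir / "g4.narrowPeak", "narrowPeak")
    tf_sets = {
        f.stem: gio.read_peaks(f, "narrowPeak")
        for f in sorted((data_dir / "tf").glob("*.narrowPeak"))
    }
    signal = gio.read_bedgraph(data_dir / "signal.bedgraph", chrom_sizes)
    rnapii = gio.read_bedgraph(data_dir / "rnapii.bedgraph", chrom_sizes)
    ledger = scenario.ledger

    checks: list[LedgerCheck] = []

    # --- screen -----------------------------------------------------------
    table = run_screen(tf_sets, rloop, g4)
    write_screen_table(outdir / "screen.tsv", table, metadata={"seed": str(seed)})
    max_count_diff = 0
    for rec in table:
        planted = ledger["proteins"][rec.protein]
        max_count_diff = max(
            max_count_diff,
            abs(rec.n_overlap_rloop - planted["n_rloop"]),
            abs(rec.n_overlap_g4 - planted["n_g4"]),
            abs(rec.n_overlap_both - planted["n_both"]),
        )
    checks.append(_check("screen_planted_count_max_abs_diff", 0.0, max_count_diff, 0.0))
    if ledger["realized_pearson_r"] is not None and table.pearson_r is not None:
        checks.append(
            _check(
                "screen_pearson_r_vs_ledger",
                ledger["realized_pearson_r"],
                table.pearson_r,
                1e-12,
            )
        )

    # --- promoter annotation ---------------------------------------------
    promoters = promoter_regions(
        genes, cfg.promoter_upstream, cfg.promoter_downstream, chrom_sizes
    )
    frac = promoter_fraction(rloop, promoters)
    checks.append(
        _check(
            "rloop_promoter_fraction_pct",
            ledger["structure"]["rloop"]["promoter_fraction_pct"],
            frac,
            0.0,
        )
    )
    _write_classes(outdir / "classes.tsv", rloop, promoters, genes)

    # --- aggregation around structure peak centers ------------------------
    anchors = [(p.chrom, peak_center(p)) for p in rloop]
    profile = aggregate_profile(signal, anchors, cfg.window, cfg.bin_size, chrom_sizes)
    truth_curve = np.array(ledger["coverage"]["truth_mean_curve"])
    rms = float(np.sqrt(np.mean((profile.mean_curve - truth_curve) ** 2)))
    rms_tol = (
        3.0 * cfg.noise_sd / math.sqrt(profile.n_anchors) if cfg.noise_sd > 0 else 1e-9
    )
    checks.append(_check("aggregation_rms_vs_truth", 0.0, rms, rms_tol))
    center_bins = {profile.n_bins // 2 - 1, profile.n_bins // 2}
    argmax_ok = int(np.argmax(profile.mean_curve)) in center_bins
    checks.append(_check("aggregation_max_at_center", 1.0, float(argmax_ok), 0.0))
    _write_curve(
        outdir / "profile.tsv",
        profile.bin_offsets,
        profile.mean_curve,
        f"aggregation profile over {profile.n_anchors} anchors",
    )

    # --- metagene ----------------------------------------------------------
    mg = metagene_profile(rnapii, genes, flank=cfg.window, body_bins=100,
                          flank_bin=cfg.bin_size, chrom_sizes=chrom_sizes)
    up, body, _ = mg.split()
    n_prom_bins = cfg.promoter_upstream // mg.flank_bin
    prom_signal = float(np.mean(up[-n_prom_bins:]))
    mid = mg.body_bins // 2
    body_signal = float(np.mean(body[mid - 5 : mid + 5]))
    expected_ratio = ledger["regions"]["expected_ratio"]
    mg_ratio = prom_signal / body_signal
    checks.append(
        _check("metagene_promoter_body_ratio", expected_ratio, mg_ratio, 0.1 * expected_ratio)
    )
    _write_curve(
        outdir / "metagene.tsv",
        np.arange(len(mg.curve)),
        mg.curve,
        f"metagene profile over {mg.n_genes} genes "
        f"({mg.n_flank_bins} flank bins each side, {mg.body_bins} body bins)",
    )

    # --- region densities --------------------------------------------------
    regions = _density_regions(genes, promoters)
    densities = region_density(rnapii, regions, rnapii.total_signal())
    prom_d = [d.density for d in densities if d.region_class == "promoter"]
    body_d = [d.density for d in densities if d.region_class == "body"]
    density_ratio = (sum(prom_d) / len(prom_d)) / (sum(body_d) / len(body_d))
    checks.append(
        _check(
            "density_promoter_body_ratio",
            expected_ratio,
            density_ratio,
            0.1 * expected_ratio,
        )
    )
    with open(outdir / "density.tsv", "wt", encoding="utf-8") as fh:
        fh.write("region_id\tclass\tdensity\n")
        for d in densities:
            fh.write(f"{d.region_id}\t{d.region_class}\t{d.density!r}\n")

    # --- report ------------------------------------------------------------
    all_passed = all(c.passed for c in checks)
    with open(outdir / "report.tsv", "wt", encoding="utf-8") as fh:
        fh.write(f"# colocscreen run-all seed={seed}\n")
        for key, value in sorted(dataclasses.asdict(cfg).items()):
            fh.write(f"# config.{key}\t{value}\n")
        fh.write("check\texpected\tobserved\ttolerance\tpass\n")
        for c in checks:
            fh.write(
                f"{c.name}\t{c.expected!r}\t{c.observed!r}\t{c.tolerance!r}"
                f"\t{'yes' if c.passed else 'NO'}\n"
            )
    return checks, 0 if all_passed else 3


def _write_classes(path: Path, peaks, promoters, genes) -> None:
    from .annotation import classify_peaks

    classes = classify_peaks(peaks, promoters, genes)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("peak\tclass\tgene_id\n")
        for p, (label, gid) in zip(peaks, classes):
            fh.write(f"{p.name}\t{label}\t{gid}\n")


def _write_curve(path: Path, xs, ys, title: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {title}\n")
        fh.write("bin\tmean_signal\n")
        for x, y in zip(np.asarray(xs).tolist(), np.asarray(ys).tolist()):
            fh.write(f"{x}\t{y!r}\n")


def _density_regions(genes, promoters):
    """Promoter windows plus gene-body-minus-promoter segments, as inputs to
    region_density."""
    regions: list[tuple[str, str, GenomicInterval]] = []
    for w in promoters:
        regions.append((f"prom_{w.gene_id}", "promoter", w.interval))
    body_segs = _subtract(_merge(g.interval for g in genes), _merge(w.interval for w in promoters))
    i = 0
    for chrom in sorted(body_segs):
        for s, e in body_segs[chrom]:
            i += 1
            regions.append((f"body_{i:05d}", "body", GenomicInterval(chrom, int(s), int(e))))
    return regions


# ---------------------------------------------------------------------------
# input validation (report-only)

_FORMAT_READERS = {
    "chrom_sizes": gio.read_chrom_sizes,
    "narrowPeak": lambda p: gio.read_peaks(p, "narrowPeak"),
    "bed6_genes": gio.read_gene_models,
    "bed3": lambda p: gio.read_peaks(p, "bed3"),
    "bedgraph": lambda p: gio.read_bedgraph(p),
}


def _guess_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".sizes") or "chrom.sizes" in name:
        return "chrom_sizes"
    if name.endswith((".narrowpeak", ".narrowpeak.gz")):
        return "narrowPeak"
    if name.endswith((".bedgraph", ".bdg", ".bedgraph.gz")):
        return "bedgraph"
    if name.endswith((".bed", ".bed.gz")):
        return "bed6_genes"
    return "bed3"


def validate_inputs(paths: Sequence[str | Path]) -> dict:
    """Per-file format detection, record counts and chromosome-name audit.

    Never raises on bad data — problems become entries in the returned
    report.  Disjoint chromosome-name sets between files are flagged, with a
    specific warning when the disagreement looks like a 'chr'-prefix
    mismatch (which would silently produce zero overlaps downstream).
    """
    files = []
    chrom_sets: dict[str, set[str]] = {}
    warnings: list[str] = []
    for raw in paths:
        path = Path(raw)
        entry: dict = {"path": str(path), "format": None, "n_records": 0, "ok": False}
        if not path.exists():
            entry["error"] = "file not found"
            files.append(entry)
            continue
        fmt = _guess_format(path)
        entry["format"] = fmt
        try:
            records = _FORMAT_READERS[fmt](path)
        except (ParseError, PipelineUsageError, ValueError) as exc:
            entry["error"] = str(exc)
            files.append(entry)
            continue
        if fmt == "chrom_sizes":
            chroms = set(records)
            n = len(records)
        elif fmt == "bedgraph":
            chroms = set(records.chroms)
            n = records.n_steps()
        elif fmt == "bed6_genes":
            chroms = {g.chrom for g in records}
            n = len(records)
        else:
            chroms = {p.chrom for p in records}
            n = len(records)
        entry["n_records"] = n
        entry["chroms"] = sorted(chroms)
        entry["ok"] = True
        if n == 0:
            warnings.append(f"{path}: zero records")
        chrom_sets[str(path)] = chroms
        files.append(entry)

    names = [k for k in chrom_sets if chrom_sets[k]]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = chrom_sets[names[i]], chrom_sets[names[j]]
            if a and b and not (a & b):
                strip = {c.removeprefix("chr") for c in a} & {
                    c.removeprefix("chr") for c in b
                }
                hint = (
                    " (looks like a 'chr'-prefix mismatch)" if strip else ""
                )
                warnings.append(
                    f"disjoint chromosome names between {names[i]} and {names[j]}{hint}"
                )
    return {"files": files, "warnings": warnings}
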