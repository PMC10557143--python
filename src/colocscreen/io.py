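"""Readers and writers for the plain-text genomic formats the pipeline uses.

Supported dialects: BED3/BED6, ENCODE narrowPeak (10 columns), bedGraph
(4 columns) and two-column chrom.sizes files.  All files are tab-separated
UTF-8; reading is gzip-transparent (``.gz`` suffix).  Lines starting with
``#``, ``track`` or ``browser`` are skipped and counted.  Parsers never
reorder records: sorting is always an explicit separate step.

Chromosome names are matched as exact strings — there is no silent
``chr``-prefix normalisation, because aliasing produces false zero overlaps;
:func:`colocscreen.pipeline.validate_inputs` flags likely prefix mismatches
instead.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from .types import (
    CoverageTrack,
    GeneModel,
    GenomicDataError,
    GenomicInterval,
    ParseError,
    Peak,
    PipelineUsageError,
)

logger = logging.getLogger(__name__)

PEAK_DIALECTS = ("bed3", "bed6", "narrowPeak")

_SKIP_PREFIXES = ("#", "track", "browser")


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for every data line."""
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                n_skipped += 1
                continue
            yield lineno, line.split("\t")
    if n_skipped:
        logger.debug("%s: skipped %d header/comment lines", path, n_skipped)


def _parse_int(text: str, what: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{what} is not an integer: {text!r}", str(path), lineno)


def _parse_float(text: str, what: str, path, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{what} is not a number: {text!r}", str(path), lineno)


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a peak file in the given dialect, in file order.

    bed3 fills ``name="."``, ``score=0``, ``summit_offset=-1``; bed6
    additionally reads name and score; narrowPeak reads all ten columns but
    retains only location, name, score and summit (column 10).  signalValue,
    pValue and qValue are dropped with a debug log — the screen needs only
    location and summit.
    """
    if dialect not in PEAK_DIALECTS:
        raise PipelineUsageError(
            f"unknown peak dialect {dialect!r}; expected one of {PEAK_DIALECTS}"
        )
    min_fields = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[dialect]
    peaks: list[Peak] = []
    for lineno, f in _data_lines(path):
        if len(f) < min_fields:
            raise ParseError(
                f"expected >= {min_fields} fields for {dialect}, got {len(f)}",
                str(path),
                lineno,
            )
        chrom = f[0]
        start = _parse_int(f[1], "start", path, lineno)
        end = _parse_int(f[2], "end", path, lineno)
        try:
            interval = GenomicInterval(chrom, start, end)
        except GenomicDataError as exc:
            raise ParseError(str(exc), str(path), lineno)
        name, score, summit = ".", 0.0, -1
        if dialect in ("bed6", "narrowPeak"):
            name = f[3]
            score = _parse_float(f[4], "score", path, lineno)
        if dialect == "narrowPeak":
            summit = _parse_int(f[9], "summit offset", path, lineno)
            if len(f) >= 10:
                logger.debug(
                    "%s:%d: dropping signalValue/pValue/qValue columns", path, lineno
                )
        try:
            peaks.append(Peak(interval, name=name, score=score, summit_offset=summit))
        except GenomicDataError as exc:
            raise ParseError(str(exc), str(path), lineno)
    return peaks


def write_peaks(
    path: str | Path,
    peaks: Iterable[Peak],
    dialect: str = "narrowPeak",
    header: Iterable[str] = (),
) -> None:
    """Write peaks in the given dialect; ``header`` lines are '#'-prefixed."""
    if dialect not in PEAK_DIALECTS:
        raise PipelineUsageError(f"unknown peak dialect {dialect!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for p in peaks:
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            elif dialect == "bed6":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{_fmt(p.score)}\t.\n")
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{_fmt(p.score)}"
                    f"\t.\t0\t-1\t-1\t{p.summit_offset}\n"
                )


def _fmt(value: float) -> str:
    """Shortest exact decimal form of a float (ints stay ints)."""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file into an ordered mapping."""
    sizes: dict[str, int] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 2:
            raise ParseError("expected 2 tab-separated columns", str(path), lineno)
        chrom = f[0]
        length = _parse_int(f[1], "chromosome length", path, lineno)
        if length <= 0:
            raise ParseError(f"non-positive length {length}", str(path), lineno)
        if chrom in sizes:
            raise ParseError(f"duplicate chromosome {chrom!r}", str(path), lineno)
        sizes[chrom] = length
    return sizes


def write_chrom_sizes(
    path: str | Path, sizes: Mapping[str, int], header: Iterable[str] = ()
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Overlapping input steps are an error (no silent merging); intervals must
    fall inside the chromosome bounds when ``chrom_sizes`` is given.
    """
    steps: list[tuple[str, int, int, float]] = []
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise ParseError("expected 4 bedGraph columns", str(path), lineno)
        chrom = f[0]
        start = _parse_int(f[1], "start", path, lineno)
        end = _parse_int(f[2], "end", path, lineno)
        value = _parse_float(f[3], "value", path, lineno)
        steps.append((chrom, start, end, value))
    try:
        return CoverageTrack(steps, chrom_sizes=chrom_sizes)
    except GenomicDataError as exc:
        raise ParseError(str(exc), str(path))


def write_bedgraph(
    path: str | Path, track: CoverageTrack, header: Iterable[str] = ()
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for chrom, start, end, value in track.iter_steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


# ---------------------------------------------------------------------------
# gene models (BED6)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED6 gene models (columns 4/5/6 = id/score/strand), in file order.

    Strand '.' is an error: TSS-anchored logic requires an orientation.
    """
    genes: list[GeneModel] = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise ParseError("expected 6 BED columns for gene models", str(path), lineno)
        start = _parse_int(f[1], "start", path, lineno)
        end = _parse_int(f[2], "end", path, lineno)
        strand = f[5]
        if strand not in ("+", "-"):
            raise ParseError(
                f"strand must be '+' or '-' (gene {f[3]!r}); strandless gene "
                "models cannot anchor TSS logic",
                str(path),
                lineno,
            )
        try:
            genes.append(GeneModel(f[0], start, end, strand, f[3]))
        except GenomicDataError as exc:
            raise ParseError(str(exc), str(path), lineno)
    return genes


def write_gene_models(
    path: str | Path, genes: Iterable[GeneModel], header: Iterable[str] = ()
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\n")
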