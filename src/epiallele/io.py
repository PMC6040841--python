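"""Readers and writers for the on-disk formats used by the pipeline.

Supported inputs: Bismark cytosine reports (1-based, stranded), bedGraph-style
count tables, BED3/BED6, VCF (positions only), and a per-read CpG call TSV.
Everything is converted to the internal convention on read: 0-based half-open
coordinates, CpG dyads addressed by the plus-strand C, strand counts merged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .core import CpGSiteRecord, GenomicInterval, sort_intervals
from .readlevel import ReadCalls

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_CALL_SYMBOLS = {"M": 1, "U": 0, ".": -1}
_SYMBOL_OF = {1: "M", 0: "U", -1: "."}


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_cytosine_report(path: PathLike, min_depth: int = 10) -> list[CpGSiteRecord]:
    """Read per-CpG counts, merge strands onto the dyad, apply a depth floor.

    Two dialects are auto-detected per file:

    * Bismark cytosine report: ``chrom  pos(1-based)  strand  n_meth  n_unmeth
      [context  trinucleotide]``.  A ``+`` record at 1-based p addresses the
      dyad at 0-based p-1; a ``-`` record at p addresses the dyad at p-2.
    * bedGraph-with-counts: ``chrom  pos(0-based dyad)  n_meth  n_total``
      (already strand-merged).

    Strand merging happens before the ``min_depth`` filter, so depth is the
    combined total of both strands.
    """
    dyads: dict[tuple[str, int], list[int]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        try:
            if len(fields) >= 5 and fields[2] in ("+", "-"):
                chrom, pos_s, strand, meth_s, unmeth_s = fields[:5]
                pos1 = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
                if n_meth < 0 or n_unmeth < 0:
                    raise ParseError(path, lineno, "negative counts")
                dyad = pos1 - 1 if strand == "+" else pos1 - 2
                if dyad < 0:
                    raise ParseError(path, lineno, f"position {pos1} maps before chromosome start")
                n_total = n_meth + n_unmeth
            elif len(fields) == 4:
                chrom, pos_s, meth_s, total_s = fields
                dyad = int(pos_s)
                n_meth = int(meth_s)
                n_total = int(total_s)
                if n_meth < 0 or n_total < 0:
                    raise ParseError(path, lineno, "negative counts")
                if n_meth > n_total:
                    raise ParseError(path, lineno, f"n_meth {n_meth} > n_total {n_total}")
            else:
                raise ParseError(path, lineno, f"unrecognized record with {len(fields)} fields")
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        acc = dyads.setdefault((chrom, dyad), [0, 0])
        acc[0] += n_meth
        acc[1] += n_total
    records = [
        CpGSiteRecord(chrom, pos, meth, total)
        for (chrom, pos), (meth, total) in sorted(dyads.items())
        if total >= min_depth
    ]
    logger.debug("read %d CpG dyads >= depth %d from %s", len(records), min_depth, path)
    return records


def write_cytosine_counts(records: Iterable[CpGSiteRecord], path: PathLike) -> None:
    """Write the 4-column bedGraph-with-counts dialect (0-based dyad)."""
    with open(path, "w") as fh:
        for r in sorted(records):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.n_meth}\t{r.n_total}\n")


def read_read_calls(path: PathLike) -> list[ReadCalls]:
    """Read the per-read call TSV: read_id, chrom, ``pos:call`` tokens.

    Call symbols: ``M`` methylated, ``U`` unmethylated, ``.`` missing.
    Positions must be strictly increasing within a read.
    """
    reads = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 tab-separated fields, got {len(fields)}")
        read_id, chrom, tokens = fields
        positions: list[int] = []
        calls: list[int] = []
        for token in tokens.split(","):
            try:
                pos_s, sym = token.split(":")
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad token {token!r}") from exc
            if sym not in _CALL_SYMBOLS:
                raise ParseError(path, lineno, f"unknown call symbol {sym!r}")
            positions.append(pos)
            calls.append(_CALL_SYMBOLS[sym])
        for prev, nxt in zip(positions, positions[1:]):
            if nxt <= prev:
                raise ParseError(
                    path, lineno, f"positions not strictly increasing ({prev} then {nxt})"
                )
        reads.append(ReadCalls(read_id=read_id, chrom=chrom, positions=positions, calls=calls))
    return reads


def write_read_calls(reads: Iterable[ReadCalls], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            tokens = ",".join(
                f"{p}:{_SYMBOL_OF[int(c)]}" for p, c in zip(r.positions, r.calls)
            )
            fh.write(f"{r.read_id}\t{r.chrom}\t{tokens}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted intervals (column 4 becomes the label)."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED needs at least 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        if start >= end:
            raise ParseError(path, lineno, f"start {start} >= end {end}")
        label = fields[3] if len(fields) >= 4 else None
        intervals.append(GenomicInterval(chrom, start, end, label))
    return sort_intervals(intervals)


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def write_regions(regions: pd.DataFrame, path: PathLike, header_comment: Optional[str] = None) -> None:
    """Write a region table (chrom/start/end plus per-region statistics) as TSV."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        regions.to_csv(fh, sep="\t", index=False)


def read_regions(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_vcf_positions(path: PathLike) -> dict[str, list[int]]:
    """Extract SNP positions from a VCF: CHROM and POS only, genotypes ignored.

    Returns 0-based positions grouped by chromosome, sorted.
    """
    by_chrom: dict[str, list[int]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "VCF record needs CHROM and POS")
        chrom = fields[0]
        try:
            pos1 = int(fields[1])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad POS {fields[1]!r}") from exc
        if pos1 < 1:
            raise ParseError(path, lineno, f"POS must be >= 1, got {pos1}")
        by_chrom.setdefault(chrom, []).append(pos1 - 1)
    return {c: sorted(ps) for c, ps in by_chrom.items()}


def write_vcf_positions(by_chrom: dict[str, list[int]], path: PathLike) -> None:
    """Write a minimal sites-only VCF (positions converted back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in sorted(by_chrom):
            for pos in sorted(by_chrom[chrom]):
                fh.write(f"{chrom}\t{pos + 1}\t.\tN\t.\t.\t.\t.\n")
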