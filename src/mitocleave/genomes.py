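"""Genome and interval primitives.

All coordinates are 0-based half-open (BED convention). The mitochondrial
chromosome is circular: an interval with ``start > end`` wraps through the
origin, and subsequence extraction wraps modulo the chromosome length.
FASTA carries no circularity flag, so circularity is assigned by chromosome
name (default: any name containing "chrM" or equal to "MT").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")

DEFAULT_CIRCULAR_PATTERNS = ("chrM", "MT")


class FastaFormatError(ValueError):
    """Malformed or inconsistent FASTA input."""


class BedFormatError(ValueError):
    """Malformed BED/narrowPeak input."""


class CoordinateError(ValueError):
    """Out-of-range coordinates on a linear chromosome."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single reference chromosome.

    Parameters
    ----------
    name : chromosome identifier (non-empty, unique within a genome set)
    sequence : uppercase DNA over {A,C,G,T,N}
    is_circular : True for the mitochondrial chromosome
    """

    name: str
    sequence: str
    is_circular: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise FastaFormatError("chromosome name must be non-empty")
        if not self.sequence:
            raise FastaFormatError(f"record {self.name!r} has empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FastaFormatError(
                f"record {self.name!r} contains non-IUPAC characters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open.

    ``start > end`` is permitted only to denote wrapping through the origin
    of a circular chromosome, in which case the span is
    ``(L - start) + end`` for chromosome length L.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def span(self, chrom_length: int | None = None) -> int:
        if self.start < self.end:
            return self.end - self.start
        if chrom_length is None:
            raise CoordinateError(
                f"wrapped interval {self.chrom}:{self.start}-{self.end} "
                "requires the chromosome length to compute its span"
            )
        return (chrom_length - self.start) + self.end


def _is_circular(name: str, circular_names: Sequence[str]) -> bool:
    return any(p in name if len(p) > 2 else p == name for p in circular_names)


def read_fasta(
    path: str | Path,
    circular_names: Sequence[str] = DEFAULT_CIRCULAR_PATTERNS,
) -> dict[str, Genome]:
    """Read a (multi-record) FASTA file into a dict of Genome keyed by name.

    Sequences are uppercased. Circularity is assigned by name against
    ``circular_names``: multi-character patterns match as substrings
    (e.g. "chrM" matches "chrM" and "chrM_rCRS"), short ones exactly.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    genomes: dict[str, Genome] = {}
    for rec in records:
        if rec.id in genomes:
            raise FastaFormatError(f"{path}: duplicate record name {rec.id!r}")
        genomes[rec.id] = Genome(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            is_circular=_is_circular(rec.id, circular_names),
        )
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def fetch_subseq(genome: Genome, start: int, end: int, strand: str = "+") -> str:
    """Strand-resolved subsequence; wraps through the origin when circular.

    On a circular chromosome coordinates are taken modulo the length and
    ``start >= end`` denotes a span crossing the origin. Minus strand
    returns the reverse complement of the plus-strand span.
    """
    L = len(genome)
    if genome.is_circular:
        start %= L
        end %= L
        if start < end:
            sub = genome.sequence[start:end]
        else:
            sub = genome.sequence[start:] + genome.sequence[:end]
    else:
        if not (0 <= start < end <= L):
            raise CoordinateError(
                f"{genome.name}:{start}-{end} out of range on linear "
                f"chromosome of length {L}"
            )
        sub = genome.sequence[start:end]
    if strand == "-":
        return reverse_complement(sub)
    return sub


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 (tab-separated, no header) into Intervals.

    Column 5 (score) is used when present; "." means no score.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(Interval(chrom, start, end, strand, score))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write Intervals as BED6; round-trips (chrom,start,end,strand,score)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else repr(iv.score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")


def read_narrowpeak(path: str | Path, score_column: str = "signalValue") -> list[Interval]:
    """Read a narrowPeak file, taking the score from ``signalValue``
    (column 7) or ``score`` (column 5)."""
    if score_column not in ("signalValue", "score"):
        raise ValueError("score_column must be 'signalValue' or 'score'")
    col = 6 if score_column == "signalValue" else 4
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < col + 1:
                raise BedFormatError(
                    f"{path}: line {lineno}: expected ≥{col + 1} columns"
                )
            start, end = int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            out.append(
                Interval(fields[0], start, end, fields[5] if len(fields) > 5 else ".",
                         float(fields[col]))
            )
    return out


def _subject_trees(subjects: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in subjects:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_flags(
    queries: Sequence[Interval],
    subjects: Iterable[Interval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean flag per query: overlaps ≥1 subject by ≥ ``min_overlap`` bp.

    Overlap is computed on half-open intervals (adjacent intervals do not
    overlap), matching ``bedtools intersect -u`` for min_overlap=1.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be ≥ 1")
    trees = _subject_trees(subjects)
    flags = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            if min(q.end, hit.end) - max(q.start, hit.begin) >= min_overlap:
                flags[i] = True
                break
    return flags


def intersect_count(
    queries: Sequence[Interval],
    subjects: Sequence[Interval],
    min_overlap: int = 1,
    distinct: bool = True,
) -> int:
    """Count query/subject overlaps of ≥ ``min_overlap`` bp.

    With ``distinct=True`` each query is counted at most once (the
    ``bedtools intersect -u`` contract); otherwise every overlapping
    (query, subject) pair is counted.
    """
    if distinct:
        return int(overlap_flags(queries, subjects, min_overlap).sum())
    if min_overlap < 1:
        raise ValueError("min_overlap must be ≥ 1")
    trees = _subject_trees(subjects)
    total = 0
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(q.start, q.end):
            if min(q.end, hit.end) - max(q.start, hit.begin) >= min_overlap:
                total += 1
    return total


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Coalesce overlapping or touching intervals per chromosome (strand
    and score are dropped)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged
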