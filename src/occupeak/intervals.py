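"""Genomic interval primitives and BED-family I/O.

All coordinates are 0-based half-open (the BED convention). One-based
inputs (SNP positions) are converted at read time by their own readers.
Chromosome names are compared as exact strings; no "chr" prefix
normalisation is applied implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalCollection",
    "read_bed",
    "write_bed",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional summit and strand.

    ``summit`` is an offset from ``start`` (narrowPeak field 10 semantics);
    ``effective_summit`` falls back to the interval midpoint when absent.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    summit: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length {self.length}"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True iff the two spans share at least ``min_bp`` bases."""
        if min_bp < 1:
            raise ValueError("min_bp must be a positive integer")
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def effective_summit(self) -> int:
        """Genomic position of the summit, or the midpoint when no summit is set."""
        if self.summit is not None:
            return self.start + self.summit
        return self.start + (self.end - self.start) // 2

    @property
    def id(self) -> str:
        """Stable identifier: the name when present, else the coordinate string."""
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"


class IntervalCollection:
    """An ordered, validated list of :class:`GenomicInterval`.

    Normalised on construction: intervals are sorted by (chrom, start, end).
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalCollection):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalCollection({self.label!r}, n={len(self)})"

    # -- indexed queries ---------------------------------------------------

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees

    def overlap_any(self, subject: "IntervalCollection", min_bp: int = 1) -> np.ndarray:
        """Boolean flag per interval: does it overlap >=1 subject interval by >= min_bp?"""
        if min_bp < 1:
            raise ValueError("min_bp must be a positive integer")
        trees = subject._index()
        flags = np.zeros(len(self), dtype=bool)
        for i, iv in enumerate(self.intervals):
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
                    flags[i] = True
                    break
        return flags

    def overlapping(self, iv: GenomicInterval, min_bp: int = 1) -> list[GenomicInterval]:
        """All intervals in this collection overlapping ``iv`` by >= min_bp."""
        tree = self._index().get(iv.chrom)
        if tree is None:
            return []
        hits = [
            h.data
            for h in tree.overlap(iv.start, iv.end)
            if min(iv.end, h.end) - max(iv.start, h.begin) >= min_bp
        ]
        return sorted(hits, key=lambda x: (x.start, x.end))

    def merge(self, max_gap: int = 0) -> "IntervalCollection":
        """Merge intervals separated by <= ``max_gap`` bases.

        Book-ended intervals (gap 0 under half-open coordinates) merge at the
        default ``max_gap=0``, matching the bedtools-merge dialect. Names,
        summits and strands are dropped; merged spans are anonymous regions.
        """
        merged: list[GenomicInterval] = []
        cur_chrom: str | None = None
        cur_start = cur_end = 0
        for iv in self.intervals:
            if iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                if cur_chrom is not None:
                    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
                cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        if cur_chrom is not None:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
        return IntervalCollection(merged, label=self.label)

    def total_bp(self) -> int:
        """Total bases covered, counting overlapped bases once."""
        # book-ended merging does not change the covered-bp total
        return sum(iv.length for iv in self.merge(max_gap=0).intervals)


# -- I/O -------------------------------------------------------------------

_DIALECTS = {"bed3plus", "narrowPeak", "bed12"}


def _parse_line(fields: list[str], dialect: str, lineno: int) -> GenomicInterval:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if start < 0 or start >= end:
        raise ValueError(
            f"line {lineno}: invalid coordinates {chrom}:{start}-{end} (require 0 <= start < end)"
        )
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
    strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else None
    summit: int | None = None
    if dialect == "narrowPeak":
        if len(fields) < 10:
            raise ValueError(f"line {lineno}: narrowPeak requires 10 fields, got {len(fields)}")
        raw = int(fields[9])
        if raw < -1:
            raise ValueError(f"line {lineno}: narrowPeak summit must be -1 or >= 0")
        summit = None if raw == -1 else raw
    return GenomicInterval(chrom, start, end, name=name, summit=summit, strand=strand)


def read_bed(path: str | Path, dialect: str = "bed3plus", label: str | None = None) -> IntervalCollection:
    """Read a BED-family file into a normalised :class:`IntervalCollection`.

    Dialects: ``bed3plus`` (>=3 columns), ``narrowPeak`` (ENCODE 10-column;
    field 10 of -1 maps to "summit absent"), ``bed12`` (span-level view; use
    :func:`occupeak.annotation.read_transcripts_bed12` to retain exon blocks).
    Malformed coordinates are rejected with the offending line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated fields")
            intervals.append(_parse_line(fields, dialect, lineno))
    return IntervalCollection(intervals, label=label if label is not None else path.stem)


def write_bed(collection: IntervalCollection, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write BED; narrowPeak-style summit column is emitted when any summit is set."""
    path = Path(path)
    has_summit = any(iv.summit is not None for iv in collection)
    with path.open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n" if not line.startswith("#") else line + "\n")
        for iv in collection:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.id]
            if has_summit:
                cols += ["0", iv.strand or ".", "0", "-1", "-1",
                         str(iv.summit if iv.summit is not None else -1)]
            fh.write("\t".join(cols) + "\n")
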