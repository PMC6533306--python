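"""Annotation of peaks to genomic elements with fixed upstream distance bins.

Each peak is annotated against every transcript element it touches — a peak
can therefore carry several records (multiple gene annotations). Upstream
bins are measured 5'-ward of the TSS along transcript strand:

* ``TSS-200``   — 1–200 bp upstream (a peak overlapping the TSS base itself
  is folded into this most-proximal bin),
* ``TSS-1500``  — 201–1,500 bp upstream,
* ``TSS-50kb``  — 1,501–50,000 bp upstream,
* ``TTS``       — 1–10,000 bp downstream (3'-ward) of the transcript
  termination site,
* ``exon`` / ``intron`` — overlap with exon spans / the transcript body
  minus exons,
* ``intergenic`` — emitted once for a peak with no other record.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import IntervalCollection

__all__ = [
    "TranscriptModel",
    "AnnotationRecord",
    "CATEGORIES",
    "PRECEDENCE",
    "read_transcripts_bed12",
    "annotate_peaks",
    "distance_to_nearest_tss",
    "category_proportions",
    "peak_primary_categories",
    "write_annotation_tsv",
]

CATEGORIES = ("TSS-200", "TSS-1500", "TSS-50kb", "exon", "intron", "TTS", "intergenic")
# explicit precedence for optional one-category-per-peak summaries
PRECEDENCE = ("TSS-200", "TSS-1500", "exon", "intron", "TTS", "TSS-50kb", "intergenic")


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware transcript: half-open span plus sorted non-overlapping exons."""

    chrom: str
    strand: str  # "+" or "-"
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    transcript_id: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid transcript span {self.tx_start}-{self.tx_end}")
        prev_end = self.tx_start
        for (s, e) in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"exons of {self.transcript_id} must be sorted, non-overlapping "
                    f"and inside the transcript span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        """0-based position of the transcription termination site base."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def introns(self) -> list[tuple[int, int]]:
        spans = []
        prev_end: int | None = None
        for (s, e) in self.exons:
            if prev_end is not None and s > prev_end:
                spans.append((prev_end, s))
            prev_end = e
        return spans


@dataclass(frozen=True)
class AnnotationRecord:
    peak_id: str
    category: str
    transcript_id: str = ""
    gene_id: str = ""
    distance: float = float("nan")  # signed summit-to-TSS distance; NaN for intergenic


def read_transcripts_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a 12-column BED file.

    Column 4 carries the transcript id, optionally ``transcript|gene``.
    """
    models = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: BED12 requires 12 fields, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"line {lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            tid, _, gid = name.partition("|")
            models.append(
                TranscriptModel(
                    chrom=chrom, strand=strand, tx_start=start, tx_end=end,
                    exons=exons, transcript_id=tid, gene_id=gid,
                )
            )
    return models


def _category_windows(t: TranscriptModel) -> list[tuple[str, int, int]]:
    """Genomic half-open windows per category for one transcript, clipped at 0."""
    w: list[tuple[str, int, int]] = []
    tss, tts = t.tss, t.tts
    if t.strand == "+":
        # upstream is genomic-left of the TSS; TSS base folded into TSS-200
        w.append(("TSS-200", max(0, tss - 200), tss + 1))
        w.append(("TSS-1500", max(0, tss - 1500), max(0, tss - 200)))
        w.append(("TSS-50kb", max(0, tss - 50000), max(0, tss - 1500)))
        w.append(("TTS", tts + 1, tts + 1 + 10000))
    else:
        w.append(("TSS-200", tss, tss + 201))
        w.append(("TSS-1500", tss + 201, tss + 1501))
        w.append(("TSS-50kb", tss + 1501, tss + 50001))
        w.append(("TTS", max(0, tts - 10000), tts))
    for (s, e) in t.exons:
        w.append(("exon", s, e))
    for (s, e) in t.introns():
        w.append(("intron", s, e))
    return [(c, s, e) for (c, s, e) in w if s < e]


def annotate_peaks(
    peaks: IntervalCollection, transcripts: Sequence[TranscriptModel]
) -> list[AnnotationRecord]:
    """Annotate every peak against every transcript window it overlaps.

    All matching categories are emitted, with no precedence; a peak touching
    nothing yields a single intergenic record. The ``distance`` field is the
    signed summit-to-TSS distance for the paired transcript (negative when
    the summit lies upstream of that TSS in transcript orientation).
    """
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault(t.chrom, IntervalTree())
        for cat, s, e in _category_windows(t):
            tree.addi(s, e, (cat, t))

    records: list[AnnotationRecord] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        hits: set[tuple[str, str]] = set()
        pairs: list[tuple[str, TranscriptModel]] = []
        if tree is not None:
            for h in sorted(tree.overlap(peak.start, peak.end),
                            key=lambda h: (h.begin, h.end, h.data[0], h.data[1].transcript_id)):
                cat, t = h.data
                if (cat, t.transcript_id) not in hits:
                    hits.add((cat, t.transcript_id))
                    pairs.append((cat, t))
        if not pairs:
            records.append(AnnotationRecord(peak_id=peak.id, category="intergenic"))
            continue
        summit = peak.effective_summit()
        for cat, t in pairs:
            d = summit - t.tss if t.strand == "+" else t.tss - summit
            records.append(
                AnnotationRecord(
                    peak_id=peak.id, category=cat,
                    transcript_id=t.transcript_id, gene_id=t.gene_id,
                    distance=float(d),
                )
            )
    return records


def distance_to_nearest_tss(
    peaks: IntervalCollection, transcripts: Sequence[TranscriptModel]
) -> np.ndarray:
    """Signed distance from each peak's effective summit to the nearest TSS.

    Negative = summit upstream of that TSS in its transcript's orientation,
    positive = downstream, 0 at the TSS base. NaN for peaks on chromosomes
    without any transcript.
    """
    if not transcripts:
        raise ValueError("at least one transcript is required")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    sites = {
        chrom: (
            np.array(sorted(t.tss for t in ts)),
            {t.tss: t.strand for t in ts},
        )
        for chrom, ts in by_chrom.items()
    }
    out = np.full(len(peaks), np.nan)
    for i, peak in enumerate(peaks):
        if peak.chrom not in sites:
            continue
        positions, strand_of = sites[peak.chrom]
        summit = peak.effective_summit()
        j = int(np.searchsorted(positions, summit))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(positions):
                cand = int(positions[k])
                if best is None or abs(summit - cand) < abs(summit - best):
                    best = cand
        assert best is not None
        d = summit - best if strand_of[best] == "+" else best - summit
        out[i] = d
    return out


def category_proportions(records: Sequence[AnnotationRecord]) -> dict[str, float]:
    """Fraction of annotation records per category (sums to 1 over records)."""
    if not records:
        raise ValueError("no annotation records given")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.category] = counts.get(r.category, 0) + 1
    n = len(records)
    return {cat: counts[cat] / n for cat in CATEGORIES if cat in counts}


def peak_primary_categories(records: Sequence[AnnotationRecord]) -> dict[str, str]:
    """One category per peak under the explicit precedence order.

    Offered for figure-style per-peak summaries; the default multi-record
    view has no precedence.
    """
    rank = {c: i for i, c in enumerate(PRECEDENCE)}
    best: dict[str, str] = {}
    for r in records:
        if r.peak_id not in best or rank[r.category] < rank[best[r.peak_id]]:
            best[r.peak_id] = r.category
    return best


def write_annotation_tsv(
    records: Sequence[AnnotationRecord], path: str | Path, header: Sequence[str] = ()
) -> None:
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#peak_id\tcategory\ttranscript_id\tgene_id\tdistance\n")
        for r in records:
            d = "" if np.isnan(r.distance) else f"{int(r.distance)}"
            fh.write(f"{r.peak_id}\t{r.category}\t{r.transcript_id}\t{r.gene_id}\t{d}\n")
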