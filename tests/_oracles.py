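"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (per-bp bitmaps, all-pairs scans,
exact integer enumeration) and shares no code with the library paths it
checks.
"""

from __future__ import annotations

from math import comb

import numpy as np


def brute_overlap_any(query, subject, min_bp: int = 1) -> np.ndarray:
    """All-pairs overlap flags: O(n*m) comparison of every interval pair."""
    flags = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        for s in subject:
            if q.chrom == s.chrom and min(q.end, s.end) - max(q.start, s.start) >= min_bp:
                flags[i] = True
                break
    return flags


def bitmap_covered_bp(intervals, chrom_len: int = 100_000) -> int:
    """Union of covered bases via a per-bp bitmap, one bitmap per chromosome."""
    maps: dict[str, np.ndarray] = {}
    for iv in intervals:
        bm = maps.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        bm[iv.start : iv.end] = True
    return int(sum(bm.sum() for bm in maps.values()))


def bitmap_merged_spans(intervals, chrom_len: int = 100_000) -> list[tuple[str, int, int]]:
    """Maximal runs of covered bases from a per-bp bitmap (merge with gap 0)."""
    maps: dict[str, np.ndarray] = {}
    for iv in intervals:
        bm = maps.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        bm[iv.start : iv.end] = True
    spans = []
    for chrom in sorted(maps):
        bm = maps[chrom]
        padded = np.concatenate(([False], bm, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            spans.append((chrom, int(s), int(e)))
    return spans


def fisher_two_sided_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher p by full enumeration in exact integer arithmetic.

    Fixing both margins, every table is indexed by k = successes in group 1;
    the p-value sums the hypergeometric probabilities of all tables no more
    probable than the observed one. Numerators C(n1,k)*C(n2,K-k) are exact
    integers, so ties are compared without floating-point error.
    """
    K = k1 + k2
    lo, hi = max(0, K - n2), min(n1, K)
    numerators = {k: comb(n1, k) * comb(n2, K - k) for k in range(lo, hi + 1)}
    obs = numerators[k1]
    total = sum(numerators.values())
    return sum(v for v in numerators.values() if v <= obs) / total


def bh_stepup(pvalues) -> np.ndarray:
    """Hand-applied Benjamini-Hochberg step-up."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def paint_annotation_bitmap(transcript, chrom_len: int) -> dict[str, np.ndarray]:
    """Per-category boolean masks for one transcript, painted base by base.

    Uses only the published bin definitions (1-200 / 201-1500 / 1501-50000 bp
    upstream, 1-10000 bp downstream of the termination site, exon spans,
    transcript-minus-exon spans), walking upstream base offsets explicitly.
    """
    masks = {c: np.zeros(chrom_len, dtype=bool) for c in
             ("TSS-200", "TSS-1500", "TSS-50kb", "TTS", "exon", "intron")}
    if transcript.strand == "+":
        tss, tts, step = transcript.tx_start, transcript.tx_end - 1, -1
    else:
        tss, tts, step = transcript.tx_end - 1, transcript.tx_start, +1
    for d in range(0, 50_001):  # upstream offsets; 0 = the TSS base itself
        pos = tss + step * d
        if not (0 <= pos < chrom_len):
            continue
        if d <= 200:
            masks["TSS-200"][pos] = True
        elif d <= 1500:
            masks["TSS-1500"][pos] = True
        else:
            masks["TSS-50kb"][pos] = True
    for d in range(1, 10_001):  # downstream of the termination site
        pos = tts - step * d
        if 0 <= pos < chrom_len:
            masks["TTS"][pos] = True
    body = np.zeros(chrom_len, dtype=bool)
    body[transcript.tx_start : transcript.tx_end] = True
    exonic = np.zeros(chrom_len, dtype=bool)
    for s, e in transcript.exons:
        exonic[s:e] = True
    masks["exon"] = exonic
    masks["intron"] = body & ~exonic
    return masks
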