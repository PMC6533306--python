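"""Feature-set overlap enrichment against a fixed chance null, enhancer
classification from histone marks, and SNP-in-peak overlap with LD/MAF filters.

The enrichment null is deliberately simple: a fixed fraction (default 5%) of
peaks is expected to overlap any feature set by chance, and the observed
overlap count is tested with a one-degree-of-freedom Pearson goodness-of-fit
chi-square (no continuity correction). This declared null ignores the
feature's genomic footprint — it is a modelling choice, exposed as the
``chance_fraction`` parameter. Permutation-based genomic nulls are a
deliberate non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .consensus import bh_fdr
from .intervals import GenomicInterval, IntervalCollection

__all__ = [
    "FeatureSet",
    "EnrichmentResult",
    "SNPRecord",
    "SnpOverlapResult",
    "chance_overlap_test",
    "enrichment_batch",
    "classify_enhancer_state",
    "snp_in_peak",
    "dmr_overlap",
    "partition_by_overlap",
    "read_snp_table",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named collection of intervals (histone mark, regulatory class, TF
    peaks, enhancers, DMRs) used as the subject of overlap queries."""

    name: str
    intervals: IntervalCollection

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            raise ValueError(f"feature set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    feature: str
    n_peaks: int
    n_overlap: int
    expected: float
    chi2: float
    p: float
    direction: str  # "enriched" / "depleted"
    q: float = float("nan")  # filled by enrichment_batch


def chance_overlap_test(
    peaks: IntervalCollection, feature: FeatureSet, chance_fraction: float = 0.05
) -> EnrichmentResult:
    """Goodness-of-fit chi-square of the observed overlap count against a
    fixed chance fraction of all peaks.

    Statistic: sum over the two cells (overlap / no overlap) of
    (observed - expected)^2 / expected; p is the upper tail of chi2 with
    1 df. Direction is "enriched" when observed exceeds expectation.
    """
    if not (0 < chance_fraction < 1):
        raise ValueError("chance_fraction must lie strictly between 0 and 1")
    n_peaks = len(peaks)
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    n_overlap = int(peaks.overlap_any(feature.intervals).sum())
    expected = chance_fraction * n_peaks
    expected_out = (1 - chance_fraction) * n_peaks
    stat = (n_overlap - expected) ** 2 / expected + (
        (n_peaks - n_overlap) - expected_out
    ) ** 2 / expected_out
    p = float(chi2.sf(stat, df=1))
    direction = "enriched" if n_overlap > expected else "depleted"
    return EnrichmentResult(
        feature=feature.name,
        n_peaks=n_peaks,
        n_overlap=n_overlap,
        expected=expected,
        chi2=float(stat),
        p=p,
        direction=direction,
    )


def enrichment_batch(
    peaks: IntervalCollection,
    features: Sequence[FeatureSet],
    chance_fraction: float = 0.05,
) -> list[EnrichmentResult]:
    """Run :func:`chance_overlap_test` for each feature and BH-adjust across them."""
    results = [chance_overlap_test(peaks, f, chance_fraction) for f in features]
    qvals = bh_fdr([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def classify_enhancer_state(
    peaks: IntervalCollection, h3k4me1: FeatureSet, h3k27ac: FeatureSet
) -> list[str]:
    """Per-peak enhancer state from histone marks.

    Both H3K4me1 and H3K27ac present = active enhancer; H3K4me1 alone =
    inactive (poised) enhancer; anything else — including H3K27ac alone —
    is "neither". The three states partition the peaks.
    """
    me1 = peaks.overlap_any(h3k4me1.intervals)
    ac = peaks.overlap_any(h3k27ac.intervals)
    states = np.where(
        me1 & ac, "active_enhancer", np.where(me1 & ~ac, "inactive_enhancer", "neither")
    )
    return [str(s) for s in states]


@dataclass(frozen=True)
class SNPRecord:
    """A SNP with its LD tag. Positions are 1-based as delivered by GWAS/LD
    tooling and converted to 0-based only at overlap time. Index SNPs tag
    themselves (``index_snp == rsid``)."""

    chrom: str
    pos: int  # 1-based
    rsid: str
    index_snp: str
    r2: float
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: 1-based position must be >= 1")
        if not (0 <= self.r2 <= 1):
            raise ValueError(f"{self.rsid}: r2 must lie in [0, 1]")
        if not (0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF must lie in [0, 0.5]")

    @property
    def is_index(self) -> bool:
        return self.index_snp == self.rsid


@dataclass
class SnpOverlapResult:
    index_hits: list[tuple[str, str]]  # (rsid, peak_id)
    ld_hits: list[tuple[str, str]]

    @property
    def n_index(self) -> int:
        return len({r for r, _ in self.index_hits})

    @property
    def n_ld(self) -> int:
        return len({r for r, _ in self.ld_hits})


def snp_in_peak(
    peaks: IntervalCollection,
    snps: Sequence[SNPRecord],
    r2_min: float = 0.8,
    maf_min: float = 0.01,
) -> SnpOverlapResult:
    """SNP-in-peak overlap after LD and allele-frequency filtering.

    SNPs below ``maf_min`` are excluded; LD proxies additionally require
    ``r2 >= r2_min`` (index SNPs are tested directly and bypass the r^2
    filter). A SNP hits a peak iff its 0-based base lies in [start, end).
    Hits are partitioned into index-SNP and LD-proxy hits.
    """
    index_hits: list[tuple[str, str]] = []
    ld_hits: list[tuple[str, str]] = []
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos, s.rsid)):
        if snp.maf < maf_min:
            continue
        if not snp.is_index and snp.r2 < r2_min:
            continue
        base = GenomicInterval(snp.chrom, snp.pos - 1, snp.pos)
        for peak in peaks.overlapping(base):
            (index_hits if snp.is_index else ld_hits).append((snp.rsid, peak.id))
    return SnpOverlapResult(index_hits=index_hits, ld_hits=ld_hits)


def dmr_overlap(
    peaks: IntervalCollection, dmrs: FeatureSet
) -> tuple[list[tuple[str, str]], int]:
    """All overlapping (peak, DMR) pairs plus the count of distinct peaks hit."""
    pairs: list[tuple[str, str]] = []
    for peak in peaks:
        for dmr in dmrs.intervals.overlapping(peak):
            pairs.append((peak.id, dmr.id))
    n_distinct = len({p for p, _ in pairs})
    return pairs, n_distinct


def partition_by_overlap(
    peaks: IntervalCollection,
    feature_sets: Sequence[FeatureSet],
    unmatched_label: str = "unmatched",
) -> list[str]:
    """Assign each peak exactly one label: the first feature set (in the
    given precedence order) it overlaps, else ``unmatched_label``.

    This is the operation behind overlap classifications of a peak universe
    into named classes plus an unmatched remainder; by construction the
    class counts partition the peak set.
    """
    labels = [unmatched_label] * len(peaks)
    assigned = np.zeros(len(peaks), dtype=bool)
    for fs in feature_sets:
        flags = peaks.overlap_any(fs.intervals)
        newly = flags & ~assigned
        for i in np.flatnonzero(newly):
            labels[i] = fs.name
        assigned |= flags
    return labels


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Read a SNP TSV with header columns chrom, pos, rsid, index_snp, r2, maf."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return [
        SNPRecord(
            chrom=str(r.chrom), pos=int(r.pos), rsid=str(r.rsid),
            index_snp=str(r.index_snp), r2=float(r.r2), maf=float(r.maf),
        )
        for r in df.itertuples()
    ]


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: str | Path, header: Sequence[str] = ()
) -> None:
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#feature\tn_peaks\tn_overlap\texpected\tchi2\tp\tq\tdirection\n")
        for r in results:
            fh.write(
                f"{r.feature}\t{r.n_peaks}\t{r.n_overlap}\t{r.expected:.6g}\t"
                f"{r.chi2:.6g}\t{r.p:.6g}\t{r.q:.6g}\t{r.direction}\n"
            )
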