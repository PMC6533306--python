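"""Consensus peaks across donors and the occupancy-based differential test.

A consensus peak is a merged region of the pooled per-donor peaks that is
supported by at least ``min_donors`` donors (a donor supports a region if any
of its peaks overlaps it by >= 1 bp). Presence/absence of each consensus peak
across donors ("occupancy") is then compared between disease groups with a
two-sided Fisher exact test per peak, Benjamini-Hochberg adjusted across
peaks. This occupancy view is deliberately distinct from read-count
("affinity") models, whose result tables are consumed, not fitted, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalCollection, read_bed

__all__ = [
    "DonorPeakSet",
    "ConsensusPeak",
    "OccupancyMatrix",
    "DifferentialPeakResult",
    "build_consensus",
    "occupancy_fisher",
    "bh_fdr",
    "intersect_differential",
    "load_cohort",
    "write_consensus_bed",
    "write_differential_tsv",
]

GROUPS = ("T2D", "ND")


@dataclass(frozen=True)
class DonorPeakSet:
    """Per-donor called peaks plus the metadata carried through the analysis.

    Sex and fresh/frozen treatment are recorded but not modelled by the
    occupancy test; they are covariates only of out-of-scope affinity models.
    """

    donor_id: str
    group: str  # "T2D" or "ND"
    sex: str = "."  # "M" / "F"
    treatment: str = "."  # "frozen" / "fresh"
    peaks: IntervalCollection = field(default_factory=lambda: IntervalCollection([]))

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval
    supporting_donors: frozenset[str]

    @property
    def n_support(self) -> int:
        return len(self.supporting_donors)

    @property
    def id(self) -> str:
        return self.interval.id


@dataclass
class OccupancyMatrix:
    """Consensus peaks x donors boolean presence with donor group labels."""

    peaks: list[ConsensusPeak]
    donors: list[DonorPeakSet]
    present: np.ndarray  # bool, shape (n_peaks, n_donors)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.peaks), len(self.donors)):
            raise ValueError("presence matrix shape does not match peaks x donors")
        row_support = self.present.sum(axis=1)
        for peak, s in zip(self.peaks, row_support):
            if s != peak.n_support:
                raise ValueError(f"row sum {s} != n_support {peak.n_support} for {peak.id}")

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([d.group for d in self.donors])

    def donor_ids(self) -> list[str]:
        return [d.donor_id for d in self.donors]


@dataclass(frozen=True)
class DifferentialPeakResult:
    peak: ConsensusPeak
    n_present_t2d: int
    n_absent_t2d: int
    n_present_nd: int
    n_absent_nd: int
    direction: str  # "T2D-enriched", "ND-enriched", "none"
    p: float
    q: float


def build_consensus(
    donor_sets: Sequence[DonorPeakSet],
    min_donors: int = 3,
    donor_subset: Iterable[str] | None = None,
) -> OccupancyMatrix:
    """Merge pooled donor peaks and keep regions supported by >= min_donors donors.

    ``donor_subset`` restricts the construction to the named donors, which
    gives the per-group peak universes (e.g. ND-only / T2D-only) alongside
    the combined one. The result is invariant to donor input order.
    """
    if donor_subset is not None:
        wanted = set(donor_subset)
        donor_sets = [d for d in donor_sets if d.donor_id in wanted]
        missing = wanted - {d.donor_id for d in donor_sets}
        if missing:
            raise ValueError(f"donor_subset names unknown donors: {sorted(missing)}")
    donors = sorted(donor_sets, key=lambda d: d.donor_id)
    ids = [d.donor_id for d in donors]
    if len(set(ids)) != len(ids):
        raise ValueError("donor_id values must be unique within a cohort")
    if min_donors < 1:
        raise ValueError("min_donors must be >= 1")
    if min_donors > len(donors):
        raise ValueError(f"min_donors={min_donors} exceeds the {len(donors)} donors provided")

    pooled = IntervalCollection(
        [iv for d in donors for iv in d.peaks], label="pooled"
    )
    candidates = pooled.merge(max_gap=0)

    support = np.zeros((len(candidates), len(donors)), dtype=bool)
    for j, donor in enumerate(donors):
        support[:, j] = candidates.overlap_any(donor.peaks)

    keep = support.sum(axis=1) >= min_donors
    peaks: list[ConsensusPeak] = []
    for i in np.flatnonzero(keep):
        iv = candidates[i]
        supporters = frozenset(ids[j] for j in np.flatnonzero(support[i]))
        peaks.append(
            ConsensusPeak(
                interval=GenomicInterval(
                    iv.chrom, iv.start, iv.end, name=f"consensus_{iv.chrom}_{iv.start}"
                ),
                supporting_donors=supporters,
            )
        )
    return OccupancyMatrix(peaks=peaks, donors=donors, present=support[keep])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fisher_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def occupancy_fisher(matrix: OccupancyMatrix) -> list[DifferentialPeakResult]:
    """Per-peak two-sided Fisher test of presence/absence between T2D and ND donors.

    Group sizes are fixed across peaks, so p-values are memoised on the
    presence counts. Direction follows the presence fractions; exact ties are
    labelled "none". q-values are BH-adjusted across all tested peaks.
    """
    groups = matrix.group_labels
    t2d_mask = groups == "T2D"
    nd_mask = groups == "ND"
    n1, n2 = int(t2d_mask.sum()), int(nd_mask.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both donor groups (T2D and ND) must be non-empty")

    k1s = matrix.present[:, t2d_mask].sum(axis=1)
    k2s = matrix.present[:, nd_mask].sum(axis=1)

    cache: dict[tuple[int, int], float] = {}
    pvals = np.empty(len(matrix.peaks))
    for i, (k1, k2) in enumerate(zip(k1s, k2s)):
        key = (int(k1), int(k2))
        if key not in cache:
            cache[key] = _fisher_two_sided(key[0], n1, key[1], n2)
        pvals[i] = cache[key]
    qvals = bh_fdr(pvals)

    results = []
    for peak, k1, k2, p, q in zip(matrix.peaks, k1s, k2s, pvals, qvals):
        f1, f2 = k1 / n1, k2 / n2
        direction = "T2D-enriched" if f1 > f2 else "ND-enriched" if f2 > f1 else "none"
        results.append(
            DifferentialPeakResult(
                peak=peak,
                n_present_t2d=int(k1),
                n_absent_t2d=n1 - int(k1),
                n_present_nd=int(k2),
                n_absent_nd=n2 - int(k2),
                direction=direction,
                p=float(p),
                q=float(q),
            )
        )
    return results


def intersect_differential(
    occupancy_results: Sequence[DifferentialPeakResult],
    affinity_table: pd.DataFrame,
    q_threshold: float = 0.05,
    significant_col: str = "significant",
) -> list[str]:
    """Peaks significant in the occupancy test AND overlapping a significant
    row of an external affinity-differential table.

    The affinity table must carry ``chrom``/``start``/``end`` columns and a
    boolean significance indicator; the affinity model itself is an upstream
    input, never refitted here.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(affinity_table.columns):
        raise ValueError(f"affinity table must have columns {sorted(required)}")
    if significant_col in affinity_table.columns:
        sig_rows = affinity_table[affinity_table[significant_col].astype(bool)]
    else:
        sig_rows = affinity_table
    affinity = IntervalCollection(
        [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in sig_rows.itertuples()
        ],
        label="affinity",
    )
    hits = [r for r in occupancy_results if r.q <= q_threshold]
    if not hits or len(affinity) == 0:
        return []
    occ = IntervalCollection([r.peak.interval for r in hits])
    flags = occ.overlap_any(affinity)
    # occ is sorted; map flags back through the sorted order
    order = sorted(range(len(hits)), key=lambda i: (
        hits[i].peak.interval.chrom, hits[i].peak.interval.start, hits[i].peak.interval.end
    ))
    out = [hits[order[i]].peak.id for i in range(len(hits)) if flags[i]]
    return sorted(out)


# -- cohort I/O ------------------------------------------------------------

def load_cohort(metadata_tsv: str | Path, peaks_dir: str | Path | None = None) -> list[DonorPeakSet]:
    """Load donor metadata TSV (donor_id, group, sex, treatment, peaks_path)
    and the per-donor narrowPeak files it points to."""
    meta_path = Path(metadata_tsv)
    df = pd.read_csv(meta_path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    base = Path(peaks_dir) if peaks_dir is not None else meta_path.parent
    cohort = []
    for row in df.itertuples():
        peaks_path = base / str(row.peaks_path)
        cohort.append(
            DonorPeakSet(
                donor_id=str(row.donor_id),
                group=str(row.group),
                sex=str(getattr(row, "sex", ".")),
                treatment=str(getattr(row, "treatment", ".")),
                peaks=read_bed(peaks_path, dialect="narrowPeak", label=str(row.donor_id)),
            )
        )
    return cohort


def write_consensus_bed(matrix: OccupancyMatrix, path: str | Path, header: Sequence[str] = ()) -> None:
    """Consensus peaks as BED with donor support count in the score column."""
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        for peak in matrix.peaks:
            iv = peak.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peak.id}\t{peak.n_support}\n")


def write_differential_tsv(
    results: Sequence[DifferentialPeakResult], path: str | Path, header: Sequence[str] = ()
) -> None:
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write(
            "#chrom\tstart\tend\tpeak_id\tn_present_T2D\tn_present_ND\tdirection\tp\tq\n"
        )
        for r in results:
            iv = r.peak.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.peak.id}\t"
                f"{r.n_present_t2d}\t{r.n_present_nd}\t{r.direction}\t"
                f"{r.p:.6g}\t{r.q:.6g}\n"
            )
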