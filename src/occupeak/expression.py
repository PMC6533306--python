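"""Expression categorisation and linkage of open chromatin to expression level.

Transcripts below a TPM threshold (default 0.1) are "non-expressed"; the
remainder are split by rank into three contiguous tertiles (low / medium /
high) of sizes as equal as integer division permits. Each transcript is then
flagged for having a peak summit within a window (default 1,500 bp) of its
span, and each expressed tertile is compared with the non-expressed
reference by a 2x2 Pearson chi-square, BH-adjusted across the three tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .annotation import TranscriptModel
from .consensus import bh_fdr
from .intervals import IntervalCollection

__all__ = [
    "ExpressionCategoryAssignment",
    "EXPRESSION_CATEGORIES",
    "categorize_expression",
    "flag_nearby_peaks",
    "expression_enrichment",
    "read_expression_table",
    "write_assignments_tsv",
]

EXPRESSION_CATEGORIES = ("non", "low", "medium", "high")


@dataclass
class ExpressionCategoryAssignment:
    transcript_id: str
    tpm: float
    category: str
    has_nearby_peak: bool | None = None


def categorize_expression(
    table: Mapping[str, float], tpm_threshold: float = 0.1
) -> list[ExpressionCategoryAssignment]:
    """Assign non/low/medium/high expression categories.

    Transcripts with TPM < threshold are "non"; the rest are sorted
    ascending by (tpm, transcript_id) — a stable, deterministic tie-break —
    and split into three contiguous rank groups whose sizes differ by at
    most one.
    """
    items = [(tid, float(tpm)) for tid, tpm in table.items()]
    for tid, tpm in items:
        if tpm < 0:
            raise ValueError(f"{tid}: TPM must be non-negative")
    non = [(tid, tpm) for tid, tpm in items if tpm < tpm_threshold]
    expressed = sorted(
        ((tid, tpm) for tid, tpm in items if tpm >= tpm_threshold),
        key=lambda x: (x[1], x[0]),
    )
    n = len(expressed)
    if n < 3:
        raise ValueError(f"need >= 3 expressed transcripts to form tertiles, got {n}")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = [
        ExpressionCategoryAssignment(tid, tpm, "non")
        for tid, tpm in sorted(non, key=lambda x: (x[1], x[0]))
    ]
    start = 0
    for cat, size in zip(("low", "medium", "high"), sizes):
        for tid, tpm in expressed[start : start + size]:
            out.append(ExpressionCategoryAssignment(tid, tpm, cat))
        start += size
    return out


def _summit_to_span_distance(summit: int, t: TranscriptModel) -> int:
    if summit < t.tx_start:
        return t.tx_start - summit
    if summit >= t.tx_end:
        return summit - (t.tx_end - 1)
    return 0


def flag_nearby_peaks(
    assignments: Sequence[ExpressionCategoryAssignment],
    transcripts: Sequence[TranscriptModel],
    peaks: IntervalCollection,
    window_bp: int = 1500,
    mode: str = "span",
) -> list[ExpressionCategoryAssignment]:
    """Fill ``has_nearby_peak``: is any peak summit within ``window_bp`` of
    the transcript?

    ``mode="span"`` (default) measures the minimal distance from the summit
    to the transcript span (0 when the summit falls inside it);
    ``mode="tss"`` measures summit-to-TSS distance instead.
    """
    if mode not in ("span", "tss"):
        raise ValueError("mode must be 'span' or 'tss'")
    by_id = {t.transcript_id: t for t in transcripts}
    tmp: dict[str, list[int]] = {}
    for peak in peaks:
        tmp.setdefault(peak.chrom, []).append(peak.effective_summit())
    summits_by_chrom = {c: np.array(sorted(v)) for c, v in tmp.items()}

    out = []
    for a in assignments:
        t = by_id.get(a.transcript_id)
        if t is None:
            raise KeyError(f"no transcript model for {a.transcript_id}")
        summits = summits_by_chrom.get(t.chrom, np.array([], dtype=int))
        near = False
        if summits.size:
            if mode == "tss":
                lo, hi = t.tss - window_bp, t.tss + window_bp
            else:
                # summit within window_bp of the span [tx_start, tx_end)
                lo, hi = t.tx_start - window_bp, (t.tx_end - 1) + window_bp
            j = int(np.searchsorted(summits, lo))
            near = j < summits.size and summits[j] <= hi
        out.append(
            ExpressionCategoryAssignment(a.transcript_id, a.tpm, a.category, bool(near))
        )
    return out


def expression_enrichment(
    assignments: Sequence[ExpressionCategoryAssignment],
) -> pd.DataFrame:
    """Per-tertile 2x2 Pearson chi-square of peak proximity versus the
    non-expressed reference, plus the proportion-with-peak readout.

    Returns a DataFrame indexed by category with columns n, n_with_peak,
    proportion, chi2, p, q, skipped. Tests on empty tertiles are skipped
    and flagged rather than failing the batch.
    """
    counts = {c: [0, 0] for c in EXPRESSION_CATEGORIES}  # [with peak, without]
    for a in assignments:
        if a.has_nearby_peak is None:
            raise ValueError("assignments must have has_nearby_peak filled first")
        counts[a.category][0 if a.has_nearby_peak else 1] += 1
    ref = counts["non"]
    if sum(ref) == 0:
        raise ValueError("non-expressed reference category is empty")

    rows = []
    pvals, tested = [], []
    for cat in EXPRESSION_CATEGORIES:
        with_peak, without = counts[cat]
        n = with_peak + without
        prop = with_peak / n if n else float("nan")
        row = {
            "category": cat, "n": n, "n_with_peak": with_peak,
            "proportion": prop, "chi2": float("nan"), "p": float("nan"),
            "q": float("nan"), "skipped": False,
        }
        if cat != "non":
            if n == 0:
                row["skipped"] = True
            else:
                table = np.array([[with_peak, without], ref])
                if table.sum(axis=0).min() == 0:
                    # a degenerate margin (e.g. nobody anywhere has a peak)
                    stat, p = 0.0, 1.0
                else:
                    stat, p, _, _ = chi2_contingency(table, correction=False)
                row["chi2"], row["p"] = float(stat), float(p)
                pvals.append(float(p))
                tested.append(cat)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("category")
    if pvals:
        for cat, q in zip(tested, bh_fdr(pvals)):
            df.loc[cat, "q"] = float(q)
    return df


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a TSV of transcript_id, tpm into a mapping."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return dict(zip(df["transcript_id"].astype(str), df["tpm"].astype(float)))


def write_assignments_tsv(
    assignments: Sequence[ExpressionCategoryAssignment],
    path: str | Path,
    header: Sequence[str] = (),
) -> None:
    with Path(path).open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#transcript_id\ttpm\tcategory\thas_nearby_peak\n")
        for a in assignments:
            flag = "" if a.has_nearby_peak is None else str(int(a.has_nearby_peak))
            fh.write(f"{a.transcript_id}\t{a.tpm:.6g}\t{a.category}\t{flag}\n")
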