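"""Sample-level QC: fragment-size distributions and between-donor binned
Spearman correlation with hierarchical clustering.

QC operates on fragment interval/length tables rather than alignment files,
keeping the pipeline format-light. Fragment midpoints are counted per
consecutive genome bin (default 10 kb, chrY excluded), donors are compared
by Spearman rank correlation (average ranks on ties), and clustered by
average linkage on the distance 1 - rho.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "fragment_histogram",
    "binned_midpoint_counts",
    "binned_spearman_cluster",
    "linkage_to_newick",
    "read_fragments_tsv",
    "read_chrom_sizes",
]


def fragment_histogram(
    table: Mapping[str, Iterable[int]], bin_width: int = 10, max_len: int = 1000
) -> pd.DataFrame:
    """Per-donor fragment-length histogram.

    Bins are half-open [k*w, (k+1)*w) up to ``max_len``; longer fragments
    pool into a final overflow bin. In real ATAC data the histogram shows
    a sub-nucleosomal mode plus mono-/di-/tri-nucleosomal modes.
    """
    if bin_width < 1 or max_len < bin_width:
        raise ValueError("require bin_width >= 1 and max_len >= bin_width")
    n_bins = max_len // bin_width
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    cols = [f"[{edges[i]},{edges[i+1]})" for i in range(n_bins)] + [f">{n_bins * bin_width}"]
    rows = {}
    for donor, lengths in table.items():
        arr = np.asarray(list(lengths), dtype=int)
        if arr.size and arr.min() <= 0:
            raise ValueError(f"donor {donor}: fragment lengths must be positive")
        counts = np.zeros(n_bins + 1, dtype=int)
        if arr.size:
            in_range = arr < n_bins * bin_width
            counts[:n_bins] = np.bincount(arr[in_range] // bin_width, minlength=n_bins)
            counts[n_bins] = int((~in_range).sum())
        rows[donor] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def binned_midpoint_counts(
    fragments: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10_000,
    exclude_chroms: Iterable[str] = ("chrY",),
) -> pd.DataFrame:
    """Fragment-midpoint counts per consecutive genome bin, donors as rows.

    ``fragments`` needs columns donor_id, chrom, start, end. Chromosomes in
    ``exclude_chroms`` are dropped before binning; fragments on chromosomes
    absent from ``chrom_sizes`` are an error.
    """
    excluded = set(exclude_chroms)
    chroms = [c for c in sorted(chrom_sizes) if c not in excluded]
    offsets, total_bins = {}, 0
    for c in chroms:
        offsets[c] = total_bins
        total_bins += int(np.ceil(chrom_sizes[c] / bin_size))

    donors = sorted(fragments["donor_id"].astype(str).unique())
    mat = np.zeros((len(donors), total_bins), dtype=int)
    frag = fragments[~fragments["chrom"].isin(excluded)]
    unknown = set(frag["chrom"].unique()) - set(chroms)
    if unknown:
        raise ValueError(f"fragments on chromosomes without declared sizes: {sorted(unknown)}")
    didx = {d: i for i, d in enumerate(donors)}
    mid = (frag["start"].to_numpy() + frag["end"].to_numpy()) // 2
    bins = np.array([offsets[c] for c in frag["chrom"]]) + mid // bin_size if len(frag) else np.array([], dtype=int)
    rows = np.array([didx[str(d)] for d in frag["donor_id"]], dtype=int) if len(frag) else np.array([], dtype=int)
    np.add.at(mat, (rows, bins), 1)
    return pd.DataFrame(mat, index=donors)


def binned_spearman_cluster(
    fragments: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 10_000,
    exclude_chroms: Iterable[str] = ("chrY",),
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Spearman correlation matrix between donors plus its average-linkage tree.

    Returns (correlation DataFrame, scipy linkage matrix, Newick string).
    Distances are 1 - rho; the matrix is symmetric with unit diagonal.
    """
    counts = binned_midpoint_counts(fragments, chrom_sizes, bin_size, exclude_chroms)
    if counts.shape[0] < 2:
        raise ValueError("need at least two donors for correlation")
    rho = spearmanr(counts.to_numpy().T).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-donor case to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=counts.index, columns=counts.index)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    newick = linkage_to_newick(linkage, list(counts.index))
    return corr, linkage, newick


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(linkage)

    def build(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    inner = build(tree, tree.dist)
    return inner.rsplit(":", 1)[0] + ";"


def read_fragments_tsv(path: str | Path) -> pd.DataFrame:
    """Read a fragment TSV (donor_id, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes
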