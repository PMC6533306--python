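"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study design the analysis is built for: a toy
genome carries latent accessible sites; each donor of a 6 T2D / 9 ND cohort
carries each site with a group-specific occupancy probability (a fraction of
sites is differential, the rest sit at a common baseline); peak calls are the
present sites with jittered boundaries and sampled widths. Feature sets,
transcript models, expression tables, SNP/LD tables and fragment tables are
generated on the same toy genome with known ground truth, so every analysis
stage is testable without downloads.

A single integer seed drives one named pseudorandom stream per artifact
(sites, cohort, features, annotation, expression, snps, fragments), so
regenerating one input does not perturb the others. Identical configs give
byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .consensus import DonorPeakSet
from .enrichment import FeatureSet, SNPRecord
from .intervals import GenomicInterval, IntervalCollection

__all__ = [
    "SimulationConfig",
    "CohortSim",
    "FeatureSim",
    "AnnotationSim",
    "simulate_cohort",
    "simulate_features",
    "simulate_annotation_inputs",
    "simulate_fragments",
    "sites_layout",
    "write_config",
    "read_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the target
    study design (6 T2D vs 9 ND donors; a strong differential minority of
    sites over a 50% baseline occupancy)."""

    seed: int = 0
    # toy genome / latent sites
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_sites: int = 1000
    site_width_mean: float = 400.0
    site_width_sd: float = 50.0
    jitter_sd: float = 50.0
    # cohort
    n_t2d: int = 6
    n_nd: int = 9
    baseline_occupancy: float = 0.5
    differential_fraction: float = 0.1
    p_t2d: float = 0.95
    p_nd: float = 0.05
    # feature sets: fraction of latent sites each feature covers
    feature_overlap_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "H3K4me1": 0.40,
            "H3K27ac": 0.30,
            "H3K4me3": 0.20,
            "FANTOM5": 0.10,
            "DMR": 0.12,
            "TF_PDX1": 0.15,
        }
    )
    # mutually exclusive regulatory classes (fractions of sites; sum <= 1)
    regulatory_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.10, "C2": 0.10, "C3": 0.15, "C4": 0.10, "C5": 0.05}
    )
    # SNP / LD table
    n_index_snps: int = 30
    ld_group_size: int = 6  # index SNP + (size - 1) proxies
    snp_in_peak_fraction: float = 0.4
    r2_low: float = 0.5  # proxies draw r2 ~ Uniform(r2_low, 1)
    # transcripts / expression
    n_transcripts: int = 600
    tpm_threshold: float = 0.1
    # category weights follow the real cohort's proportions:
    # 38,428 / 60,517 non-expressed, the rest split into three tertiles
    non_expressed_weight: float = 38_428 / 60_517
    proximity_probs: tuple[float, float, float, float] = (0.1, 0.4, 0.6, 0.8)
    proximity_window: int = 1500
    # fragments (QC)
    fragments_per_donor: int = 2000
    chry_fragments_per_donor: int = 50

    def __post_init__(self) -> None:
        probs = [
            self.baseline_occupancy, self.differential_fraction, self.p_t2d,
            self.p_nd, self.snp_in_peak_fraction, self.non_expressed_weight,
            *self.proximity_probs, *self.feature_overlap_fractions.values(),
            *self.regulatory_class_fractions.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities/fractions must lie in [0, 1]")
        if sum(self.regulatory_class_fractions.values()) > 1 + 1e-9:
            raise ValueError("regulatory class fractions must sum to <= 1")
        if self.n_t2d < 1 or self.n_nd < 1:
            raise ValueError("donor counts must be >= 1")
        if self.n_sites < 1 or self.n_chroms < 1:
            raise ValueError("need at least one site and one chromosome")

    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self, include_chry: bool = True) -> dict[str, int]:
        sizes = {c: self.chrom_length for c in self.chroms()}
        if include_chry:
            sizes["chrY"] = self.chrom_length
        return sizes


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One independent generator per named stream of a given master seed."""
    key = zlib.crc32(stream.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def sites_layout(config: SimulationConfig) -> list[tuple[str, int]]:
    """Deterministic (chrom, center) placement of the latent accessible sites.

    Sites sit on a regular per-chromosome grid with a small jittered offset,
    spaced widely enough that jittered peaks from neighbouring sites can
    never merge. Shared by the cohort, feature and SNP generators.
    """
    rng = _rng(config.seed, "sites")
    chroms = config.chroms()
    per_chrom = [config.n_sites // config.n_chroms] * config.n_chroms
    for i in range(config.n_sites % config.n_chroms):
        per_chrom[i] += 1
    max_extent = config.site_width_mean + 4 * config.site_width_sd + 4 * config.jitter_sd
    sites: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        spacing = config.chrom_length // (k + 1)
        if spacing < 2 * max_extent:
            raise ValueError(
                f"{k} sites on a {config.chrom_length} bp chromosome are too "
                f"dense for site width/jitter settings (spacing {spacing})"
            )
        offsets = rng.integers(-spacing // 8, spacing // 8 + 1, size=k)
        for i in range(k):
            sites.append((chrom, int((i + 1) * spacing + offsets[i])))
    return sites


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    donors: list[DonorPeakSet]
    sites: list[tuple[str, int]]
    presence: np.ndarray  # (n_sites, n_donors) realized occupancy
    truth: pd.DataFrame  # site_id, chrom, center, p_t2d, p_nd, is_differential


def _donor_roster(config: SimulationConfig) -> list[tuple[str, str, str, str]]:
    """(donor_id, group, sex, treatment) — deterministic cycling assignment."""
    roster = []
    sexes = ("M", "F")
    treatments = ("fresh", "frozen")
    for i in range(config.n_t2d):
        roster.append((f"T2D_{i + 1:02d}", "T2D", sexes[i % 2], treatments[i % 2]))
    for i in range(config.n_nd):
        roster.append((f"ND_{i + 1:02d}", "ND", sexes[i % 2], treatments[(i + 1) % 2]))
    return roster


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> CohortSim:
    """Simulate per-donor peak sets with group-specific occupancy.

    For each latent site and donor, a Bernoulli draw at the donor's group
    probability decides presence; present peaks get jittered starts, sampled
    widths and a summit at the site centre. Optionally writes one narrowPeak
    per donor, a metadata TSV and the ground-truth site table.
    """
    sites = sites_layout(config)
    n_sites = len(sites)
    rng = _rng(config.seed, "cohort")

    n_diff = int(round(config.differential_fraction * n_sites))
    diff_idx = np.sort(rng.choice(n_sites, size=n_diff, replace=False))
    is_diff = np.zeros(n_sites, dtype=bool)
    is_diff[diff_idx] = True
    p_t2d = np.where(is_diff, config.p_t2d, config.baseline_occupancy)
    p_nd = np.where(is_diff, config.p_nd, config.baseline_occupancy)

    roster = _donor_roster(config)
    groups = np.array([g for _, g, _, _ in roster])
    p_mat = np.where(groups[None, :] == "T2D", p_t2d[:, None], p_nd[:, None])
    presence = rng.random((n_sites, len(roster))) < p_mat

    donors: list[DonorPeakSet] = []
    for j, (donor_id, group, sex, treatment) in enumerate(roster):
        idx = np.flatnonzero(presence[:, j])
        widths = np.clip(
            np.round(rng.normal(config.site_width_mean, config.site_width_sd, size=idx.size)),
            50, None,
        ).astype(int)
        jitters = np.round(rng.normal(0.0, config.jitter_sd, size=idx.size)).astype(int)
        peaks = []
        for k, site_i in enumerate(idx):
            chrom, center = sites[site_i]
            start = max(0, center - widths[k] // 2 + jitters[k])
            end = start + widths[k]
            summit = min(max(center - start, 0), widths[k] - 1)
            peaks.append(
                GenomicInterval(
                    chrom, int(start), int(end),
                    name=f"{donor_id}_peak_{site_i}", summit=int(summit),
                )
            )
        donors.append(
            DonorPeakSet(
                donor_id=donor_id, group=group, sex=sex, treatment=treatment,
                peaks=IntervalCollection(peaks, label=donor_id),
            )
        )

    truth = pd.DataFrame(
        {
            "site_id": [f"site_{i}" for i in range(n_sites)],
            "chrom": [c for c, _ in sites],
            "center": [p for _, p in sites],
            "p_t2d": p_t2d,
            "p_nd": p_nd,
            "is_differential": is_diff,
        }
    )
    sim = CohortSim(donors=donors, sites=sites, presence=presence, truth=truth)
    if out_dir is not None:
        _write_cohort(sim, Path(out_dir))
    return sim


def _write_cohort(sim: CohortSim, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for donor in sim.donors:
        fname = f"{donor.donor_id}.narrowPeak"
        with (out_dir / fname).open("w") as fh:
            for iv in donor.peaks:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t.\t0\t-1\t-1\t"
                    f"{iv.summit if iv.summit is not None else -1}\n"
                )
        rows.append(
            {
                "donor_id": donor.donor_id, "group": donor.group,
                "sex": donor.sex, "treatment": donor.treatment, "peaks_path": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "donor_metadata.tsv", sep="\t", index=False)
    sim.truth.to_csv(out_dir / "ground_truth_sites.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature sets
# ---------------------------------------------------------------------------

@dataclass
class FeatureSim:
    features: dict[str, FeatureSet]
    truth: pd.DataFrame  # per-site boolean column per feature (+ reg. class)


def simulate_features(
    config: SimulationConfig,
    sites: Sequence[tuple[str, int]] | None = None,
    out_dir: str | Path | None = None,
) -> FeatureSim:
    """Generate feature-set BEDs overlapping configured fractions of sites.

    Each named feature covers round(fraction * n_sites) site centres with an
    interval placed on the centre, plus decoy intervals placed in the gaps
    between sites (guaranteed non-overlapping with any site). The C-class
    fractions define mutually exclusive site classes.
    """
    if sites is None:
        sites = sites_layout(config)
    n = len(sites)
    rng = _rng(config.seed, "features")
    truth = pd.DataFrame({"site_id": [f"site_{i}" for i in range(n)]})

    def site_interval(i: int, width: int, name: str) -> GenomicInterval:
        chrom, center = sites[i]
        start = max(0, center - width // 2)
        return GenomicInterval(chrom, start, start + width, name=name)

    def decoy_intervals(count: int, prefix: str) -> list[GenomicInterval]:
        # midway between adjacent same-chromosome sites: never touches a site
        out = []
        gaps = [
            ((sites[i][1] + sites[i + 1][1]) // 2, sites[i][0])
            for i in range(n - 1)
            if sites[i][0] == sites[i + 1][0]
        ]
        if not gaps:
            return out
        pick = rng.choice(len(gaps), size=min(count, len(gaps)), replace=False)
        for k, g in enumerate(np.sort(pick)):
            mid, chrom = gaps[g][0], gaps[g][1]
            width = int(rng.integers(300, 701))
            out.append(GenomicInterval(chrom, mid - width // 2, mid + width - width // 2,
                                       name=f"{prefix}_decoy_{k}"))
        return out

    features: dict[str, FeatureSet] = {}
    for name, frac in config.feature_overlap_fractions.items():
        k = int(round(frac * n))
        if k > n:
            raise ValueError(f"feature {name}: fraction {frac} incompatible with {n} sites")
        chosen = np.sort(rng.choice(n, size=k, replace=False)) if k else np.array([], dtype=int)
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        ivs = [
            site_interval(int(i), int(rng.integers(300, 701)), f"{name}_{i}")
            for i in chosen
        ]
        ivs += decoy_intervals(max(1, k // 4), name)
        features[name] = FeatureSet(name=name, intervals=IntervalCollection(ivs, label=name))
        truth[name] = mask

    # mutually exclusive regulatory classes over a single permutation
    perm = rng.permutation(n)
    cursor = 0
    class_label = np.array(["none"] * n, dtype=object)
    for name, frac in config.regulatory_class_fractions.items():
        k = int(round(frac * n))
        chosen = perm[cursor : cursor + k]
        cursor += k
        mask = np.zeros(n, dtype=bool)
        mask[chosen] = True
        class_label[chosen] = name
        ivs = [
            site_interval(int(i), int(rng.integers(300, 701)), f"{name}_{i}")
            for i in np.sort(chosen)
        ]
        if ivs:
            features[name] = FeatureSet(name=name, intervals=IntervalCollection(ivs, label=name))
        truth[name] = mask
    truth["regulatory_class"] = class_label

    sim = FeatureSim(features=features, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fs in features.items():
            with (out / f"{name}.bed").open("w") as fh:
                for iv in fs.intervals:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
        truth.to_csv(out / "feature_truth.tsv", sep="\t", index=False)
    return sim


# ---------------------------------------------------------------------------
# transcripts, expression, SNPs
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSim:
    transcripts: list[TranscriptModel]
    expression: dict[str, float]
    snps: list[SNPRecord]
    expression_peaks: IntervalCollection  # peaks placed to realise proximity labels
    truth: pd.DataFrame  # transcript_id, category, has_nearby_peak
    snp_truth: pd.DataFrame  # rsid, in_site, passes_filters


def _expression_category_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_transcripts
    n_non = int(round(config.non_expressed_weight * n))
    n_expr = n - n_non
    if n_expr < 3:
        raise ValueError("config leaves fewer than 3 expressed transcripts")
    base, rem = divmod(n_expr, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    return {"non": n_non, "low": sizes[0], "medium": sizes[1], "high": sizes[2]}


# disjoint TPM ranges per expressed category keep rank-derived tertiles
# aligned with the generating labels (see docs/methods.md)
_TPM_RANGES = {"low": (0.1, 1.0), "medium": (1.0, 10.0), "high": (10.0, 1000.0)}


def _draw_tpm(rng: np.random.Generator, category: str, threshold: float) -> float:
    if category == "non":
        return float(rng.uniform(0.0, threshold * 0.99))
    lo, hi = _TPM_RANGES[category]
    # log-normal component truncated to the category's range
    mu = np.log(np.sqrt(lo * hi))
    while True:
        x = float(rng.lognormal(mean=mu, sigma=0.8))
        if lo <= x < hi:
            return x


def simulate_annotation_inputs(
    config: SimulationConfig,
    sites: Sequence[tuple[str, int]] | None = None,
    out_dir: str | Path | None = None,
) -> AnnotationSim:
    """Generate transcript models, an expression table, a SNP/LD table and
    the proximity-realising peak set, all with ground-truth labels.

    Transcripts sit on their own wide grid (strand-balanced, 1–4 exons);
    each gets a TPM from a four-component mixture and, with its category's
    proximity probability, a peak whose summit lies within the proximity
    window of its span. SNPs form LD groups sharing an index SNP; a
    configured fraction is placed at site centres (in peaks), the rest in
    gaps between sites.
    """
    if sites is None:
        sites = sites_layout(config)
    rng = _rng(config.seed, "annotation")
    chroms = config.chroms()

    # -- transcripts on a wide grid ----------------------------------------
    per_chrom = [config.n_transcripts // config.n_chroms] * config.n_chroms
    for i in range(config.n_transcripts % config.n_chroms):
        per_chrom[i] += 1
    counts = _expression_category_counts(config)
    categories = (
        ["non"] * counts["non"] + ["low"] * counts["low"]
        + ["medium"] * counts["medium"] + ["high"] * counts["high"]
    )
    rng.shuffle(categories)

    transcripts: list[TranscriptModel] = []
    peaks: list[GenomicInterval] = []
    truth_rows = []
    exp_rng = _rng(config.seed, "expression")
    t_i = 0
    prox = dict(zip(("non", "low", "medium", "high"), config.proximity_probs))
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        spacing = config.chrom_length // (k + 1)
        min_spacing = 2 * (8000 // 2 + config.proximity_window + 1000)
        if spacing < min_spacing:
            raise ValueError(
                f"{k} transcripts per {config.chrom_length} bp chromosome are too "
                "dense for independent proximity labels"
            )
        for i in range(k):
            center = (i + 1) * spacing
            span = int(rng.integers(2000, 8001))
            tx_start = max(0, center - span // 2)
            tx_end = tx_start + span
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            if n_exons == 1:
                exons: tuple[tuple[int, int], ...] = ((tx_start, tx_end),)
            else:
                bps = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 2, replace=False))
                bounds = [0, *bps.tolist(), span]
                exons = tuple(
                    (tx_start + bounds[2 * e], tx_start + bounds[2 * e + 1])
                    for e in range(n_exons)
                )
            tid = f"tx_{t_i:05d}"
            cat = categories[t_i]
            transcripts.append(
                TranscriptModel(
                    chrom=chrom, strand=strand, tx_start=tx_start, tx_end=tx_end,
                    exons=exons, transcript_id=tid, gene_id=f"gene_{t_i:05d}",
                )
            )
            has_peak = bool(exp_rng.random() < prox[cat])
            if has_peak:
                # summit a random distance (<= window) upstream of the span
                u = int(exp_rng.integers(0, config.proximity_window + 1))
                summit_pos = max(0, tx_start - u)
                width = 400
                start = max(0, summit_pos - width // 2)
                peaks.append(
                    GenomicInterval(
                        chrom, start, start + width,
                        name=f"exppeak_{t_i:05d}",
                        summit=min(summit_pos - start, width - 1),
                    )
                )
            truth_rows.append({"transcript_id": tid, "category": cat, "has_nearby_peak": has_peak})
            t_i += 1

    expression = {
        row["transcript_id"]: _draw_tpm(exp_rng, row["category"], config.tpm_threshold)
        for row in truth_rows
    }

    # -- SNP / LD table ------------------------------------------------------
    snp_rng = _rng(config.seed, "snps")
    snps: list[SNPRecord] = []
    snp_truth_rows = []
    n_sites = len(sites)
    gap_positions = [
        (sites[i][0], (sites[i][1] + sites[i + 1][1]) // 2 + 1500)
        for i in range(n_sites - 1)
        if sites[i][0] == sites[i + 1][0]
    ]
    for g in range(config.n_index_snps):
        in_peak = bool(snp_rng.random() < config.snp_in_peak_fraction)
        if in_peak:
            site_i = int(snp_rng.integers(0, n_sites))
            chrom, anchor = sites[site_i]
        else:
            chrom, anchor = gap_positions[int(snp_rng.integers(0, len(gap_positions)))]
        index_rsid = f"rs{g:04d}000"
        for m in range(config.ld_group_size):
            rsid = index_rsid if m == 0 else f"rs{g:04d}{m:03d}"
            delta = 0 if m == 0 else int(snp_rng.integers(-100, 101))
            pos1 = max(1, anchor + 1 + delta)  # 1-based
            r2 = 1.0 if m == 0 else float(snp_rng.uniform(config.r2_low, 1.0))
            maf = float(snp_rng.uniform(0.0, 0.5))
            snps.append(
                SNPRecord(chrom=chrom, pos=pos1, rsid=rsid, index_snp=index_rsid, r2=r2, maf=maf)
            )
            snp_truth_rows.append(
                {
                    "rsid": rsid, "index_snp": index_rsid, "in_site_group": in_peak,
                    "r2": r2, "maf": maf,
                }
            )

    sim = AnnotationSim(
        transcripts=transcripts,
        expression=expression,
        snps=snps,
        expression_peaks=IntervalCollection(peaks, label="expression_peaks"),
        truth=pd.DataFrame(truth_rows),
        snp_truth=pd.DataFrame(snp_truth_rows),
    )
    if out_dir is not None:
        _write_annotation_inputs(sim, Path(out_dir))
    return sim


def _write_annotation_inputs(sim: AnnotationSim, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "transcripts.bed12").open("w") as fh:
        for t in sim.transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offs = ",".join(str(s - t.tx_start) for s, _ in t.exons) + ","
            fh.write(
                f"{t.chrom}\t{t.tx_start}\t{t.tx_end}\t{t.transcript_id}|{t.gene_id}\t0\t"
                f"{t.strand}\t{t.tx_start}\t{t.tx_end}\t0\t{len(t.exons)}\t{sizes}\t{offs}\n"
            )
    with (out_dir / "expression.tsv").open("w") as fh:
        fh.write("transcript_id\ttpm\n")
        for tid in sorted(sim.expression):
            fh.write(f"{tid}\t{sim.expression[tid]:.6g}\n")
    with (out_dir / "snps.tsv").open("w") as fh:
        fh.write("chrom\tpos\trsid\tindex_snp\tr2\tmaf\n")
        for s in sim.snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.index_snp}\t{s.r2:.6g}\t{s.maf:.6g}\n")
    with (out_dir / "expression_peaks.narrowPeak").open("w") as fh:
        for iv in sim.expression_peaks:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t.\t0\t-1\t-1\t{iv.summit}\n"
            )
    sim.truth.to_csv(out_dir / "annotation_truth.tsv", sep="\t", index=False)
    sim.snp_truth.to_csv(out_dir / "snp_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragments (QC)
# ---------------------------------------------------------------------------

_FRAGMENT_MODES = ((60.0, 15.0, 0.45), (200.0, 30.0, 0.30), (390.0, 35.0, 0.15), (580.0, 40.0, 0.10))


def simulate_fragments(
    config: SimulationConfig,
    sites: Sequence[tuple[str, int]] | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Per-donor fragment tables with nucleosome-phased length modes.

    Fragment midpoints concentrate around latent site centres (80%) with a
    uniform background (20%); a small chrY component exercises the QC
    exclusion rule. Lengths mix sub-nucleosomal and mono-/di-/tri-nucleosomal
    modes.
    """
    if sites is None:
        sites = sites_layout(config)
    rng = _rng(config.seed, "fragments")
    roster = _donor_roster(config)
    means = np.array([m for m, _, _ in _FRAGMENT_MODES])
    sds = np.array([s for _, s, _ in _FRAGMENT_MODES])
    weights = np.array([w for _, _, w in _FRAGMENT_MODES])
    weights = weights / weights.sum()
    rows = []
    site_chroms = np.array([c for c, _ in sites])
    site_centers = np.array([p for _, p in sites])
    for donor_id, _, _, _ in roster:
        n = config.fragments_per_donor
        comp = rng.choice(len(means), size=n, p=weights)
        lengths = np.clip(np.round(rng.normal(means[comp], sds[comp])), 20, None).astype(int)
        near_site = rng.random(n) < 0.8
        site_i = rng.integers(0, len(sites), size=n)
        noise = np.round(rng.normal(0, 200, size=n)).astype(int)
        mids = np.where(
            near_site,
            site_centers[site_i] + noise,
            rng.integers(0, config.chrom_length, size=n),
        )
        # background fragments keep the chosen site's chromosome for simplicity
        chroms = site_chroms[site_i]
        starts = np.clip(mids - lengths // 2, 0, None)
        for c, s, ln in zip(chroms, starts, lengths):
            rows.append((donor_id, str(c), int(s), int(s + ln)))
        # chrY component
        ny = config.chry_fragments_per_donor
        y_lengths = np.clip(np.round(rng.normal(200, 30, size=ny)), 20, None).astype(int)
        y_starts = rng.integers(0, config.chrom_length - 1000, size=ny)
        for s, ln in zip(y_starts, y_lengths):
            rows.append((donor_id, "chrY", int(s), int(s + ln)))
    df = pd.DataFrame(rows, columns=["donor_id", "chrom", "start", "end"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "fragments.tsv", sep="\t", index=False)
        with (out / "chrom_sizes.tsv").open("w") as fh:
            for name, length in config.chrom_sizes().items():
                fh.write(f"{name}\t{length}\n")
    return df


# ---------------------------------------------------------------------------
# flat key=value config I/O
# ---------------------------------------------------------------------------

def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialise the config as a flat key=value file (dicts as name:value lists)."""
    with Path(path).open("w") as fh:
        for f in fields(config):
            v = getattr(config, f.name)
            if isinstance(v, dict):
                v = ",".join(f"{k}:{val}" for k, val in v.items())
            elif isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f.name} = {v}\n")


def read_config(path: str | Path) -> SimulationConfig:
    raw: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    kwargs: dict[str, object] = {}
    for f in fields(SimulationConfig):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if f.name in ("feature_overlap_fractions", "regulatory_class_fractions"):
            kwargs[f.name] = {
                k: float(v) for k, v in (item.split(":") for item in val.split(",") if item)
            }
        elif f.name == "proximity_probs":
            kwargs[f.name] = tuple(float(x) for x in val.split(","))
        elif f.type in ("int", int):
            kwargs[f.name] = int(val)
        else:
            kwargs[f.name] = float(val)
    return SimulationConfig(**kwargs)
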