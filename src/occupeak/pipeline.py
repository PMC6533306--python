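"""End-to-end pipeline: simulate (or load) inputs, then run every analysis
stage in the workflow order consensus -> differential occupancy -> annotation
-> enrichment -> SNP overlap -> expression linkage -> QC.

Outputs are plain TSV/BED/Newick files in one directory, each carrying a
header naming the producing version and the config hash. Given the same
config the outputs are byte-identical across reruns; timestamped logging
goes to a logger, never into the data files. A manifest lists every output
with its row count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd

from . import __version__
from .annotation import annotate_peaks, category_proportions, distance_to_nearest_tss, write_annotation_tsv
from .consensus import (
    build_consensus,
    occupancy_fisher,
    write_consensus_bed,
    write_differential_tsv,
)
from .enrichment import classify_enhancer_state, dmr_overlap, enrichment_batch, snp_in_peak
from .expression import (
    categorize_expression,
    expression_enrichment,
    flag_nearby_peaks,
    write_assignments_tsv,
)
from .intervals import IntervalCollection
from .qc import binned_spearman_cluster, fragment_histogram
from .simulate import (
    SimulationConfig,
    simulate_annotation_inputs,
    simulate_cohort,
    simulate_features,
    simulate_fragments,
    write_config,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("occupeak")


@dataclass(frozen=True)
class RunConfig:
    """Run-level thresholds plus the simulation config that generates inputs."""

    out_dir: str
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_donors: int = 3
    r2_min: float = 0.8
    maf_min: float = 0.01
    tpm_threshold: float = 0.1
    proximity_window: int = 1500
    chance_fraction: float = 0.05
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.min_donors < 1:
            raise ValueError("min_donors must be >= 1")
        if self.min_donors > self.sim.n_t2d + self.sim.n_nd:
            raise ValueError(
                f"min_donors={self.min_donors} exceeds the "
                f"{self.sim.n_t2d + self.sim.n_nd} donors of the cohort"
            )
        for name, value, lo, hi in (
            ("r2_min", self.r2_min, 0.0, 1.0),
            ("maf_min", self.maf_min, 0.0, 0.5),
            ("chance_fraction", self.chance_fraction, 0.0, 1.0),
            ("q_threshold", self.q_threshold, 0.0, 1.0),
        ):
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.tpm_threshold < 0 or self.proximity_window < 0:
            raise ValueError("tpm_threshold and proximity_window must be non-negative")

    def config_hash(self) -> str:
        """Hash of the analytic configuration; the output path is excluded so
        the same analysis is recognisable wherever it is written."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> list[str]:
    return [f"occupeak v{__version__} config={config.config_hash()}"]


def run_pipeline(config: RunConfig) -> dict[str, int]:
    """Run every stage on a simulated cohort and write all artifacts.

    Returns the manifest mapping output filename -> data row count.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    manifest: dict[str, int] = {}

    logger.info("simulating inputs (seed=%d)", config.sim.seed)
    cohort = simulate_cohort(config.sim, out_dir=out / "inputs")
    feats = simulate_features(config.sim, sites=cohort.sites, out_dir=out / "inputs" / "features")
    ann = simulate_annotation_inputs(config.sim, sites=cohort.sites, out_dir=out / "inputs")
    fragments = simulate_fragments(config.sim, sites=cohort.sites, out_dir=out / "inputs")
    write_config(config.sim, out / "config_echo.txt")

    logger.info("building consensus peaks (min_donors=%d)", config.min_donors)
    matrix = build_consensus(cohort.donors, min_donors=config.min_donors)
    write_consensus_bed(matrix, out / "consensus_peaks.bed", header=header)
    manifest["consensus_peaks.bed"] = len(matrix.peaks)
    peaks = IntervalCollection([p.interval for p in matrix.peaks], label="consensus")

    logger.info("occupancy differential test on %d peaks", len(matrix.peaks))
    results = occupancy_fisher(matrix)
    write_differential_tsv(results, out / "occupancy_differential.tsv", header=header)
    manifest["occupancy_differential.tsv"] = len(results)

    logger.info("annotating peaks against %d transcripts", len(ann.transcripts))
    records = annotate_peaks(peaks, ann.transcripts)
    write_annotation_tsv(records, out / "annotation.tsv", header=header)
    manifest["annotation.tsv"] = len(records)
    props = category_proportions(records)
    dists = distance_to_nearest_tss(peaks, ann.transcripts)
    with (out / "annotation_summary.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#category\tproportion\n")
        for cat, frac in props.items():
            fh.write(f"{cat}\t{frac:.6g}\n")
    manifest["annotation_summary.tsv"] = len(props)
    pd.DataFrame(
        {"peak_id": [p.id for p in peaks], "distance_to_tss": dists}
    ).to_csv(out / "tss_distances.tsv", sep="\t", index=False)
    manifest["tss_distances.tsv"] = len(peaks)

    logger.info("feature enrichment against the %.0f%% chance null", 100 * config.chance_fraction)
    from .enrichment import write_enrichment_tsv  # local import avoids a cycle at module load

    enr = enrichment_batch(peaks, list(feats.features.values()), config.chance_fraction)
    write_enrichment_tsv(enr, out / "enrichment.tsv", header=header)
    manifest["enrichment.tsv"] = len(enr)

    if "H3K4me1" in feats.features and "H3K27ac" in feats.features:
        states = classify_enhancer_state(peaks, feats.features["H3K4me1"], feats.features["H3K27ac"])
        with (out / "enhancer_states.tsv").open("w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write("#peak_id\tstate\n")
            for p, s in zip(peaks, states):
                fh.write(f"{p.id}\t{s}\n")
        manifest["enhancer_states.tsv"] = len(states)

    logger.info("SNP-in-peak overlap (r2>=%.2f, MAF>=%.3f)", config.r2_min, config.maf_min)
    snp_res = snp_in_peak(peaks, ann.snps, r2_min=config.r2_min, maf_min=config.maf_min)
    with (out / "snp_overlap.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#rsid\tpeak_id\tsnp_class\n")
        for rsid, pid in snp_res.index_hits:
            fh.write(f"{rsid}\t{pid}\tindex\n")
        for rsid, pid in snp_res.ld_hits:
            fh.write(f"{rsid}\t{pid}\tld\n")
    manifest["snp_overlap.tsv"] = len(snp_res.index_hits) + len(snp_res.ld_hits)

    if "DMR" in feats.features:
        pairs, n_distinct = dmr_overlap(peaks, feats.features["DMR"])
        with (out / "dmr_overlap.tsv").open("w") as fh:
            for line in header:
                fh.write(f"#{line}\n")
            fh.write(f"#distinct_peaks_with_dmr={n_distinct}\n")
            fh.write("#peak_id\tdmr_id\n")
            for pid, did in pairs:
                fh.write(f"{pid}\t{did}\n")
        manifest["dmr_overlap.tsv"] = len(pairs)

    logger.info("expression linkage (TPM threshold %.2f)", config.tpm_threshold)
    assignments = categorize_expression(ann.expression, tpm_threshold=config.tpm_threshold)
    assignments = flag_nearby_peaks(
        assignments, ann.transcripts, ann.expression_peaks, window_bp=config.proximity_window
    )
    write_assignments_tsv(assignments, out / "expression_link.tsv", header=header)
    manifest["expression_link.tsv"] = len(assignments)
    summary = expression_enrichment(assignments)
    with (out / "expression_summary.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        summary.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.6g")
    manifest["expression_summary.tsv"] = len(summary)

    logger.info("QC: fragment histogram and binned Spearman clustering")
    lengths = {
        d: (g["end"] - g["start"]).to_numpy()
        for d, g in fragments.groupby("donor_id")
    }
    hist = fragment_histogram(lengths)
    with (out / "qc_fragment_histogram.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        hist.reset_index(names="donor_id").to_csv(fh, sep="\t", index=False)
    manifest["qc_fragment_histogram.tsv"] = len(hist)
    corr, _, newick = binned_spearman_cluster(fragments, config.sim.chrom_sizes())
    with (out / "qc_correlation.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        corr.reset_index(names="donor_id").to_csv(fh, sep="\t", index=False, float_format="%.6g")
    manifest["qc_correlation.tsv"] = len(corr)
    (out / "qc_dendrogram.nwk").write_text(newick + "\n")
    manifest["qc_dendrogram.nwk"] = 1

    with (out / "manifest.tsv").open("w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        fh.write("#output\tn_rows\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    logger.info("pipeline complete: %d outputs in %s", len(manifest), out)
    return manifest
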