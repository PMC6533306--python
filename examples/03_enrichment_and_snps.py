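"""Feature-set enrichment, enhancer states and SNP-in-peak overlap.

Simulates feature sets covering known fractions of the latent sites, tests
each against the 5%-by-chance chi-square null, classifies enhancer states
from the two histone marks, and overlaps an LD-structured SNP table with
the consensus peaks after r2/MAF filtering.
"""

from occupeak import (
    IntervalCollection,
    build_consensus,
    classify_enhancer_state,
    enrichment_batch,
    snp_in_peak,
)
from occupeak.simulate import SimulationConfig, simulate_annotation_inputs, simulate_cohort, simulate_features

cfg = SimulationConfig(seed=1)
sim = simulate_cohort(cfg)
matrix = build_consensus(sim.donors, min_donors=3)
peaks = IntervalCollection([p.interval for p in matrix.peaks], label="consensus")

feats = simulate_features(cfg, sites=sim.sites)
for r in enrichment_batch(peaks, list(feats.features.values())):
    print(f"{r.feature:>10}: {r.n_overlap:>4}/{r.n_peaks} peaks overlap "
          f"(expected {r.expected:.0f} by chance), chi2={r.chi2:.1f}, "
          f"q={r.q:.2g}, {r.direction}")

states = classify_enhancer_state(peaks, feats.features["H3K4me1"], feats.features["H3K27ac"])
counts = {s: states.count(s) for s in ("active_enhancer", "inactive_enhancer", "neither")}
print("enhancer states (both marks = active, H3K4me1 alone = inactive):", counts)

ann = simulate_annotation_inputs(cfg, sites=sim.sites)
res = snp_in_peak(peaks, ann.snps, r2_min=0.8, maf_min=0.01)
print(f"SNPs inside peaks after filters: {res.n_index} index, {res.n_ld} LD proxies")
# Enrichment compares each observed overlap count with the fixed 5% chance
# expectation; features simulated at 30-40% site coverage come out strongly
# enriched, the 5%-level decoys do not.
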