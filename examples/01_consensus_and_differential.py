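"""Consensus peaks and the occupancy-based differential test.

Simulates a 6 T2D / 9 ND donor cohort over 1,000 latent accessible sites
(100 of them strongly differential), builds consensus peaks supported by at
least three donors, and tests each peak's presence/absence pattern between
the groups with a two-sided Fisher exact test (BH-adjusted).
"""

from occupeak import build_consensus, occupancy_fisher
from occupeak.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=1)
sim = simulate_cohort(cfg)
print(f"cohort: {sum(d.group == 'T2D' for d in sim.donors)} T2D, "
      f"{sum(d.group == 'ND' for d in sim.donors)} ND donors, "
      f"{len(sim.sites)} latent sites ({int(sim.truth.is_differential.sum())} differential)")

matrix = build_consensus(sim.donors, min_donors=3)
print(f"consensus peaks supported by >=3 donors: {len(matrix.peaks)}")

results = occupancy_fisher(matrix)
hits = [r for r in results if r.q < 0.05]
t2d_up = sum(r.direction == "T2D-enriched" for r in hits)
print(f"differential peaks at q<0.05: {len(hits)} "
      f"({t2d_up} T2D-enriched, {len(hits) - t2d_up} ND-enriched)")
best = min(results, key=lambda r: r.p)
print(f"strongest peak: {best.peak.id} present {best.n_present_t2d}/6 T2D vs "
      f"{best.n_present_nd}/9 ND, p={best.p:.3g}, q={best.q:.3g}")
# The hit count approximates the 100 truly differential sites; with this
# occupancy gap (0.95 vs 0.05) the test recovers most of them with few
# false positives.
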