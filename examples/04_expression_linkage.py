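"""Linking open chromatin to expression level.

Categorises transcripts into non-expressed (TPM < 0.1) plus three expression
tertiles, flags transcripts with a peak summit within 1,500 bp of their
span, and tests each tertile's proximity rate against the non-expressed
reference with a 2x2 chi-square.
"""

from occupeak import categorize_expression, expression_enrichment, flag_nearby_peaks
from occupeak.simulate import SimulationConfig, simulate_annotation_inputs

cfg = SimulationConfig(seed=1)
sim = simulate_annotation_inputs(cfg)

assignments = categorize_expression(sim.expression, tpm_threshold=cfg.tpm_threshold)
assignments = flag_nearby_peaks(
    assignments, sim.transcripts, sim.expression_peaks, window_bp=cfg.proximity_window
)
summary = expression_enrichment(assignments)
print(summary[["n", "n_with_peak", "proportion", "chi2", "q"]].round(4))
# The proportion-with-peak column rises monotonically from non- to
# high-expressed transcripts, reproducing the expected gradient: open
# chromatin concentrates near highly expressed genes. q-values are
# BH-adjusted across the three tertile tests.
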