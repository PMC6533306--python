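"""Annotating peaks to transcript elements with fixed upstream bins.

Builds a handful of peaks around one transcript and prints every record the
annotator emits: upstream bins (TSS-200 / TSS-1500 / TSS-50kb), exon,
intron, the downstream TTS window, and the intergenic fallback.
"""

from occupeak import GenomicInterval, IntervalCollection, TranscriptModel
from occupeak.annotation import annotate_peaks, category_proportions, distance_to_nearest_tss

tx = TranscriptModel(
    chrom="chr1", strand="+", tx_start=100_000, tx_end=110_000,
    exons=((100_000, 101_000), (105_000, 110_000)),
    transcript_id="TX1", gene_id="GENE1",
)
peaks = IntervalCollection([
    GenomicInterval("chr1", 99_900, 99_950, name="promoter_proximal"),  # 50-100 bp upstream
    GenomicInterval("chr1", 98_800, 99_900, name="straddles_two_bins"),
    GenomicInterval("chr1", 100_500, 100_600, name="exonic"),
    GenomicInterval("chr1", 103_000, 103_200, name="intronic"),
    GenomicInterval("chr1", 112_000, 112_300, name="downstream"),
    GenomicInterval("chr1", 400_000, 400_200, name="far_away"),
])

records = annotate_peaks(peaks, [tx])
for r in records:
    print(f"{r.peak_id:>20}  {r.category:<10} {r.transcript_id}")
print("record proportions:", {k: round(v, 3) for k, v in category_proportions(records).items()})
print("summit-to-nearest-TSS distances:", distance_to_nearest_tss(peaks, [tx]).tolist())
# A peak may carry several records (one per element it touches); a peak
# touching nothing yields exactly one intergenic record. Negative distances
# are upstream of the TSS in transcript orientation.
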