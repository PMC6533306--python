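"""Peak-to-element annotation: fixed upstream bins, strand correctness,
nearest-TSS distances — all checked against per-bp bitmap oracles."""

import numpy as np
import pytest

from occupeak.annotation import (
    AnnotationRecord,
    TranscriptModel,
    annotate_peaks,
    category_proportions,
    distance_to_nearest_tss,
    peak_primary_categories,
    read_transcripts_bed12,
)
from occupeak.intervals import GenomicInterval, IntervalCollection

from _oracles import paint_annotation_bitmap


def _tx(chrom="chr1", strand="+", start=10_000, end=15_000, exons=None,
        tid="t1", gid="g1"):
    exons = exons if exons is not None else ((start, end),)
    return TranscriptModel(chrom=chrom, strand=strand, tx_start=start, tx_end=end,
                           exons=tuple(exons), transcript_id=tid, gene_id=gid)


def _peaks(*spans):
    return IntervalCollection(
        [GenomicInterval("chr1", s, e, name=f"p{i}") for i, (s, e) in enumerate(spans)]
    )


class TestTranscriptModel:
    def test_tss_tts_strand_aware(self):
        plus = _tx(strand="+", start=100, end=200)
        minus = _tx(strand="-", start=100, end=200)
        assert (plus.tss, plus.tts) == (100, 199)
        assert (minus.tss, minus.tts) == (199, 100)

    def test_exon_validation(self):
        with pytest.raises(ValueError):
            _tx(exons=((10_500, 10_100),))
        with pytest.raises(ValueError):
            _tx(exons=((10_000, 12_000), (11_000, 13_000)))

    def test_bed12_roundtrip(self, tmp_path):
        p = tmp_path / "tx.bed12"
        p.write_text(
            "chr1\t1000\t5000\ttxA|geneA\t0\t-\t1000\t5000\t0\t2\t500,1000,\t0,3000,\n"
        )
        (t,) = read_transcripts_bed12(p)
        assert (t.tx_start, t.tx_end, t.strand) == (1000, 5000, "-")
        assert t.exons == ((1000, 1500), (4000, 5000))
        assert t.introns() == [(1500, 4000)]
        assert (t.transcript_id, t.gene_id) == ("txA", "geneA")


class TestAnnotatePeaks:
    def test_upstream_bin_assignment(self):
        """A peak 50-100 bp upstream of a + TSS at 1,000 falls in TSS-200."""
        t = _tx(start=1000, end=3000)
        records = annotate_peaks(_peaks((900, 950)), [t])
        assert {r.category for r in records} == {"TSS-200"}

    def test_window_straddle_emits_both_bins(self):
        t = _tx(start=1000, end=3000)
        records = annotate_peaks(_peaks((700, 901)), [t])  # 100-300 bp upstream
        assert {r.category for r in records} == {"TSS-200", "TSS-1500"}

    def test_peak_overlapping_tss_folds_into_most_proximal_bin(self):
        t = _tx(start=1000, end=3000)
        records = annotate_peaks(_peaks((995, 1005)), [t])
        assert "TSS-200" in {r.category for r in records}

    def test_intergenic_fallback_single_record(self):
        t = _tx(start=500_000, end=505_000)
        records = annotate_peaks(_peaks((100, 200)), [t])
        assert records == [AnnotationRecord(peak_id="p0", category="intergenic")]

    def test_multiple_transcript_annotations(self):
        ts = [_tx(start=10_000, end=15_000, tid="t1"),
              _tx(start=12_000, end=20_000, tid="t2", gid="g2")]
        records = annotate_peaks(_peaks((12_500, 12_600)), ts)
        assert {r.transcript_id for r in records} == {"t1", "t2"}

    def test_matches_bitmap_oracle(self, rng):
        """Random peaks vs random transcripts agree with a per-bp painter."""
        chrom_len = 120_000
        for trial in range(12):
            transcripts = []
            for i in range(6):
                start = int(rng.integers(5_000, chrom_len - 20_000))
                span = int(rng.integers(2_000, 15_000))
                strand = "+" if rng.random() < 0.5 else "-"
                n_ex = int(rng.integers(1, 4))
                if n_ex == 1:
                    exons = ((start, start + span),)
                else:
                    bps = np.sort(rng.choice(np.arange(1, span), 2 * n_ex - 2, replace=False))
                    bounds = [0, *bps.tolist(), span]
                    exons = tuple((start + bounds[2 * e], start + bounds[2 * e + 1])
                                  for e in range(n_ex))
                transcripts.append(_tx(start=start, end=start + span, strand=strand,
                                       exons=exons, tid=f"t{i}"))
            peaks = IntervalCollection(
                [GenomicInterval("chr1", s, s + int(rng.integers(50, 2_000)), name=f"p{j}")
                 for j, s in enumerate(rng.integers(0, chrom_len - 2_000, size=40))]
            )
            got = {(r.peak_id, r.category, r.transcript_id) for r in annotate_peaks(peaks, transcripts)}
            expected = set()
            masks = {t.transcript_id: paint_annotation_bitmap(t, chrom_len) for t in transcripts}
            for peak in peaks:
                hit_any = False
                for t in transcripts:
                    for cat, mask in masks[t.transcript_id].items():
                        if mask[peak.start : peak.end].any():
                            expected.add((peak.id, cat, t.transcript_id))
                            hit_any = True
                if not hit_any:
                    expected.add((peak.id, "intergenic", ""))
            assert got == expected, f"trial {trial}"

    def test_strand_mirror_symmetry(self, rng):
        """Mirroring transcripts and peaks about a point reproduces mirrored records."""
        axis = 200_000
        t = _tx(start=50_000, end=60_000, strand="+",
                exons=((50_000, 52_000), (55_000, 60_000)))
        mirrored = TranscriptModel(
            chrom="chr1", strand="-",
            tx_start=axis - t.tx_end, tx_end=axis - t.tx_start,
            exons=tuple(sorted((axis - e, axis - s) for s, e in t.exons)),
            transcript_id="t1", gene_id="g1",
        )
        for _ in range(25):
            s = int(rng.integers(0, 120_000))
            ln = int(rng.integers(50, 3_000))
            fwd = annotate_peaks(_peaks((s, s + ln)), [t])
            rev = annotate_peaks(
                IntervalCollection([GenomicInterval("chr1", axis - s - ln, axis - s, name="p0")]),
                [mirrored],
            )
            assert {r.category for r in fwd} == {r.category for r in rev}


class TestDistanceToNearestTss:
    def test_summit_at_tss_is_zero(self):
        t = _tx(start=1000, end=3000)
        peaks = IntervalCollection([GenomicInterval("chr1", 900, 1101)])  # midpoint 1000
        assert distance_to_nearest_tss(peaks, [t])[0] == 0

    def test_minus_strand_upstream_is_negative(self):
        t = _tx(strand="-", start=1000, end=3000)  # TSS at 2999
        peaks = IntervalCollection([GenomicInterval("chr1", 3449, 3550)])  # summit 3499
        assert distance_to_nearest_tss(peaks, [t])[0] == -500

    def test_no_transcript_chromosome_is_nan(self):
        t = _tx()
        peaks = IntervalCollection([GenomicInterval("chr9", 100, 200)])
        assert np.isnan(distance_to_nearest_tss(peaks, [t])[0])

    def test_matches_all_pairs_scan(self, rng):
        transcripts = [
            _tx(start=int(s), end=int(s) + 1000, strand=("+" if rng.random() < 0.5 else "-"),
                tid=f"t{i}")
            for i, s in enumerate(rng.integers(0, 500_000, size=30))
        ]
        peaks = IntervalCollection(
            [GenomicInterval("chr1", int(s), int(s) + 100, name=f"p{j}")
             for j, s in enumerate(rng.integers(0, 500_000, size=100))]
        )
        got = distance_to_nearest_tss(peaks, transcripts)
        for j, peak in enumerate(peaks):
            summit = peak.effective_summit()
            best = min(transcripts, key=lambda t: abs(summit - t.tss))
            expected = summit - best.tss if best.strand == "+" else best.tss - summit
            assert abs(got[j]) == abs(summit - best.tss)
            # sign follows the orientation of *some* nearest transcript (ties allowed)
            candidates = {t for t in transcripts if abs(summit - t.tss) == abs(summit - best.tss)}
            signs = {(summit - t.tss if t.strand == "+" else t.tss - summit) for t in candidates}
            assert got[j] in signs


class TestCategorySummaries:
    def test_proportions(self):
        recs = [AnnotationRecord("p0", "exon"), AnnotationRecord("p0", "intron"),
                AnnotationRecord("p1", "exon"), AnnotationRecord("p2", "intron")]
        props = category_proportions(recs)
        assert props == {"exon": 0.5, "intron": 0.5}
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_intergenic(self):
        recs = [AnnotationRecord(f"p{i}", "intergenic") for i in range(3)]
        assert category_proportions(recs) == {"intergenic": 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            category_proportions([])

    def test_precedence_summary(self):
        recs = [AnnotationRecord("p0", "TSS-50kb"), AnnotationRecord("p0", "exon"),
                AnnotationRecord("p1", "TTS"), AnnotationRecord("p1", "intron")]
        assert peak_primary_categories(recs) == {"p0": "exon", "p1": "intron"}
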