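# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the tests demonstrate.

## Coordinates and overlap conventions

All internal coordinates are 0-based half-open (BED convention). SNP tables
arrive 1-based, as GWAS/LD tooling emits them, and are converted exactly
once, at overlap time. Chromosome names are compared as exact strings — no
implicit `chr`-prefix normalisation, because silent renaming hides input
errors. Overlap requires ≥ 1 shared base by default (`min_bp` is exposed;
no published threshold exists for these intersections, and 1 bp is the
permissive standard). Book-ended intervals (gap 0 under half-open
coordinates) merge at `max_gap = 0`, matching the bedtools-merge dialect.
Strand is ignored by all overlap operations and used only by annotation:
accessibility is unstranded.

## Consensus peaks and the occupancy test

"Supported by at least *k* donors" is operationalised as: merge the pooled
peaks of all donors into candidate regions; a donor supports a region if
any of its peaks overlaps it by ≥ 1 bp; keep regions with ≥ *k* supporters
(default 3). This union-merge-plus-recount reading is the simplest faithful
one and is invariant to donor input order. A `donor_subset` parameter
builds per-group peak universes (ND-only, T2D-only) with the same rule.

The occupancy test is the two-sided Fisher exact test on each peak's
(present/absent) × (T2D/ND) table — two-sided because both directions of
prevalence are of interest. Group sizes are constant across peaks, so
p-values are memoised on the presence-count pair; a cohort of any size
costs at most (n₁+1)(n₂+1) distinct exact tests. Multiple testing uses
Benjamini–Hochberg (the field default where a specific FDR procedure is
unnamed), significance q < 0.05. Direction ties (equal presence fractions)
are labelled `none` rather than arbitrarily assigned. Sex and fresh/frozen
treatment are carried as metadata but deliberately not modelled: covariate
adjustment belongs to read-count (affinity) models, which this package
consumes as external tables (`intersect_differential`) and never fits.

The test suite verifies the Fisher p-values against full-table enumeration
in exact integer arithmetic (numerators C(n₁,k)·C(n₂,K−k) compared as
integers, so probability ties are tie-broken without floating-point error)
for every table with both group sizes ≤ 15; observed agreement is at
machine precision (~3×10⁻¹⁶).

## Enrichment null

Feature-set enrichment uses the declared fixed-chance null: 5% of peaks are
expected to overlap any feature by chance, tested with an uncorrected 1-df
Pearson goodness-of-fit chi-square (continuity correction is a modelling
choice not taken; the uncorrected form is the plain Pearson statistic of
the declared test). This null ignores the feature's genomic footprint — it
is exposed as `chance_fraction` rather than silently "improved".
Permutation-based genomic nulls (GAT/regioneR-style) are a deliberate
non-goal. Under a binomial simulation at the chance rate the test's
rejection rate at p < 0.05 is ≈ 5%, as the calibration test asserts.

Enhancer classification follows the two-mark rule: H3K4me1 ∧ H3K27ac →
active enhancer, H3K4me1 alone → inactive enhancer, anything else
(including H3K27ac alone) → neither. The three states partition the peaks.

Index SNPs bypass the r² filter because they are tested directly, separately
from their LD proxies; proxies require r² ≥ 0.8 and everything requires
MAF ≥ 0.01 by default.

## Annotation bins

Upstream bins are measured 5′-ward of the TSS along transcript strand:
1–200, 201–1,500 and 1,501–50,000 bp; the TTS window is 1–10,000 bp
3′-ward of the termination site. A peak overlapping the TSS base itself is
folded into TSS-200 (the bins as published start at 1 bp and leave
TSS-overlap unassigned; the most-proximal bin is the least surprising
home). No category precedence is applied by default — a peak emits all
matching records, so one peak can annotate to several genes. For
figure-style one-category-per-peak summaries an explicit precedence
(TSS-200 > TSS-1500 > exon > intron > TTS > TSS-50kb > intergenic) is
available behind `peak_primary_categories`; since published proportion
denominators are generally unstated, both modes are offered and neither is
asserted as canonical. Transcript models are read from BED12, the simplest
standard carrier of exon structure; GTF conversion is out of scope.

Nearest-TSS distances are signed from the peak's effective summit (the
narrowPeak summit when present, else the interval midpoint, floor division)
— negative upstream of the TSS in transcript orientation.

## Expression linkage

Transcripts below TPM 0.1 are non-expressed; the rest are rank-split into
three contiguous tertiles whose sizes differ by at most one, with a stable
(tpm, transcript_id) sort for deterministic ties. At the reference cohort
scale (60,517 transcripts, 38,428 non-expressed) the split is exactly
3 × 7,363. "Within 1,500 bp of a peak summit" is read as summit-to-span
distance (0 when the summit falls inside the transcript), the most literal
reading; a summit-to-TSS mode sits behind `mode="tss"`. Each tertile is
tested against the non-expressed reference with an uncorrected 2×2 Pearson
chi-square, BH-adjusted across the three tests; the reference choice is a
design decision (the published contrast is expressed versus non-expressed
proportions), and the fixed-chance null remains available through the
enrichment module for symmetry.

## QC

QC consumes fragment interval/length tables, not alignments — keeping the
package download-free; a BAM adapter is out of scope. Binned correlation
counts fragment midpoints (whether published analyses counted reads or
fragments per bin is unstated; midpoints are used and documented here) in
consecutive 10-kb bins, excludes chrY, and uses Spearman correlation with
average ranks on ties and average-linkage clustering on 1 − ρ — the common
defaults of deepTools-style sample comparison. The dendrogram is emitted as
Newick with branch lengths from the linkage heights.

## The synthetic-data generator

The generator defines the study conditions the tests run under:

* **Design.** 6 T2D vs 9 ND donors (the target study's design); 1,000
  latent accessible sites on a 4 × 2 Mb toy genome; 10% of sites
  differential at occupancy 0.95 (T2D) vs 0.05 (ND); all other sites at a
  0.5/0.5 baseline. Peak widths ~ N(400, 50²) bp (floor 50), start jitter
  ~ N(0, 50²), summit at the site centre. Sites sit on a jittered grid
  spaced so that neighbouring donors' peaks can never merge across sites —
  this is what makes ground-truth recounting exact, and a guard raises if a
  config violates it.
* **Streams.** One named RNG stream per artifact (sites, cohort, features,
  annotation, expression, snps, fragments), all derived from one master
  seed, so regenerating one input leaves the others untouched. Identical
  configs yield byte-identical files.
* **Features.** Each feature set covers a configured fraction of site
  centres plus decoy intervals placed midway between sites (provably
  non-overlapping); C1–C5-style classes are drawn mutually exclusively from
  one permutation.
* **Expression.** Category counts are assigned exactly from the published
  proportions (38,428/60,517 non-expressed, remainder split in three), then
  TPMs are drawn per category: uniform below 0.1 for non-expressed and
  log-normal components truncated to disjoint ranges (0.1–1, 1–10,
  10–1,000) for the tertiles. The disjoint ranges keep rank-derived
  tertiles aligned with the generating labels, which is what lets tests
  assert exact label recovery; the price is zero between-category TPM
  overlap, which real data has.
* **Proximity.** Transcripts sit on a grid wide enough (guard enforced)
  that a peak placed near one transcript cannot fall within the proximity
  window of another, so per-transcript proximity labels are independent
  Bernoulli draws at each category's probability (defaults 0.1 / 0.4 / 0.6
  / 0.8 for non/low/medium/high).
* **SNPs.** LD groups of 6 share an index SNP; proxies sit within ±100 bp
  of it with r² ~ U(0.5, 1), all MAFs ~ U(0, 0.5), and 40% of groups are
  anchored at site centres (in peaks).
* **Fragments.** Length mixture with modes near 60/200/390/580 bp
  (sub-nucleosomal through tri-nucleosomal); 80% of midpoints concentrate
  around site centres, plus a small chrY component to exercise exclusion.

What passing tests therefore show: the pipeline's operations implement
their definitions exactly (oracle agreement), the Fisher machinery is
exact, calibration holds under the declared nulls, and the full path
recovers strong planted effects at the study's sample sizes. What they do
not show: performance on real data with overlapping site structure,
correlated peaks, donor-specific peak-calling artefacts, GC/mappability
structure, or expression distributions with overlapping categories — none
of which the generator emulates.

## Problem sizes and determinism

Default analyses run at 1,000 sites × 15 donors, 600 transcripts, 180 SNPs
and 2,000 fragments per donor — sizes chosen so every stage and the
end-to-end pipeline complete in seconds while keeping the donor design and
effect structure of the target study. The null-calibration check uses
5,000 peaks; the Fisher-exactness sweep covers all 18,225 tables with group
sizes ≤ 15. All randomness flows from explicit seeds; pipeline outputs are
timestamp-free (logs go to stderr) and carry a version + config-hash
header, so reruns of the same config are byte-identical.

## Known limitations

* The occupancy test ignores covariates by design; confounding by sex or
  treatment would require the external affinity-model route.
* The fixed 5% chance null is a declared convention, not a genomic null;
  enrichment q-values should be read accordingly.
* The consensus rule resolves region boundaries by union-merge; alternative
  consensus definitions (majority-vote boundaries, iterative re-merging per
  donor subset) can shift peak counts on real, densely overlapping data.
* Published per-group peak universes may or may not re-merge per group;
  both modes exist here (`donor_subset`), neither is asserted as canonical.
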