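"""Consensus construction and the occupancy Fisher test, checked against
exact enumeration and a ground-truth recount on simulated cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from occupeak.consensus import (
    ConsensusPeak,
    DonorPeakSet,
    OccupancyMatrix,
    bh_fdr,
    build_consensus,
    intersect_differential,
    occupancy_fisher,
)
from occupeak.intervals import GenomicInterval, IntervalCollection
from occupeak.simulate import SimulationConfig, simulate_cohort

from _oracles import bh_stepup, fisher_two_sided_exact


def _donor(donor_id, group, spans):
    return DonorPeakSet(
        donor_id=donor_id, group=group,
        peaks=IntervalCollection([GenomicInterval("chr1", s, e) for s, e in spans]),
    )


def _matrix_from_presence(present, n_t2d, n_nd):
    """Occupancy matrix with one synthetic peak per row of ``present``."""
    present = np.asarray(present, dtype=bool)
    donors = [
        DonorPeakSet(donor_id=f"T2D_{i}", group="T2D") for i in range(n_t2d)
    ] + [DonorPeakSet(donor_id=f"ND_{i}", group="ND") for i in range(n_nd)]
    keep = present.sum(axis=1) >= 1
    present = present[keep]
    peaks = [
        ConsensusPeak(
            interval=GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100),
            supporting_donors=frozenset(
                donors[j].donor_id for j in np.flatnonzero(present[i])
            ),
        )
        for i in range(present.shape[0])
    ]
    return OccupancyMatrix(peaks=peaks, donors=donors, present=present)


class TestBuildConsensus:
    def test_identical_peak_in_all_donors(self):
        donors = [_donor(f"d{i}", "ND" if i % 2 else "T2D", [(100, 200)]) for i in range(5)]
        matrix = build_consensus(donors, min_donors=3)
        assert len(matrix.peaks) == 1
        assert matrix.peaks[0].n_support == 5
        assert (matrix.peaks[0].interval.start, matrix.peaks[0].interval.end) == (100, 200)

    def test_below_threshold_excluded(self):
        donors = [_donor(f"d{i}", "ND", [(100, 200)] if i < 2 else [(5000, 5100)]) for i in range(9)]
        matrix = build_consensus(donors, min_donors=3)
        spans = [(p.interval.start, p.interval.end) for p in matrix.peaks]
        assert (100, 200) not in spans and (5000, 5100) in spans

    def test_validation_errors(self):
        donors = [_donor(f"d{i}", "ND", [(0, 10)]) for i in range(4)]
        with pytest.raises(ValueError):
            build_consensus(donors, min_donors=5)
        with pytest.raises(ValueError):
            build_consensus(donors, min_donors=0)
        with pytest.raises(ValueError):
            build_consensus(donors + [_donor("d0", "ND", [(0, 10)])])

    def test_recount_against_generator_truth(self):
        """Retained peaks equal a site-by-site recount of donor support."""
        cfg = SimulationConfig(seed=5, n_sites=50, n_chroms=1, baseline_occupancy=0.9,
                               differential_fraction=0.0)
        sim = simulate_cohort(cfg)
        matrix = build_consensus(sim.donors, min_donors=3)
        # oracle: a site is retained iff >= 3 donors have a peak overlapping
        # the merged region; with well-separated sites that is just the
        # realized per-site presence count
        support = sim.presence.sum(axis=1)
        expected = int((support >= 3).sum())
        assert len(matrix.peaks) == expected
        realized = {i for i in range(len(sim.sites)) if support[i] >= 3}
        for peak in matrix.peaks:
            covered = [
                i for i, (c, p) in enumerate(sim.sites)
                if c == peak.interval.chrom and peak.interval.start <= p < peak.interval.end
            ]
            assert len(covered) == 1 and covered[0] in realized
            assert peak.n_support == support[covered[0]]

    def test_invariant_to_donor_order(self, small_cohort):
        fwd = build_consensus(small_cohort.donors, min_donors=3)
        rev = build_consensus(small_cohort.donors[::-1], min_donors=3)
        assert [(p.interval.chrom, p.interval.start, p.interval.end, p.supporting_donors)
                for p in fwd.peaks] == [
            (p.interval.chrom, p.interval.start, p.interval.end, p.supporting_donors)
            for p in rev.peaks]

    def test_donor_subset_builds_group_universe(self, small_cohort):
        nd_ids = [d.donor_id for d in small_cohort.donors if d.group == "ND"]
        matrix = build_consensus(small_cohort.donors, min_donors=3, donor_subset=nd_ids)
        assert {d.donor_id for d in matrix.donors} == set(nd_ids)
        assert all(p.n_support >= 3 for p in matrix.peaks)


class TestOccupancyFisher:
    def test_six_of_six_vs_zero_of_nine(self):
        """The all-or-nothing 6 vs 9 split: p = 1/5005."""
        present = [[True] * 6 + [False] * 9]
        res = occupancy_fisher(_matrix_from_presence(present, 6, 9))
        assert res[0].p == pytest.approx(1 / 5005, rel=1e-12)
        assert res[0].direction == "T2D-enriched"
        assert (res[0].n_present_t2d, res[0].n_absent_t2d) == (6, 0)
        assert (res[0].n_present_nd, res[0].n_absent_nd) == (0, 9)

    def test_near_equal_fractions(self):
        present = [[True] * 3 + [False] * 3 + [True] * 4 + [False] * 5]
        res = occupancy_fisher(_matrix_from_presence(present, 6, 9))
        assert res[0].p == pytest.approx(fisher_two_sided_exact(3, 6, 4, 9), rel=1e-12)
        assert res[0].p > 0.9
        assert res[0].direction == "T2D-enriched"  # 0.5 vs 0.444

    def test_all_present_degenerate(self):
        present = [[True] * 15] * 4
        res = occupancy_fisher(_matrix_from_presence(present, 6, 9))
        assert all(r.p == 1 and r.q == 1 and r.direction == "none" for r in res)

    def test_matches_enumeration_for_study_margins(self):
        """Exact agreement with full-table enumeration on the 6 + 9 design."""
        for k1 in range(7):
            for k2 in range(10):
                present = [[True] * k1 + [False] * (6 - k1) + [True] * k2 + [False] * (9 - k2)]
                if k1 + k2 == 0:
                    continue
                res = occupancy_fisher(_matrix_from_presence(present, 6, 9))
                assert res[0].p == pytest.approx(
                    fisher_two_sided_exact(k1, 6, k2, 9), abs=1e-12
                ), (k1, k2)

    def test_single_group_errors(self):
        present = [[True] * 6]
        with pytest.raises(ValueError):
            occupancy_fisher(_matrix_from_presence(present, 6, 0))


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_is_monotone(self, pvals):
        q = bh_fdr(pvals)
        np.testing.assert_allclose(q, bh_stepup(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12) and np.all(q <= 1)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestIntersectDifferential:
    def _results(self, spans_and_q):
        present = [[True] * 6 + [False] * 9] * len(spans_and_q)
        matrix = _matrix_from_presence(present, 6, 9)
        res = occupancy_fisher(matrix)
        out = []
        for r, (span, q) in zip(res, spans_and_q):
            iv = GenomicInterval("chr1", span[0], span[1])
            peak = ConsensusPeak(interval=iv, supporting_donors=r.peak.supporting_donors)
            out.append(type(r)(peak, r.n_present_t2d, r.n_absent_t2d, r.n_present_nd,
                               r.n_absent_nd, r.direction, r.p, q))
        return out

    def test_empty_affinity_table(self):
        res = self._results([((100, 200), 0.01)])
        table = pd.DataFrame(columns=["chrom", "start", "end", "significant"])
        assert intersect_differential(res, table) == []

    def test_identity(self):
        res = self._results([((100, 200), 0.01), ((500, 700), 0.02)])
        table = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 500], "end": [200, 700],
             "significant": [True, True]}
        )
        assert sorted(intersect_differential(res, table)) == sorted(r.peak.id for r in res)

    def test_partial_coverage_counts(self, rng):
        spans = [(1000 * i, 1000 * i + 300) for i in range(1, 21)]
        res = self._results([(s, 0.01) for s in spans])
        covered = sorted(rng.choice(20, size=7, replace=False))
        table = pd.DataFrame(
            {"chrom": "chr1",
             "start": [spans[i][0] + 100 for i in covered],
             "end": [spans[i][0] + 150 for i in covered],
             "significant": True}
        )
        hits = intersect_differential(res, table)
        assert len(hits) == 7
        assert set(hits) == {res[i].peak.id for i in covered}

    def test_q_threshold_and_missing_columns(self):
        res = self._results([((100, 200), 0.5)])
        table = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        assert intersect_differential(res, table, q_threshold=0.05) == []
        with pytest.raises(ValueError):
            intersect_differential(res, pd.DataFrame({"chrom": ["chr1"]}))
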