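import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xpsweep as x
from xpsweep.core import ValidationError
from xpsweep.permutation import empirical_p, normal_p

from conftest import random_peakset


class TestCountOverlapping:
    def test_partial_overlap_counted_once(self, layout_small):
        q = x.PeakSet([x.Peak("chr1", 0, 10), x.Peak("chr1", 20, 30)], layout_small)
        r = x.PeakSet([x.Peak("chr1", 5, 6)], layout_small)
        assert x.count_overlapping(q, r) == 1

    def test_empty_query(self, layout_small):
        r = x.PeakSet([x.Peak("chr1", 5, 6)], layout_small)
        assert x.count_overlapping(x.PeakSet([], layout_small), r) == 0

    def test_self_overlap(self, layout_small):
        q = x.PeakSet([x.Peak("chr1", 0, 10), x.Peak("chr2", 100, 400)], layout_small)
        assert x.count_overlapping(q, q) == len(q)

    def test_bounded_by_query_size(self, layout_small):
        rng = np.random.default_rng(0)
        q = random_peakset(layout_small, 30, rng)
        r = random_peakset(layout_small, 50, rng)
        assert x.count_overlapping(q, r) <= len(q)

    def test_book_ended_not_overlapping(self, layout_small):
        q = x.PeakSet([x.Peak("chr1", 0, 10)], layout_small)
        r = x.PeakSet([x.Peak("chr1", 10, 20)], layout_small)
        assert x.count_overlapping(q, r) == 0

    def test_matches_bruteforce_pairwise(self, layout_small):
        rng = np.random.default_rng(1)
        for _ in range(30):
            q = random_peakset(layout_small, int(rng.integers(1, 20)), rng)
            r = random_peakset(layout_small, int(rng.integers(1, 20)), rng)
            expected = sum(any(a.overlaps(b) for b in r) for a in q)
            assert x.count_overlapping(q, r) == expected

    def test_layout_mismatch_rejected(self, layout_small):
        other = x.make_genome_layout(1, [500])
        with pytest.raises(ValidationError):
            x.count_overlapping(x.PeakSet([], layout_small), x.PeakSet([], other))


class TestSampleRandomRegions:
    def test_sizes_preserved(self, layout_small):
        rng = np.random.default_rng(2)
        sizes = [100, 5000, 70_000, 100, 999_999]
        ps = x.sample_random_regions(layout_small, sizes, rng)
        assert sorted(ps.sizes()) == sorted(sizes)

    def test_forced_placement_whole_chromosome(self):
        layout = x.make_genome_layout(1, [1000])
        rng = np.random.default_rng(3)
        ps = x.sample_random_regions(layout, [1000], rng)
        assert (ps.peaks[0].start, ps.peaks[0].end) == (0, 1000)

    def test_oversized_region_rejected(self, layout_small):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            x.sample_random_regions(layout_small, [3_000_000], rng)

    def test_regions_stay_in_bounds(self, layout_small):
        rng = np.random.default_rng(5)
        ps = x.sample_random_regions(layout_small, [900_000] * 50, rng)
        for p in ps:
            assert 0 <= p.start and p.end <= layout_small.length(p.chrom)

    def test_start_distribution_uniform(self):
        # 1-bp regions on a single chromosome: chi-square goodness of fit
        # over binned starts should not reject uniformity at alpha = 0.01
        layout = x.make_genome_layout(1, [1_000_000])
        rng = np.random.default_rng(6)
        ps = x.sample_random_regions(layout, [1] * 100_000, rng)
        starts = np.array([p.start for p in ps])
        counts, _ = np.histogram(starts, bins=20, range=(0, 1_000_000))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_chromosome_choice_proportional_to_valid_starts(self):
        layout = x.make_genome_layout(2, [100_000, 300_000])
        rng = np.random.default_rng(7)
        ps = x.sample_random_regions(layout, [1000] * 20_000, rng)
        n_chr2 = sum(p.chrom == "chr2" for p in ps)
        expected = 20_000 * (300_000 - 999) / ((100_000 - 999) + (300_000 - 999))
        assert abs(n_chr2 - expected) < 4 * np.sqrt(20_000 * 0.25)


class TestPermuteOverlapTest:
    def test_z_arithmetic(self):
        # observed 10, permutation mean 4, sd 2 -> Z = 3
        assert (10 - 4) / 2 == 3  # the identity the result must satisfy
        nulls = np.array([2.0, 4.0, 6.0])  # mean 4, sample sd 2
        from xpsweep.permutation import _summarize
        r = _summarize(10, nulls, seed=0)
        assert r.z == pytest.approx(3.0)
        assert r.p_normal == pytest.approx(2 * stats.norm.sf(3))

    def test_reference_covering_genome_degenerate(self, layout_small):
        rng = np.random.default_rng(8)
        q = random_peakset(layout_small, 10, rng)
        full = x.PeakSet([x.Peak(c, 0, layout_small.length(c))
                          for c in layout_small.names], layout_small)
        r = x.permute_overlap_test(q, full, n_perm=50, seed=1)
        assert r.observed == len(q)
        assert r.degenerate
        assert np.isnan(r.z) and np.isnan(r.p_normal)
        assert 0 <= r.p_empirical <= 1  # empirical p still reported

    def test_same_seed_reproducible(self, layout_small):
        rng = np.random.default_rng(9)
        q = random_peakset(layout_small, 15, rng)
        r = random_peakset(layout_small, 25, rng)
        a = x.permute_overlap_test(q, r, n_perm=100, seed=5)
        b = x.permute_overlap_test(q, r, n_perm=100, seed=5)
        assert a == b

    def test_enriched_query_gets_large_z(self, layout_small):
        # a query equal to the reference overlaps far more than chance
        rng = np.random.default_rng(10)
        ref = random_peakset(layout_small, 20, rng, 5000, 20_000)
        res = x.permute_overlap_test(ref, ref, n_perm=100, seed=2)
        assert res.observed == len(ref)
        assert res.z > 3

    def test_empirical_p_floor(self, layout_small):
        rng = np.random.default_rng(11)
        ref = random_peakset(layout_small, 20, rng, 5000, 20_000)
        res = x.permute_overlap_test(ref, ref, n_perm=200, seed=3)
        assert res.p_empirical >= 1 / 200


class TestEmpiricalP:
    def test_two_tailed_doubling(self):
        nulls = np.arange(100, dtype=float)
        # observed at the 90th value: F = 0.91, p = 2 * 0.09 = 0.18
        assert empirical_p(nulls, 90.0) == pytest.approx(0.18)

    def test_floor_when_beyond_all(self):
        nulls = np.arange(100, dtype=float)
        assert empirical_p(nulls, 1000.0) == pytest.approx(1 / 100)
        assert empirical_p(nulls, -5.0) == pytest.approx(1 / 100)


class TestZtoP:
    def test_z2_matches_nominal_005(self):
        # a Z of 2 corresponds to a two-sided normal p of ~0.0455
        assert round(normal_p(2.0), 4) == 0.0455
        assert round(normal_p(-2.0), 4) == 0.0455


class TestGwasOverlap:
    def test_underpowered_trait_skipped(self, layout_small):
        rng = np.random.default_rng(12)
        peaks = random_peakset(layout_small, 10, rng)
        pts = x.make_gwas_points(layout_small, ["big"], 300, seed=1)
        small = x.make_gwas_points(layout_small, ["small"], 299, seed=2)
        res = x.gwas_overlap_test(peaks, pd.concat([pts, small]),
                                  min_points=300, n_perm=20, seed=3)
        assert set(res) == {"big"}

    def test_no_qualifying_trait_empty(self, layout_small, caplog):
        rng = np.random.default_rng(13)
        peaks = random_peakset(layout_small, 5, rng)
        pts = x.make_gwas_points(layout_small, ["t"], 10, seed=1)
        with caplog.at_level("WARNING"):
            res = x.gwas_overlap_test(peaks, pts, min_points=300, n_perm=10, seed=0)
        assert res == {}

    def test_observed_bounded_by_peak_count(self, layout_small):
        rng = np.random.default_rng(14)
        peaks = random_peakset(layout_small, 8, rng)
        pts = x.make_gwas_points(layout_small, ["t"], 400,
                                 enriched_regions=peaks,
                                 enrichment_fraction=1.0, seed=5)
        res = x.gwas_overlap_test(peaks, pts, min_points=300, n_perm=50, seed=6)
        assert res["t"].observed <= len(peaks)

    def test_enrichment_raises_z(self, layout_small):
        # mean Z over seeds strictly larger with clustered points
        rng = np.random.default_rng(15)
        peaks = random_peakset(layout_small, 12, rng, 10_000, 40_000)
        z_enr, z_null = [], []
        for seed in range(8):
            enr = x.make_gwas_points(layout_small, ["t"], 300, peaks, 0.8, seed=seed)
            nul = x.make_gwas_points(layout_small, ["t"], 300,
                                     enrichment_fraction=0.0, seed=seed + 100)
            z_enr.append(x.gwas_overlap_test(peaks, enr, 300, 100, seed)["t"].z)
            z_null.append(x.gwas_overlap_test(peaks, nul, 300, 100, seed)["t"].z)
        assert np.mean(z_enr) > np.mean(z_null)


@pytest.fixture(scope="module")
def toy_tracks():
    layout = x.make_genome_layout(1, [1_000_000])
    rng = np.random.default_rng(16)
    tracks = []
    for _ in range(4):
        n = 800
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), size=n, replace=False))
        score = rng.normal(0, 2, size=n)
        tracks.append(x.ScoreTrack(pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "score": score})))
    return layout, tracks[:2], tracks[2:]


class TestGridScan:
    def test_grid_shape_and_counts(self, toy_tracks):
        layout, qa, qb = toy_tracks
        grid = x.grid_scan(qa, qb, [(3.0, 1.5), (4.0, 1.5)], [(3.0, 1.5), (3.5, 2.0)],
                           layout, n_perm=20, seed=1)
        assert len(grid.results) == 2 and len(grid.results[0]) == 2
        assert len(grid.n_peaks_query) == 2 and len(grid.n_peaks_reference) == 2
        # peak counts non-increasing as t_high rises with t_low fixed
        assert grid.n_peaks_query[0] >= grid.n_peaks_query[1]

    def test_cell_equals_independent_run(self, toy_tracks):
        layout, qa, qb = toy_tracks
        grid = x.grid_scan(qa, qb, [(3.0, 1.5)], [(3.0, 1.5)], layout,
                           n_perm=30, seed=9)
        cell = grid.results[0][0]
        q = x.merge_peaks([x.call_peaks(t, 3.0, 1.5, layout, use_absolute=True,
                                        statistic="query") for t in qa], layout)
        r = x.merge_peaks([x.call_peaks(t, 3.0, 1.5, layout, statistic="reference")
                           for t in qb], layout)
        solo = x.permute_overlap_test(q, r, 30, x.derive_seed(9, "grid", 0, 0),
                                      label="q0_r0")
        assert cell == solo

    def test_invalid_threshold_pair_rejected(self, toy_tracks):
        layout, qa, qb = toy_tracks
        with pytest.raises(ValidationError):
            x.grid_scan(qa, qb, [(1.0, 2.0)], [(3.0, 1.5)], layout, n_perm=5, seed=0)

    def test_long_format_frame(self, toy_tracks):
        layout, qa, qb = toy_tracks
        grid = x.grid_scan(qa, qb, [(3.0, 1.5), (4.0, 2.0)], [(3.0, 1.5)],
                           layout, n_perm=10, seed=2)
        df = grid.to_frame()
        assert len(df) == 2
        assert {"query_t_high", "ref_t_low", "z", "p_empirical"} <= set(df.columns)


class TestSelectThresholds:
    def _grid(self, means, zs, obs):
        from xpsweep.permutation import _summarize
        results = []
        for i in range(len(means)):
            row = []
            for j in range(len(means[0])):
                nulls = np.random.default_rng(i * 10 + j).normal(
                    means[i][j], 1.0, size=50)
                nulls = nulls - nulls.mean() + means[i][j]  # force exact mean
                sd = nulls.std(ddof=1)
                r = _summarize(means[i][j] + zs[i][j] * sd, nulls, seed=0)
                r.observed = obs[i][j]
                row.append(r)
            results.append(row)
        return x.EnrichmentGrid(
            thresholds_query=[(3.0 + i, 1.5) for i in range(len(means))],
            thresholds_reference=[(3.0 + j, 1.5) for j in range(len(means[0]))],
            results=results,
            n_peaks_query=[10] * len(means),
            n_peaks_reference=[10] * len(means[0]))

    def test_argmin_of_permutation_mean(self):
        grid = self._grid([[3, 1], [5, 2]], [[1, 1], [1, 1]], [[5, 5], [5, 5]])
        sel = x.select_thresholds(grid)
        assert sel == ((3.0, 1.5), (4.0, 1.5))  # cell with mean 1

    def test_single_cell(self):
        grid = self._grid([[2]], [[1]], [[4]])
        assert x.select_thresholds(grid) == ((3.0, 1.5), (3.0, 1.5))

    def test_tie_broken_by_larger_z(self):
        grid = self._grid([[2, 2]], [[2, 4]], [[5, 5]])
        assert x.select_thresholds(grid) == ((3.0, 1.5), (4.0, 1.5))

    def test_all_degenerate_rejected(self):
        from xpsweep.permutation import _summarize
        r = _summarize(5, np.array([3.0, 3.0, 3.0]), seed=0)
        grid = x.EnrichmentGrid([(3.0, 1.5)], [(3.0, 1.5)], [[r]], [1], [1])
        with pytest.raises(ValidationError):
            x.select_thresholds(grid)
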