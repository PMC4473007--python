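"""Island caller: eligibility, clustering, scoring, E-value threshold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from islandscape import (
    IslandCallerParams,
    aggregate_islands,
    background_rate,
    call_islands,
    compare_conditions,
    eligible_windows,
    score_threshold,
)
from islandscape.islands import Island, eligibility_threshold, window_score
from conftest import make_track
from _oracles import brute_force_islands

PARAMS = IslandCallerParams(effective_genome_fraction=1.0)


def mask_of(track, lam, p=0.2):
    return eligible_windows(track, lam, p)


class TestBackgroundRate:
    def test_genome_average_rate(self):
        counts = np.zeros(50_000, dtype=int)
        counts[:10_000] = 1  # 10,000 reads over a 10 Mb genome
        track = make_track(counts)
        assert background_rate(track, PARAMS) == pytest.approx(0.2)

    def test_halving_effective_fraction_doubles_lambda(self):
        track = make_track(np.ones(1000, dtype=int))
        lam1 = background_rate(track, IslandCallerParams(effective_genome_fraction=1.0))
        lam2 = background_rate(track, IslandCallerParams(effective_genome_fraction=0.5))
        assert lam2 == pytest.approx(2 * lam1)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            background_rate(make_track(np.zeros(10, dtype=int)), PARAMS)

    def test_background_simulation_matches_lambda(self):
        rng = np.random.default_rng(0)
        lams = []
        for _ in range(10):
            counts = rng.poisson(0.2, 20_000)
            track = make_track(counts)
            lams.append(background_rate(track, PARAMS))
        se = 3 * np.sqrt(0.2 / 20_000)
        assert abs(np.mean(lams) - 0.2) < 3 * se


class TestEligibility:
    def test_threshold_count_at_paper_scale_background(self):
        # P[Poisson(0.2) >= 1] = 0.181 < 0.2, so a single read makes a window eligible
        assert eligibility_threshold(0.2, 0.2) == 1

    def test_zero_count_windows_never_eligible(self):
        track = make_track([0, 0, 5, 0])
        for lam in (0.01, 0.5, 3.0):
            mask = eligible_windows(track, lam, 0.2)
            assert not mask["chr1"][0] and not mask["chr1"][1]

    def test_raising_p_window_is_monotone(self):
        track = make_track(np.random.default_rng(3).poisson(1.0, 500))
        n_eligible = [
            eligible_windows(track, 1.0, p)["chr1"].sum() for p in (0.05, 0.2, 0.5)
        ]
        assert n_eligible[0] <= n_eligible[1] <= n_eligible[2]


class TestAggregateIslands:
    def test_gap_joins_nearby_eligible_windows(self):
        counts = np.zeros(12, dtype=int)
        counts[[3, 4, 7]] = 5
        track = make_track(counts)
        islands = aggregate_islands(mask_of(track, 0.2), track, PARAMS, 0.2)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (3 * 200, 8 * 200)

    def test_gap_beyond_allowance_splits(self):
        counts = np.zeros(12, dtype=int)
        counts[[3, 8]] = 5
        track = make_track(counts)
        islands = aggregate_islands(mask_of(track, 0.2), track, PARAMS, 0.2)
        assert len(islands) == 2

    def test_read_count_includes_gap_windows(self):
        counts = np.zeros(10, dtype=int)
        counts[3] = 4
        counts[4] = 1  # sub-threshold at lam high enough
        counts[5] = 4
        lam = 1.5  # threshold c=3: P[X>=3]=0.191<0.2 while P[X>=2]=0.44
        track = make_track(counts)
        islands = aggregate_islands(mask_of(track, lam), track, PARAMS, lam)
        assert len(islands) == 1
        assert islands[0].read_count == 9  # gap window's read still counted
        assert islands[0].eligible_window_count == 2

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=50),
        st.floats(0.05, 3.0),
        st.sampled_from([0, 200, 400, 600]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, counts, lam, gap):
        params = IslandCallerParams(gap_size=gap, effective_genome_fraction=1.0)
        track = make_track(np.array(counts))
        got = aggregate_islands(mask_of(track, lam), track, params, lam)
        expected = brute_force_islands(counts, lam, 200, gap)
        assert len(got) == len(expected)
        for isl, (w0, w1, rc, score) in zip(got, expected):
            assert isl.start == w0 * 200 and isl.end == (w1 + 1) * 200
            assert isl.read_count == rc
            assert isl.score == pytest.approx(score, rel=1e-9)


class TestScoreThreshold:
    def test_huge_e_value_gives_minimum_island_score(self):
        lam = 0.2
        params = IslandCallerParams(e_value=1e9, effective_genome_fraction=1.0)
        thr = score_threshold(params, lam, 10_000)
        min_single = float(window_score(eligibility_threshold(lam, 0.2), lam))
        assert thr <= min_single + params.score_step

    def test_tiny_e_value_gives_larger_threshold(self):
        lam = 0.2
        lo = score_threshold(IslandCallerParams(e_value=100.0), lam, 10_000)
        hi = score_threshold(IslandCallerParams(e_value=1e-6), lam, 10_000)
        assert hi > lo

    def test_threshold_monotone_in_e_value(self):
        lam = 0.5
        thresholds = [
            score_threshold(IslandCallerParams(e_value=e), lam, 50_000)
            for e in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))


class TestCallIslands:
    def test_all_zero_track_returns_nothing(self):
        assert call_islands(make_track(np.zeros(100, dtype=int)), PARAMS) == []

    def test_planted_sites_recovered(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(0.2, 50_000)
        sites = np.arange(500, 50_000, 1000)[:50]
        for s in sites:
            counts[s : s + 10] += rng.poisson(4.0, 10)  # 20x background over 2 kb
        track = make_track(counts)
        called = call_islands(track, PARAMS)
        recovered = sum(
            any(isl.start < (s + 10) * 200 and (isl.end > s * 200) for isl in called)
            for s in sites
        )
        assert recovered >= 45

    def test_adding_reads_inside_island_never_decreases_score(self):
        counts = np.zeros(30, dtype=int)
        counts[10:15] = 3
        track = make_track(counts, total=15)
        lam = 0.3
        isl1 = aggregate_islands(mask_of(track, lam), track, PARAMS, lam)[0]
        counts2 = counts.copy()
        counts2[12] += 5
        track2 = make_track(counts2, total=20)
        isl2 = aggregate_islands(mask_of(track2, lam), track2, PARAMS, lam)[0]
        assert isl2.score >= isl1.score

    def test_increasing_gap_never_increases_island_count(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(0.4, 2_000)
        track = make_track(counts)
        lam = background_rate(track, PARAMS)
        sizes = []
        for gap in (0, 200, 400, 800):
            params = IslandCallerParams(gap_size=gap, effective_genome_fraction=1.0)
            sizes.append(len(aggregate_islands(mask_of(track, lam), track, params, lam)))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def _island(chrom, start, end):
    return Island(chrom, start, end, read_count=1, score=1.0, eligible_window_count=1)


class TestCompareConditions:
    def test_identical_lists_fully_shared(self):
        a = [_island("chr1", 0, 200), _island("chr1", 1000, 1400)]
        cmp_ = compare_conditions(a, list(a))
        assert cmp_.shared_a == cmp_.shared_b == 2
        assert cmp_.unique_a == cmp_.unique_b == 0

    def test_disjoint_lists_fully_unique(self):
        a = [_island("chr1", 0, 200)]
        b = [_island("chr1", 400, 600), _island("chr2", 0, 200)]
        cmp_ = compare_conditions(a, b)
        assert cmp_.shared_a == cmp_.shared_b == 0
        assert (cmp_.unique_a, cmp_.unique_b) == (1, 2)

    def test_one_broad_island_spanning_two_narrow_ones(self):
        a = [_island("chr1", 0, 2000)]
        b = [_island("chr1", 100, 300), _island("chr1", 1500, 1700)]
        cmp_ = compare_conditions(a, b)
        assert (cmp_.shared_a, cmp_.shared_b) == (1, 2)

    def test_accounting_identity(self):
        rng = np.random.default_rng(5)
        def random_islands(seed_offset):
            starts = np.sort(rng.choice(10_000, size=30, replace=False)) * 100
            return [_island("chr1", int(s), int(s) + rng.integers(100, 900)) for s in starts]
        a, b = random_islands(0), random_islands(1)
        cmp_ = compare_conditions(a, b)
        assert cmp_.shared_a + cmp_.unique_a == cmp_.total_a == len(a)
        assert cmp_.shared_b + cmp_.unique_b == cmp_.total_b == len(b)
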