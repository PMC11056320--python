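"""Pivot sampling, placement, collation, and partition merging."""

import numpy as np
import pytest

import capssa as cs
from capssa.merge import SortedRun

from conftest import random_text


def halves_of(t):
    """The two locally sorted halves of a text's index set."""
    n = t.n
    return [cs.merge_sort(np.arange(0, n // 2), t),
            cs.merge_sort(np.arange(n // 2, n), t)]


def linear_scan_locate(run, v, t, k=None):
    """Naive upper bound using full suffix comparisons."""
    idx = 0
    for p in run.positions:
        rel = cs.suffix_compare(t, int(p), int(v), k=k).relation
        if rel == "greater":
            break
        idx += 1
    return idx


class TestSamplePivots:
    def test_single_partition_needs_no_pivots(self, example_text):
        runs = [cs.merge_sort(np.arange(11), example_text)]
        assert len(cs.sample_pivots(runs, s=4, seed=0, t=example_text)) == 0

    def test_two_runs_one_pivot_is_rank_one_sample(self, example_text):
        runs = halves_of(example_text)
        ps = cs.sample_pivots(runs, s=1, seed=123, t=example_text)
        assert len(ps) == 1
        # reproduce the documented draw: one sample per run from split
        # streams of the seed, pivot = rank-1 of the 2 sorted samples
        streams = np.random.SeedSequence(123).spawn(2)
        draws = [np.random.default_rng(streams[r]).choice(runs[r].positions,
                                                          size=1, replace=False)[0]
                 for r in range(2)]
        expected = max(draws, key=lambda i: str(example_text)[i:])
        assert ps.pivots[0] == expected

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_pivots_strictly_increasing_as_suffixes(self, seed):
        t = random_text(400, seed=seed)
        runs = [cs.merge_sort(np.arange(i * 100, (i + 1) * 100), t) for i in range(4)]
        ps = cs.sample_pivots(runs, s=8, seed=seed, t=t)
        for a, b in zip(ps.pivots, ps.pivots[1:]):
            assert cs.suffix_compare(t, int(a), int(b)).relation == "less"

    def test_oversized_s_clamped(self, example_text):
        runs = halves_of(example_text)
        ps = cs.sample_pivots(runs, s=1000, seed=0, t=example_text)
        assert ps.sample_factor == min(len(r) for r in runs)


class TestLocatePivot:
    def test_pivot_larger_than_all(self, example_text):
        run = SortedRun(np.array([10, 0, 1]), np.array([0, 0, 1]))
        assert cs.locate_pivot(run, 8, example_text) == 3

    def test_upper_bound_includes_equal_element(self, example_text):
        run = SortedRun(np.array([10, 0, 1]), np.array([0, 0, 1]))
        assert cs.locate_pivot(run, 0, example_text) == 2

    def test_pivot_smaller_than_all(self, example_text):
        run = SortedRun(np.array([0, 1, 8]), np.array([0, 1, 1]))
        assert cs.locate_pivot(run, 10, example_text) == 0

    @pytest.mark.parametrize("seed", list(range(8)))
    def test_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        t = random_text(int(rng.integers(2, 500)), alphabet_size=3, seed=seed + 3)
        sub = np.sort(rng.choice(t.n, size=max(1, t.n // 2), replace=False))
        run = cs.merge_sort(sub, t)
        for v in rng.choice(t.n, size=10):
            assert cs.locate_pivot(run, int(v), t) == linear_scan_locate(run, v, t)

    def test_prefix_limit_groups_equal_prefixes_right(self):
        t = cs.build_text("ABABAB")
        run = cs.merge_sort(np.arange(t.n), t)
        # prefix "A": every suffix starting with A extends beyond it
        v = 4  # suffix "AB$"
        idx = cs.locate_pivot(run, v, t, prefix_limit=1)
        firstA = next(i for i, p in enumerate(run.positions)
                      if str(t)[int(p)] == "A")
        assert idx == firstA


class TestCollate:
    def test_single_partition_identity(self, example_text):
        runs = [cs.merge_sort(np.arange(11), example_text)]
        ps = cs.sample_pivots(runs, s=2, seed=0, t=example_text)
        layout, pos, lcp = cs.collate_partitions(runs, ps, example_text)
        assert layout.cumulative.tolist() == [0, 11]
        assert pos.tolist() == runs[0].positions.tolist()

    def test_forced_pivot_splits_at_four(self, example_text):
        # partition 0 holds the suffixes <= "AT$" (positions 10,0,1,8)
        runs = halves_of(example_text)
        ps = cs.PivotSet(np.array([8], np.int64), 1, 0)
        layout, pos, lcp = cs.collate_partitions(runs, ps, example_text)
        assert layout.cumulative.tolist() == [0, 4, 11]
        assert sorted(pos[:4].tolist()) == [0, 1, 8, 10]

    def test_sub_subarray_first_lcp_reset(self, example_text):
        runs = halves_of(example_text)
        ps = cs.PivotSet(np.array([8], np.int64), 1, 0)
        layout, pos, lcp = cs.collate_partitions(runs, ps, example_text)
        for j in range(layout.p):
            base = int(layout.cumulative[j])
            for g in layout.group_bounds[j][:-1]:
                off = base + int(g)
                if off < int(layout.cumulative[j + 1]):
                    assert lcp[off] == 0

    @pytest.mark.parametrize("seed,p", [(0, 2), (1, 3), (2, 8)])
    def test_conservation(self, seed, p):
        t = random_text(777, seed=seed)
        bounds = np.linspace(0, t.n, p + 1).astype(int)
        runs = [cs.merge_sort(np.arange(bounds[i], bounds[i + 1]), t)
                for i in range(p)]
        ps = cs.sample_pivots(runs, s=4, seed=seed, t=t)
        layout, pos, lcp = cs.collate_partitions(runs, ps, t)
        assert int(layout.sizes().sum()) == t.n
        assert np.array_equal(np.sort(pos), np.arange(t.n))


class TestMergePartition:
    def test_single_group_unchanged(self, example_text):
        g = cs.merge_sort(np.arange(11), example_text)
        out = cs.merge_partition([g], example_text)
        assert out.positions.tolist() == g.positions.tolist()

    def test_two_groups(self, example_text):
        g1 = SortedRun(np.array([5, 2]), np.array([0, 1]))
        g2 = SortedRun(np.array([7, 4]), np.array([0, 1]))
        out = cs.merge_partition([g1, g2], example_text)
        assert out.positions.tolist() == [5, 2, 7, 4]
        assert out.lcps.tolist() == [0, 1, 0, 1]

    def test_empty_groups_allowed(self, example_text):
        g1 = SortedRun(np.empty(0, np.int64), np.empty(0, np.int64))
        g2 = SortedRun(np.array([5, 2]), np.array([0, 1]))
        out = cs.merge_partition([g1, g2, g1], example_text)
        assert out.positions.tolist() == [5, 2]

    def test_collated_worked_example_matches_sa_slices(self, example_text,
                                                       example_sa, example_lcp):
        runs = halves_of(example_text)
        ps = cs.PivotSet(np.array([8], np.int64), 1, 0)
        layout, pos, lcp = cs.collate_partitions(runs, ps, example_text)
        for j in range(layout.p):
            lo, hi = int(layout.cumulative[j]), int(layout.cumulative[j + 1])
            groups = []
            gb = layout.group_bounds[j]
            for a, b in zip(gb, gb[1:]):
                groups.append(SortedRun(pos[lo + a:lo + b], lcp[lo + a:lo + b]))
            merged = cs.merge_partition(groups, example_text)
            assert merged.positions.tolist() == example_sa[lo:hi].tolist()


class TestBalance:
    def test_sampled_partitions_are_balanced(self):
        # oversampling bound: s = 32 ln n keeps every partition below
        # 3n/p across seeds (stochastic, small-scale version)
        n, p = 20_000, 8
        s = int(np.ceil(32 * np.log(n)))
        for seed in range(5):
            t = cs.random_dna(n, seed=seed)
            _, _, stats = cs.construct(t, cs.BuildConfig(p=p, s=s, seed=seed))
            assert int(stats.partition_sizes.max()) <= 3 * n // p
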