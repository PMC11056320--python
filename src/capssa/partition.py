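"""Samplesort machinery: pivot sampling, pivot placement by accelerated
binary search, partition collation, and recursive partition merging.

After the ``p`` uniform subarrays are locally sorted, ``s`` suffixes are
sampled from each, the ``s*p`` samples are sorted, and the ``p-1``
evenly-spaced order statistics become the global pivots.  Each pivot's
upper-bound position in every run cuts the runs into sub-subarrays; all
sub-subarrays destined for one partition are collated contiguously and
then merged pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .merge import MergeStats, SortedRun, merge_sort
from .text import InvalidInputError, Text, _effective_cap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PivotSet:
    """Global pivots (suffix start positions, sorted by suffix order)
    plus the sampling parameters that produced them.  The ±infinity
    sentinel pivots are implicit."""

    pivots: np.ndarray
    sample_factor: int
    seed: int

    def __len__(self) -> int:
        return int(self.pivots.shape[0])


@dataclass(frozen=True)
class PartitionLayout:
    """``cumulative[j]`` is the start offset of partition ``j`` in the
    final suffix array (``cumulative[0] == 0``, ``cumulative[p] == n``);
    ``group_bounds[j]`` delimits, in partition-local offsets, the
    sub-subarray contributed by each run."""

    cumulative: np.ndarray
    group_bounds: list

    @property
    def p(self) -> int:
        return int(self.cumulative.shape[0]) - 1

    def sizes(self) -> np.ndarray:
        return np.diff(self.cumulative)


def sample_pivots(runs, s: int, seed: int, t: Text, k=None,
                  stats: MergeStats | None = None) -> PivotSet:
    """Draw ``s`` suffixes uniformly without replacement from each run,
    sort the ``s*p`` samples, and keep the order statistics at 0-based
    ranks ``s, 2s, …, (p-1)s`` as pivots.

    Each run draws from an independent stream split off ``seed``, so the
    result is reproducible and independent of scheduling.  ``s`` larger
    than the shortest run is clamped with a logged warning.
    """
    p = len(runs)
    if p < 1 or s < 1:
        raise InvalidInputError("need p >= 1 runs and sampling factor s >= 1")
    if p == 1:
        return PivotSet(np.empty(0, np.int64), int(s), int(seed))
    shortest = min(len(r) for r in runs)
    if shortest == 0:
        raise InvalidInputError("every run must be non-empty")
    s_eff = int(s)
    if s_eff > shortest:
        logger.warning("sampling factor s=%d exceeds shortest run (%d); clamped",
                       s_eff, shortest)
        s_eff = shortest
    streams = np.random.SeedSequence(int(seed)).spawn(p)
    samples = np.concatenate([
        np.random.default_rng(streams[r]).choice(runs[r].positions, size=s_eff,
                                                 replace=False)
        for r in range(p)
    ]).astype(np.int64)
    sorted_samples = merge_sort(samples, t, k=k, stats=stats)
    ranks = np.arange(1, p) * s_eff
    return PivotSet(sorted_samples.positions[ranks].copy(), s_eff, int(seed))


def _search_cap(t: Text, prefix_limit, k):
    kcap = _effective_cap(t, k)
    if prefix_limit is None:
        return kcap, False
    if prefix_limit < 1:
        raise InvalidInputError("prefix_limit must be >= 1")
    pl = np.int64(prefix_limit)
    # A probe that exhausts an explicit pivot prefix ranks greater; a tie
    # produced by the context bound alone ranks equal.
    if pl <= kcap:
        return pl, True
    return kcap, False


def locate_pivot(run: SortedRun, v: int, t: Text, prefix_limit=None, k=None) -> int:
    """Upper-bound index of pivot suffix ``v`` in ``run``: the smallest
    index whose suffix compares greater than ``v`` (greater than ``v``'s
    ``prefix_limit``-prefix when limited, a suffix extending beyond an
    equal prefix counting as greater).

    The binary search tracks the pivot's LCP against the lo/hi bounds
    and starts each comparison at their minimum (simple accelerant).
    """
    cap, tie_greater = _search_cap(t, prefix_limit, k)
    scratch = np.zeros(2, np.int64)
    return int(_kernels.locate_kernel(t.data, run.positions, np.int64(v), cap,
                                      tie_greater, scratch))


def collate_partitions(runs, pivots: PivotSet, t: Text, prefix_limit=None, k=None):
    """Cut every run at every pivot and regroup the pieces by partition.

    Returns ``(layout, positions, lcps)``: partition ``j`` occupies
    ``[cumulative[j], cumulative[j+1])`` and holds each run's ``j``-th
    sub-subarray in run order, with run-local LCP values except that
    each sub-subarray's first entry is reset to 0 (its predecessor
    changed).
    """
    p = len(runs)
    n = sum(len(r) for r in runs)
    nparts = len(pivots) + 1
    # splits[r] holds the p+1 cut offsets of run r (0 … len(run)).
    splits = []
    for run in runs:
        cuts = [0]
        for v in pivots.pivots:
            cuts.append(locate_pivot(run, int(v), t, prefix_limit=prefix_limit, k=k))
        cuts.append(len(run))
        cuts = np.asarray(cuts, dtype=np.int64)
        if (np.diff(cuts) < 0).any():
            raise InvalidInputError("pivot locations not monotone within a run")
        splits.append(cuts)

    out_pos = np.empty(n, np.int64)
    out_lcp = np.empty(n, np.int64)
    cumulative = np.zeros(nparts + 1, np.int64)
    group_bounds = []
    off = 0
    for j in range(nparts):
        local = [0]
        for r in range(p):
            a, b = int(splits[r][j]), int(splits[r][j + 1])
            size = b - a
            if size:
                out_pos[off:off + size] = runs[r].positions[a:b]
                out_lcp[off:off + size] = runs[r].lcps[a:b]
                out_lcp[off] = 0
                off += size
            local.append(local[-1] + size)
        group_bounds.append(np.asarray(local, dtype=np.int64))
        cumulative[j + 1] = off
    if off != n:
        raise InvalidInputError("partition layout does not cover all positions")
    return PartitionLayout(cumulative, group_bounds), out_pos, out_lcp


def _pairwise_merge(a_pos, a_lcp, b_pos, b_lcp, bounds, tdata, cap, counts):
    """Merge adjacent sorted groups, halving the group list per pass and
    ping-ponging between the (a, b) buffer pairs.

    ``bounds`` are group boundary offsets into the buffers.  Returns the
    buffer pair holding the result.
    """
    cur_p, cur_l = a_pos, a_lcp
    oth_p, oth_l = b_pos, b_lcp
    bounds = [int(x) for x in bounds]
    while len(bounds) > 2:
        nxt = [bounds[0]]
        gi = 0
        while gi < len(bounds) - 1:
            s = bounds[gi]
            if gi + 2 < len(bounds):
                mid, e = bounds[gi + 1], bounds[gi + 2]
                gi += 2
            else:
                mid = e = bounds[gi + 1]
                gi += 1
            if mid < e:
                _kernels.merge_runs(tdata, cur_p[s:mid], cur_l[s:mid],
                                    cur_p[mid:e], cur_l[mid:e],
                                    oth_p[s:e], oth_l[s:e], cap, counts)
            else:
                oth_p[s:e] = cur_p[s:e]
                oth_l[s:e] = cur_l[s:e]
            nxt.append(e)
        bounds = nxt
        cur_p, oth_p = oth_p, cur_p
        cur_l, oth_l = oth_l, cur_l
    return cur_p, cur_l


def merge_partition(groups, t: Text, k=None, stats: MergeStats | None = None) -> SortedRun:
    """Merge a partition's contiguous sorted groups into one sorted run.

    The group list is reduced by balanced pairwise merges reusing two
    ping-pong buffer pairs; empty groups are permitted (a pivot need not
    split every run).
    """
    cap = _effective_cap(t, k)
    if stats is None:
        stats = MergeStats()
    groups = [g for g in groups]
    if not groups:
        return SortedRun(np.empty(0, np.int64), np.empty(0, np.int64))
    sizes = [len(g) for g in groups]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    a_pos = np.concatenate([g.positions for g in groups]) if sum(sizes) else np.empty(0, np.int64)
    a_lcp = np.concatenate([g.lcps for g in groups]) if sum(sizes) else np.empty(0, np.int64)
    a_pos = a_pos.astype(np.int64)
    a_lcp = a_lcp.astype(np.int64)
    b_pos = np.empty_like(a_pos)
    b_lcp = np.empty_like(a_lcp)
    # drop empty groups: they contribute no boundary
    bounds = np.unique(bounds)
    res_p, res_l = _pairwise_merge(a_pos, a_lcp, b_pos, b_lcp, bounds,
                                   t.data, cap, stats._counts)
    return SortedRun(res_p, res_l)
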