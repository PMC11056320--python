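"""End-to-end suffix-array + LCP-array construction.

The four high-level steps: populate an unsorted suffix array (the
identity permutation), locally sort ``p`` uniform subarrays with the
LCP-informed mergesort, sample global pivots and cut every run at each
pivot, then collate and pairwise-merge each partition.  LCP values for
pairs that cross partition boundaries are computed at the end.

Parallelism is a contract, not a primitive: subarray sorts and partition
merges are declared independent tasks, the serial schedule here is the
reference, and any parallel schedule must be bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .merge import MergeStats, SortedRun, merge_sort
from .partition import (PartitionLayout, _pairwise_merge, collate_partitions,
                        sample_pivots)
from .text import InvalidInputError, Text, _effective_cap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildConfig:
    """Construction parameters.

    p
        partition (subproblem) count; ``None`` → ``min(workers,
        max(1, n // 4096))``.
    s
        sampling factor: candidate pivots drawn per run before the
        evenly spaced global pivots are selected (default 64).
    k
        context bound; 0 or ``None`` means full context.  Suffixes
        sharing a prefix of length ≥ k may appear in arbitrary relative
        order, and reported LCP values are capped at k.
    prefix_limit
        pivot-prefix length for the placement binary searches;
        ``None`` = unlimited.
    width
        bytes per stored entry for on-disk output: 4, 8 or "auto".
    workers
        parallelism hint; only feeds the default ``p`` (the reference
        schedule is serial and any parallel one must match it exactly).
    """

    p: int | None = None
    s: int = 64
    k: int | None = None
    prefix_limit: int | None = None
    seed: int = 0
    width: object = "auto"
    workers: int = 1

    def __post_init__(self):
        if self.p is not None and self.p < 1:
            raise InvalidInputError("p must be >= 1")
        if self.s < 1:
            raise InvalidInputError("s must be >= 1")
        if self.k is not None and self.k < 0:
            raise InvalidInputError("k must be >= 0")
        if self.width not in (4, 8, "auto"):
            raise InvalidInputError("width must be 4, 8 or 'auto'")


class BuildStats(MergeStats):
    """MergeStats plus per-build instrumentation: the partition layout,
    partition sizes, and the peak count of concurrently live working
    entries (suffix-position/LCP buffers; the O(s·p) pivot-sampling
    workspace is reported separately)."""

    __slots__ = ("layout", "partition_sizes", "peak_aux_entries",
                 "sampling_entries", "p", "s_eff")

    def __init__(self):
        super().__init__()
        self.layout = None
        self.partition_sizes = None
        self.peak_aux_entries = 0
        self.sampling_entries = 0
        self.p = 1
        self.s_eff = 0

    def _track(self, live_entries: int) -> None:
        if live_entries > self.peak_aux_entries:
            self.peak_aux_entries = int(live_entries)

    def summary(self) -> dict:
        return {
            "matching": self.matching,
            "mismatching": self.mismatching,
            "p": self.p,
            "s_eff": self.s_eff,
            "partition_sizes": None if self.partition_sizes is None
            else [int(x) for x in self.partition_sizes],
            "peak_aux_entries": self.peak_aux_entries,
            "sampling_entries": self.sampling_entries,
        }


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of checking an (SA, LCP) pair against its text."""

    is_sorted: bool
    is_permutation: bool
    lcp_ok: bool
    first_violation: int | None = None

    @property
    def ok(self) -> bool:
        return self.is_sorted and self.is_permutation and self.lcp_ok


def _default_p(n: int, workers: int) -> int:
    return max(1, min(int(workers), max(1, n // 4096)))


def _chunk_bounds(n: int, p: int) -> np.ndarray:
    base, rem = divmod(n, p)
    sizes = np.full(p, base, np.int64)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def construct(t: Text, cfg: BuildConfig | None = None):
    """Build the suffix array and LCP array of ``t``.

    Returns ``(sa, lcp, stats)``; at full context the output equals the
    brute-force order, and it is identical for any worker count.
    """
    if cfg is None:
        cfg = BuildConfig()
    n = t.n
    p = cfg.p if cfg.p is not None else _default_p(n, cfg.workers)
    if p > n:
        logger.warning("p=%d exceeds n=%d; clamped", p, n)
        p = n
    cap = _effective_cap(t, cfg.k)
    stats = BuildStats()
    stats.p = p

    bounds = _chunk_bounds(n, p)
    runs = []
    done = 0
    for j in range(p):
        lo, hi = int(bounds[j]), int(bounds[j + 1])
        m = hi - lo
        stats._track(2 * done + 4 * m)  # sorted runs so far + ping-pong pair
        runs.append(merge_sort(np.arange(lo, hi, dtype=np.int64), t,
                               k=cfg.k, stats=stats))
        done += m

    if p == 1:
        sa, lcp = runs[0].positions, runs[0].lcps
        stats.layout = PartitionLayout(np.array([0, n], np.int64),
                                       [np.array([0, n], np.int64)])
        stats.partition_sizes = np.array([n], np.int64)
        return sa, lcp, stats

    pivots = sample_pivots(runs, cfg.s, cfg.seed, t, k=cfg.k, stats=stats)
    stats.s_eff = pivots.sample_factor
    stats.sampling_entries = 4 * pivots.sample_factor * p

    layout, pos, lcps = collate_partitions(runs, pivots, t,
                                           prefix_limit=cfg.prefix_limit, k=cfg.k)
    stats._track(4 * n)  # runs (input) + collated arrays (output)
    runs = None  # release the per-run buffers

    sizes = layout.sizes()
    max_part = int(sizes.max()) if sizes.size else 0
    scratch_p = np.empty(max_part, np.int64)
    scratch_l = np.empty(max_part, np.int64)
    stats._track(2 * n + 2 * max_part)
    for j in range(layout.p):
        lo, hi = int(layout.cumulative[j]), int(layout.cumulative[j + 1])
        size = hi - lo
        if size == 0:
            continue
        gb = np.unique(layout.group_bounds[j])
        view_p, view_l = pos[lo:hi], lcps[lo:hi]
        res_p, res_l = _pairwise_merge(view_p, view_l,
                                       scratch_p[:size], scratch_l[:size],
                                       gb, t.data, cap, stats._counts)
        if res_p is not view_p:
            view_p[:] = res_p
            view_l[:] = res_l

    lcps = fix_boundary_lcps(t, pos, lcps, layout, k=cfg.k)
    stats.layout = layout
    stats.partition_sizes = sizes
    return pos, lcps, stats


def fix_boundary_lcps(t: Text, sa: np.ndarray, lcp: np.ndarray,
                      layout: PartitionLayout, k=None) -> np.ndarray:
    """Recompute the LCP entries at partition boundaries (the pairs the
    per-partition merges never saw); the array is updated in place and
    returned.  ``lcp[0]`` stays 0."""
    cap = _effective_cap(t, k)
    scratch = np.zeros(2, np.int64)
    for b in layout.cumulative[1:-1]:
        b = int(b)
        if b <= 0 or b >= sa.shape[0]:
            continue
        _, val = _kernels.compare_from(t.data, int(sa[b - 1]), int(sa[b]),
                                       0, cap, scratch)
        lcp[b] = val
    if lcp.shape[0]:
        lcp[0] = 0
    return lcp


def verify(t: Text, sa: np.ndarray, lcp: np.ndarray, k=None) -> VerificationReport:
    """Check that (sa, lcp) is a valid (k-bounded) suffix/LCP array pair
    for ``t``: a permutation, pairwise non-decreasing under the bounded
    comparison, with every LCP entry equal to the pairwise value."""
    sa = np.asarray(sa, dtype=np.int64)
    lcp = np.asarray(lcp, dtype=np.int64)
    n = t.n
    is_perm = (sa.shape[0] == n and lcp.shape[0] == n
               and np.array_equal(np.sort(sa), np.arange(n)))
    if not is_perm:
        return VerificationReport(False, False, False, 0)
    cap = _effective_cap(t, k)
    scratch = np.zeros(2, np.int64)
    sorted_ok, lcp_ok, first = _kernels.verify_kernel(t.data, sa, lcp, cap, scratch)
    return VerificationReport(bool(sorted_ok), True, bool(lcp_ok),
                              None if first < 0 else int(first))


def lcp_stats(lcp: np.ndarray):
    """Population mean, standard deviation and maximum of ``lcp[1:]``
    (the defined pairwise entries)."""
    lcp = np.asarray(lcp)
    if lcp.shape[0] < 2:
        raise InvalidInputError("lcp_stats needs n >= 2")
    vals = lcp[1:].astype(np.float64)
    return float(vals.mean()), float(vals.std()), int(lcp[1:].max())
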