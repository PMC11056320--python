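"""The LCP-informed merge of sorted suffix runs and the mergesort built
on it.

A *sorted run* pairs suffix start positions, in lexicographic order,
with the LCP values of adjacent entries (the run's first entry carries
LCP 0).  Merging two such runs needs symbol comparisons only when the
freshly advanced element's run-local LCP equals the LCP of the last
compared pair; the other two cases are resolved in O(1) from the LCP
bookkeeping alone.  Every symbol comparison is counted in a
:class:`MergeStats`, and the matching-comparison count of a full sort
equals the sum of the output LCP array exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .text import InvalidInputError, Text, _effective_cap


class MergeStats:
    """Counters of matching and mismatching symbol comparisons.

    Both counters are monotone non-decreasing over a run of the
    algorithm; the matching count of a complete sort equals the sum of
    the final LCP values (exact at a single partition).
    """

    __slots__ = ("_counts",)

    def __init__(self, matching: int = 0, mismatching: int = 0):
        self._counts = np.array([matching, mismatching], dtype=np.int64)

    @property
    def matching(self) -> int:
        return int(self._counts[0])

    @property
    def mismatching(self) -> int:
        return int(self._counts[1])

    @property
    def total(self) -> int:
        return self.matching + self.mismatching

    def copy(self) -> "MergeStats":
        return MergeStats(self.matching, self.mismatching)

    def __repr__(self):
        return f"MergeStats(matching={self.matching}, mismatching={self.mismatching})"


@dataclass
class SortedRun:
    """A block of suffix start positions in sorted order plus the LCP
    values of adjacent entries (``lcps[0] == 0``)."""

    positions: np.ndarray
    lcps: np.ndarray

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        self.lcps = np.ascontiguousarray(self.lcps, dtype=np.int64)
        if self.positions.shape != self.lcps.shape:
            raise InvalidInputError("positions and lcps must have equal length")

    def __len__(self) -> int:
        return int(self.positions.shape[0])


def _check_run(run: SortedRun, t: Text, cap) -> None:
    scratch = np.zeros(2, np.int64)
    for i in range(1, len(run)):
        rel, lcp = _kernels.compare_from(
            t.data, run.positions[i - 1], run.positions[i], 0, cap, scratch
        )
        if rel > 0 or lcp != run.lcps[i]:
            raise InvalidInputError(f"run not sorted / LCP wrong at index {i}")


def lcp_merge(x: SortedRun, y: SortedRun, t: Text, k=None,
              stats: MergeStats | None = None, check: bool = False) -> SortedRun:
    """Merge two sorted runs into one, propagating LCP values.

    Under a context bound ``k`` suffixes tied at ``k`` take the x-side
    element first (stable-left), which makes the output deterministic.
    ``check`` validates the inputs first (debug aid).
    """
    cap = _effective_cap(t, k)
    if check:
        _check_run(x, t, cap)
        _check_run(y, t, cap)
    if stats is None:
        stats = MergeStats()
    nz = len(x) + len(y)
    zp = np.empty(nz, np.int64)
    zl = np.empty(nz, np.int64)
    _kernels.merge_runs(t.data, x.positions, x.lcps, y.positions, y.lcps,
                        zp, zl, cap, stats._counts)
    return SortedRun(zp, zl)


def merge_sort(positions, t: Text, k=None, stats: MergeStats | None = None) -> SortedRun:
    """Sort suffix start positions into a :class:`SortedRun`.

    Bottom-up mergesort over two ping-pong buffer pairs, so auxiliary
    storage stays at two extra entry-buffers of the input length; the
    merge step is :func:`lcp_merge`'s kernel.
    """
    pos = np.ascontiguousarray(positions, dtype=np.int64)
    cap = _effective_cap(t, k)
    if stats is None:
        stats = MergeStats()
    if pos.size == 0:
        return SortedRun(pos, pos.copy())
    out_pos, out_lcp = _kernels.merge_sort_kernel(t.data, pos, cap, stats._counts)
    return SortedRun(out_pos, out_lcp)
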