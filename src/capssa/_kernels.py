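"""Compiled hot loops shared by the text, merge and partition layers.

Everything here operates on plain numpy buffers: the text as a uint8 array
(terminator included) and suffix positions / LCP values as int64 arrays.
``stats`` is always a 2-entry int64 array accumulating
``[matching, mismatching]`` symbol-comparison counts.
"""

import numpy as np
from numba import njit

# Context cap meaning "unbounded"; larger than any representable text.
UNBOUNDED = np.int64(1) << 62


@njit(cache=True)
def compare_from(text, a, b, start, cap, stats):
    """Compare suffixes at ``a`` and ``b``, symbol by symbol, from offset
    ``start`` (a caller-guaranteed common prefix), never reading past an
    LCP of ``cap``.

    Returns ``(rel, lcp)`` with ``rel`` in {-1, 0, 1}; 0 occurs only for
    the identity pair or when the common prefix reaches ``cap``.
    """
    n = text.shape[0]
    if a == b:
        l = n - a
        if l > cap:
            l = cap
        return 0, l
    l = start
    while l < cap:
        ca = text[a + l]
        cb = text[b + l]
        if ca != cb:
            stats[0] += l - start
            stats[1] += 1
            if ca < cb:
                return -1, l
            return 1, l
        l += 1
    stats[0] += l - start
    return 0, l


@njit(cache=True)
def merge_runs(text, xp, xl, yp, yl, zp, zl, cap, stats):
    """LCP-informed merge of sorted runs (xp, xl) and (yp, yl) into
    (zp, zl).

    ``m`` is the LCP of the last compared pair; when the run-local LCP of
    the freshly advanced side differs from ``m`` the winner is decided
    without touching the text, and only the equal case compares symbols,
    starting at offset ``m``.  Ties (possible only under a context cap)
    take the x-side element first.  When a side is depleted the first
    copied entry receives ``m`` as its LCP.
    """
    nx = xp.shape[0]
    ny = yp.shape[0]
    i = 0
    j = 0
    out = 0
    m = 0
    prev_x = True  # side of the last emitted element (virtual X at start)
    while i < nx and j < ny:
        if prev_x:
            l = xl[i]
            if l > m:
                zl[out] = l if out > 0 else 0
                zp[out] = xp[i]
                i += 1
                out += 1
            elif l < m:
                zl[out] = m if out > 0 else 0
                zp[out] = yp[j]
                j += 1
                out += 1
                m = l
                prev_x = False
            else:
                rel, t = compare_from(text, xp[i], yp[j], m, cap, stats)
                if rel <= 0:
                    zl[out] = l if out > 0 else 0
                    zp[out] = xp[i]
                    i += 1
                else:
                    zl[out] = m if out > 0 else 0
                    zp[out] = yp[j]
                    j += 1
                    prev_x = False
                out += 1
                m = t
        else:
            l = yl[j]
            if l > m:
                zl[out] = l if out > 0 else 0
                zp[out] = yp[j]
                j += 1
                out += 1
            elif l < m:
                zl[out] = m if out > 0 else 0
                zp[out] = xp[i]
                i += 1
                out += 1
                m = l
                prev_x = True
            else:
                rel, t = compare_from(text, xp[i], yp[j], m, cap, stats)
                if rel <= 0:
                    zl[out] = m if out > 0 else 0
                    zp[out] = xp[i]
                    i += 1
                    prev_x = True
                else:
                    zl[out] = l if out > 0 else 0
                    zp[out] = yp[j]
                    j += 1
                out += 1
                m = t
    if i < nx:
        zp[out] = xp[i]
        zl[out] = m if out > 0 else 0
        out += 1
        i += 1
        while i < nx:
            zp[out] = xp[i]
            zl[out] = xl[i]
            out += 1
            i += 1
    elif j < ny:
        zp[out] = yp[j]
        zl[out] = m if out > 0 else 0
        out += 1
        j += 1
        while j < ny:
            zp[out] = yp[j]
            zl[out] = yl[j]
            out += 1
            j += 1


@njit(cache=True)
def merge_sort_kernel(text, pos, cap, stats):
    """Bottom-up mergesort of suffix positions with ping-pong buffers.

    Returns (sorted positions, run LCP array); allocates exactly two
    position buffers and two LCP buffers of the input length.
    """
    n = pos.shape[0]
    a_pos = pos.astype(np.int64)
    a_lcp = np.zeros(n, np.int64)
    b_pos = np.empty(n, np.int64)
    b_lcp = np.empty(n, np.int64)
    width = 1
    while width < n:
        start = 0
        while start < n:
            mid = start + width
            if mid > n:
                mid = n
            end = start + 2 * width
            if end > n:
                end = n
            if mid < end:
                merge_runs(
                    text,
                    a_pos[start:mid], a_lcp[start:mid],
                    a_pos[mid:end], a_lcp[mid:end],
                    b_pos[start:end], b_lcp[start:end],
                    cap, stats,
                )
            else:
                for q in range(start, end):
                    b_pos[q] = a_pos[q]
                    b_lcp[q] = a_lcp[q]
            start = end
        tp = a_pos
        a_pos = b_pos
        b_pos = tp
        tl = a_lcp
        a_lcp = b_lcp
        b_lcp = tl
        width *= 2
    return a_pos, a_lcp


@njit(cache=True)
def locate_kernel(text, run_pos, v, cap, tie_greater, scratch):
    """Upper-bound binary search of pivot suffix ``v`` in a sorted run.

    Implements the simple accelerant: the LCPs of the pivot against the
    low and high bounds are tracked and each probe starts comparing at
    their minimum.  ``cap`` limits the comparison (pivot prefix length
    and/or context bound); ``tie_greater`` selects whether a probe that
    exhausts the cap ranks greater (truncated-pivot mode) or equal
    (context-bound mode, and the pivot against itself).
    """
    lo = 0
    hi = run_pos.shape[0]
    lcp_lo = 0
    lcp_hi = 0
    while lo < hi:
        mid = (lo + hi) >> 1
        start = lcp_lo if lcp_lo < lcp_hi else lcp_hi
        rel, t = compare_from(text, run_pos[mid], v, start, cap, scratch)
        greater = rel > 0 or (rel == 0 and tie_greater and t == cap)
        if greater:
            hi = mid
            lcp_hi = t
        else:
            lo = mid + 1
            lcp_lo = t
    return lo


@njit(cache=True)
def verify_kernel(text, sa, lcp, cap, scratch):
    """Check pairwise (possibly context-capped) order and every LCP value.

    Returns ``(sorted_ok, lcp_ok, first_violation)`` with -1 when clean.
    """
    n = sa.shape[0]
    sorted_ok = True
    lcp_ok = True
    first = -1
    if n > 0 and lcp[0] != 0:
        lcp_ok = False
        first = 0
    for i in range(1, n):
        rel, t = compare_from(text, sa[i - 1], sa[i], 0, cap, scratch)
        bad_order = rel > 0  # rel == 0 only at the cap: a valid k-tie
        bad_lcp = lcp[i] != t
        if bad_order:
            sorted_ok = False
        if bad_lcp:
            lcp_ok = False
        if (bad_order or bad_lcp) and first < 0:
            first = i
    return sorted_ok, lcp_ok, first
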