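"""Text container, terminator handling, suffix comparison, and
brute-force oracles for suffix-array and LCP-array construction.

The indexed object is a byte string ``T`` of length ``n`` whose last
symbol is a unique terminator strictly smaller than every other byte
present, so all suffixes are distinct and the suffix array is a
permutation of ``[0, n)``.  Positions are 0-based and intervals
half-open; the first LCP-array entry is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import UNBOUNDED, compare_from

#: Terminator byte used when none is given; smaller than any ASCII symbol.
DEFAULT_TERMINATOR = 0x00

_SCRATCH = np.zeros(2, np.int64)  # comparison counters nobody reads


class InvalidInputError(ValueError):
    """Input violates a structural precondition (terminator, permutation…)."""


class BoundsError(IndexError):
    """A suffix position lies outside ``[0, n)``."""


@dataclass(frozen=True)
class SuffixOrder:
    """Outcome of comparing two suffixes.

    ``relation`` is ``"less"``, ``"greater"`` or ``"tie"``; a tie occurs
    only for the identity pair or when the common prefix reaches the
    context bound ``k``.  ``lcp`` is the exact longest-common-prefix
    length in symbols (capped at ``k`` when bounded).
    """

    relation: str
    lcp: int


@dataclass(frozen=True)
class Text:
    """A terminated byte text.

    ``data`` holds all ``n`` symbols including the terminator, which is
    ``data[n-1]``, occurs exactly once, and is strictly smaller than any
    other byte present.
    """

    data: np.ndarray = field(repr=False)
    terminator: int

    def __post_init__(self):
        object.__setattr__(self, "data", np.ascontiguousarray(self.data, dtype=np.uint8))

    @property
    def n(self) -> int:
        return int(self.data.shape[0])

    @property
    def alphabet(self) -> frozenset:
        return frozenset(int(b) for b in np.unique(self.data))

    def __str__(self) -> str:
        body = self.data[:-1].tobytes().decode("latin-1")
        return body + "$"


def _coerce_bytes(raw) -> np.ndarray:
    if isinstance(raw, str):
        raw = raw.encode("ascii")
    if isinstance(raw, (bytes, bytearray)):
        return np.frombuffer(bytes(raw), dtype=np.uint8)
    arr = np.asarray(raw)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.uint8)
    return arr


def build_text(raw, terminator=DEFAULT_TERMINATOR) -> Text:
    """Append the terminator to ``raw`` and wrap the result as a Text.

    ``raw`` may be ``str``, ``bytes`` or a uint8 array; ``terminator``
    may be a byte value or a single character (e.g. ``"$"``).  Inputs
    already containing the terminator are rejected, as is a terminator
    that is not strictly smaller than every input byte.
    """
    if isinstance(terminator, str):
        terminator = ord(terminator)
    terminator = int(terminator)
    if not 0 <= terminator <= 255:
        raise InvalidInputError(f"terminator {terminator} is not a byte value")
    body = _coerce_bytes(raw)
    if body.size:
        if (body == terminator).any():
            raise InvalidInputError("terminator byte occurs inside the text")
        if int(body.min()) <= terminator:
            raise InvalidInputError(
                "terminator must be strictly smaller than every text symbol"
            )
    data = np.empty(body.size + 1, np.uint8)
    data[:-1] = body
    data[-1] = terminator
    return Text(data=data, terminator=terminator)


def _effective_cap(t: Text, k) -> np.int64:
    if k is None or k == 0:
        return UNBOUNDED
    if k < 0:
        raise InvalidInputError(f"context bound k={k} must be non-negative")
    return np.int64(k)


def suffix_compare(t: Text, a: int, b: int, skip: int = 0, k=None,
                   check_skip: bool = False) -> SuffixOrder:
    """Order the suffixes starting at ``a`` and ``b``.

    ``skip`` is a caller-asserted known common prefix: symbol reads start
    there and the cost contract is at most ``lcp - skip + 1`` reads.  The
    skipped prefix is trusted unless ``check_skip`` is set (debug mode).
    With a context bound ``k`` the comparison stops at an LCP of ``k``
    and reports a tie.
    """
    n = t.n
    if not (0 <= a < n and 0 <= b < n):
        raise BoundsError(f"positions ({a}, {b}) out of range for n={n}")
    if check_skip and skip and not np.array_equal(t.data[a:a + skip], t.data[b:b + skip]):
        raise InvalidInputError(f"asserted common prefix of length {skip} does not hold")
    cap = _effective_cap(t, k)
    rel, lcp = compare_from(t.data, a, b, skip, cap, _SCRATCH)
    relation = "less" if rel < 0 else ("greater" if rel > 0 else "tie")
    return SuffixOrder(relation=relation, lcp=int(lcp))


def brute_force_sa(t: Text, k=None) -> np.ndarray:
    """Reference suffix array by direct lexicographic sorting.

    Sorts byte slices with the host language's own string comparison, so
    it is independent of the merge machinery it serves as an oracle for.
    In bounded-context mode suffixes tied at ``k`` are ordered by
    ascending start position (documented oracle convention).
    """
    buf = t.data.tobytes()
    n = t.n
    if k is None or k == 0:
        order = sorted(range(n), key=lambda i: buf[i:])
    else:
        order = sorted(range(n), key=lambda i: (buf[i:i + k], i))
    return np.asarray(order, dtype=np.int64)


def _pair_lcp(data: np.ndarray, a: int, b: int, cap) -> int:
    n = data.shape[0]
    m = min(n - a, n - b)
    if cap is not None:
        m = min(m, cap)
    xa = data[a:a + m]
    xb = data[b:b + m]
    mism = np.flatnonzero(xa != xb)
    return int(mism[0]) if mism.size else m


def lcp_from_sa(t: Text, sa: np.ndarray, k=None) -> np.ndarray:
    """Reference LCP array: direct pairwise comparison of adjacent
    suffix-array entries, capped at ``k`` when bounded."""
    sa = np.asarray(sa, dtype=np.int64)
    n = t.n
    if sa.shape[0] != n or not np.array_equal(np.sort(sa), np.arange(n)):
        raise InvalidInputError("sa is not a permutation of [0, n)")
    cap = None if (k is None or k == 0) else int(k)
    out = np.zeros(n, np.int64)
    for i in range(1, n):
        out[i] = _pair_lcp(t.data, int(sa[i - 1]), int(sa[i]), cap)
    return out
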