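"""Synthetic text generation.

Deterministic, seed-driven generators covering the regimes that matter
for suffix sorting: i.i.d. random texts (low mean LCP, the benign
genome-like case), periodic and unary texts (extremely repetitive,
the pathological high-LCP case), and Fibonacci words (a standard
high-repetitiveness stress family with irrational structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .text import DEFAULT_TERMINATOR, InvalidInputError, Text, build_text

KINDS = ("random", "periodic", "unary", "fibonacci")
DNA = b"ACGT"


@dataclass(frozen=True)
class GeneratorSpec:
    """What to generate: ``kind`` in {random, periodic, unary,
    fibonacci}, the body length ``n`` (terminator excluded), the
    alphabet, the motif for the periodic kind, and the seed."""

    kind: str
    n: int
    alphabet: bytes = DNA
    period: bytes = b"ACGT"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown generator kind {self.kind!r}")
        if self.n < 0:
            raise InvalidInputError("n must be >= 0")
        if self.kind == "periodic" and not self.period:
            raise InvalidInputError("periodic kind needs a non-empty motif")
        if self.kind == "random" and not self.alphabet:
            raise InvalidInputError("random kind needs a non-empty alphabet")


def _fibonacci_word(n: int, a: int, b: int) -> np.ndarray:
    """First ``n`` symbols of the infinite Fibonacci word over {a, b}
    (substitution a -> ab, b -> a)."""
    prev, cur = [a], [a, b]
    while len(cur) < n:
        prev, cur = cur, cur + prev
    return np.array(cur[:n], dtype=np.uint8)


def generate(spec: GeneratorSpec, terminator=DEFAULT_TERMINATOR) -> Text:
    """Produce the Text described by ``spec`` (terminator appended);
    deterministic for a fixed seed."""
    n = spec.n
    if spec.kind == "random":
        rng = np.random.default_rng(spec.seed)
        body = rng.choice(np.frombuffer(bytes(spec.alphabet), np.uint8), size=n)
    elif spec.kind == "periodic":
        motif = np.frombuffer(bytes(spec.period), np.uint8)
        reps = -(-n // motif.size)
        body = np.tile(motif, reps)[:n]
    elif spec.kind == "unary":
        sym = spec.alphabet[0] if spec.alphabet else ord("A")
        body = np.full(n, sym, np.uint8)
    else:  # fibonacci
        ab = spec.alphabet[:2] if len(spec.alphabet) >= 2 else b"AC"
        body = _fibonacci_word(n, ab[0], ab[1])
    return build_text(body, terminator=terminator)


def random_dna(n: int, seed: int = 0) -> Text:
    """Convenience: i.i.d. uniform DNA of length ``n``."""
    return generate(GeneratorSpec(kind="random", n=n, seed=seed))
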