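"""Closed-form reconstruction-probability machinery.

Reading a binomial letter is a coupon-collector problem: each read of the
position shows one of the K member k-mers uniformly at random, and the letter
is recovered once all K have been seen. The number of reads R needed is
R = sum R_i with R_1 = 1 and R_i ~ Geom((K-i+1)/K), so E[R] = K * Har(K).

Var(R) < (pi^2 / 6) K^2 gives, via Chebyshev, the tail bound
P(|R - K Har(K)| >= cK) <= pi^2 / (6 c^2); across l independent positions the
whole sequence is recovered from K Har(K) + cK reads with probability at least
(1 - pi^2/(6 c^2))^l, which can be inverted for the c that achieves any target
confidence 1 - delta. The bound is loose (simulated success rates sit well
above it). Requirements for observing each member k-mer t > 1 times have no
closed form here and are explored empirically through the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil, pi, sqrt

import numpy as np

__all__ = [
    "TheoryQuery",
    "harmonic",
    "expected_reads",
    "chebyshev_tail",
    "sequence_success_bound",
    "required_c",
    "required_reads",
    "simulate_collection_reads",
]


@dataclass(frozen=True)
class TheoryQuery:
    """A bound query: K member k-mers, l letters, failure tolerance delta."""

    K: int
    l: int = 1
    delta: float = 0.01

    def __post_init__(self):
        if self.K < 1 or self.l < 1:
            raise ValueError("need K >= 1 and l >= 1")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")


def harmonic(K: int) -> Fraction:
    """The K-th harmonic number, exactly."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return sum((Fraction(1, i) for i in range(1, K + 1)), Fraction(0))


def expected_reads(K: int) -> float:
    """E[R] = K * Har(K): mean reads to see every member k-mer once."""
    return float(K * harmonic(K))


def chebyshev_tail(c: float) -> float:
    """Upper bound pi^2/(6 c^2) on P(|R - K Har(K)| >= cK)."""
    if c <= 0:
        raise ValueError("c must be positive")
    return pi ** 2 / (6 * c ** 2)


def sequence_success_bound(l: int, c: float) -> float:
    """Lower bound (1 - pi^2/(6 c^2))^l on recovering all l positions from
    K Har(K) + cK reads. Meaningful only for c > pi/sqrt(6)."""
    if l < 1:
        raise ValueError("l must be >= 1")
    tail = chebyshev_tail(c)
    if tail >= 1:
        return 0.0
    return (1 - tail) ** l


def required_c(l: int, delta: float) -> float:
    """Smallest c with (1 - pi^2/(6 c^2))^l >= 1 - delta."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    return pi / sqrt(6 * (1 - (1 - delta) ** (1 / l)))


def required_reads(K: int, l: int, delta: float) -> tuple[float, int]:
    """Reads guaranteeing full-sequence recovery with probability 1 - delta.

    Returns ``(exact, ceiling)``: K Har(K) + cK as a real number and rounded
    up to whole reads (the ceiling is what a guarantee uses).
    """
    c = required_c(l, delta)
    exact = expected_reads(K) + c * K
    return exact, ceil(exact)


def simulate_collection_reads(K: int, n_trials: int, rng,
                              t: int = 1, max_reads: int | None = None) -> np.ndarray:
    """Monte-Carlo draws of the reads needed to see all K coupons >= t times.

    Direct simulation of uniform member draws (independent of the closed
    forms above, so usable as their oracle). Returns an int array of length
    ``n_trials``; trials that failed to finish within ``max_reads`` draws are
    reported as ``max_reads + 1`` (the cap defaults to a level making misses
    astronomically unlikely).
    """
    if max_reads is None:
        max_reads = 50 * K * t + 100
    out = np.empty(n_trials, dtype=np.int64)
    chunk = max(1, min(n_trials, 20_000_000 // (max_reads * K)))
    for start in range(0, n_trials, chunk):
        m = min(chunk, n_trials - start)
        draws = rng.integers(0, K, size=(m, max_reads))
        onehot = draws[:, :, None] == np.arange(K)[None, None, :]
        cum = np.cumsum(onehot, axis=1)
        done = (cum >= t).all(axis=2)  # (trials, reads): all coupons seen >= t
        finished = done.any(axis=1)
        out[start:start + m] = np.where(finished, done.argmax(axis=1) + 1,
                                        max_reads + 1)
    return out
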