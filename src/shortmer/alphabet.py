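"""Shortmer building-block sets and combinatorial alphabets.

A *shortmer set* Omega is an ordered collection of N DNA k-mers X_1..X_N with
pairwise Hamming distance >= d, used as atomic synthesis building blocks. A
*combinatorial letter* is a non-empty subset of Omega, written as an N-bit
membership vector; physically it is synthesized as a mixture of its member
k-mers in a single cycle.

Two alphabet schemes are supported:

* ``binomial`` -- subsets of size exactly K: C(N, K) letters, each carrying
  floor(log2 C(N, K)) bits;
* ``binary`` -- all 2^N - 1 non-empty subsets, carrying N - 1 bits.

Integer letter values map to subsets through the combinatorial number system
in colexicographic order, so rank/unrank run in O(K) without lookup tables.
Only the first 2^r subsets are addressable as data; the remainder are
reserved and invalid on decode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb
from pathlib import Path

__all__ = [
    "ShortmerSet",
    "CombinatorialAlphabet",
    "CombinatorialLetter",
    "build_shortmer_set",
    "alphabet_size",
    "bits_per_letter",
    "rank_letter",
    "unrank_letter",
    "default_omega",
    "write_omega",
    "read_omega",
]

_BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def _max_homopolymer_run(s: str) -> int:
    best = run = 1
    for i in range(1, len(s)):
        run = run + 1 if s[i] == s[i - 1] else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class ShortmerSet:
    """An ordered set of N k-mers with minimum pairwise Hamming distance d."""

    kmers: tuple[str, ...]
    d: int

    def __post_init__(self):
        if not self.kmers:
            raise ValueError("empty shortmer set")
        k = len(self.kmers[0])
        if any(len(x) != k for x in self.kmers):
            raise ValueError("all k-mers must have equal length")
        if any(set(x) - set(_BASES) for x in self.kmers):
            raise ValueError("k-mers must be over {A,C,G,T}")
        if len(set(self.kmers)) != len(self.kmers):
            raise ValueError("k-mers must be unique")
        for i in range(len(self.kmers)):
            for j in range(i + 1, len(self.kmers)):
                if hamming(self.kmers[i], self.kmers[j]) < self.d:
                    raise ValueError(
                        f"pair ({self.kmers[i]}, {self.kmers[j]}) closer than d={self.d}"
                    )

    @property
    def k(self) -> int:
        return len(self.kmers[0])

    @property
    def N(self) -> int:
        return len(self.kmers)

    def __len__(self) -> int:
        return self.N

    def index(self, kmer: str) -> int:
        return self.kmers.index(kmer)


def build_shortmer_set(
    k: int,
    N: int,
    d: int,
    *,
    gc_min: float | None = None,
    gc_max: float | None = None,
    max_homopolymer: int | None = None,
) -> ShortmerSet:
    """Greedy construction of a shortmer set.

    Walks all 4^k candidates in lexicographic order, accepting a candidate iff
    it is at Hamming distance >= d from every accepted k-mer and passes the
    optional GC-fraction / homopolymer filters. Deterministic given its inputs.
    Raises if fewer than N candidates survive.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    if d < 1 or N < 1:
        raise ValueError("need d >= 1 and N >= 1")
    accepted: list[str] = []
    for tup in product(_BASES, repeat=k):
        cand = "".join(tup)
        if gc_min is not None or gc_max is not None:
            gc = (cand.count("G") + cand.count("C")) / k
            if gc_min is not None and gc < gc_min:
                continue
            if gc_max is not None and gc > gc_max:
                continue
        if max_homopolymer is not None and _max_homopolymer_run(cand) > max_homopolymer:
            continue
        if all(hamming(cand, a) >= d for a in accepted):
            accepted.append(cand)
            if len(accepted) == N:
                return ShortmerSet(tuple(accepted), d)
    raise ValueError(
        f"infeasible: only {len(accepted)} k-mers satisfy (k={k}, d={d}) "
        f"with the given filters; {N} requested"
    )


_DEFAULT_OMEGA: ShortmerSet | None = None


def default_omega() -> ShortmerSet:
    """The package's default building-block set: greedy (k=3, N=16, d=2)."""
    global _DEFAULT_OMEGA
    if _DEFAULT_OMEGA is None:
        _DEFAULT_OMEGA = build_shortmer_set(3, 16, 2)
    return _DEFAULT_OMEGA


def alphabet_size(scheme: str, N: int, K: int | None = None) -> int:
    if scheme == "binomial":
        if K is None or not 1 <= K <= N:
            raise ValueError("binomial scheme needs 1 <= K <= N")
        return comb(N, K)
    if scheme == "binary":
        return (1 << N) - 1
    raise ValueError(f"unknown scheme {scheme!r}")


def bits_per_letter(scheme: str, N: int, K: int | None = None) -> int:
    return alphabet_size(scheme, N, K).bit_length() - 1


@dataclass(frozen=True)
class CombinatorialAlphabet:
    """An alphabet of subset-letters over a shortmer set."""

    scheme: str
    omega: ShortmerSet
    K: int | None = None

    def __post_init__(self):
        alphabet_size(self.scheme, self.omega.N, self.K)  # validates

    @classmethod
    def binomial(cls, omega: ShortmerSet, K: int) -> "CombinatorialAlphabet":
        return cls("binomial", omega, K)

    @classmethod
    def binary(cls, omega: ShortmerSet) -> "CombinatorialAlphabet":
        return cls("binary", omega)

    @property
    def N(self) -> int:
        return self.omega.N

    @property
    def size(self) -> int:
        return alphabet_size(self.scheme, self.omega.N, self.K)

    @property
    def bits_per_letter(self) -> int:
        return self.size.bit_length() - 1

    @property
    def n_values(self) -> int:
        """Number of addressable data values (2^r)."""
        return 1 << self.bits_per_letter


@dataclass(frozen=True)
class CombinatorialLetter:
    """A letter: an N-bit membership vector plus its data value (if assigned)."""

    membership: tuple[int, ...]
    value: int | None = None

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.membership):
            raise ValueError("membership must be a binary vector")
        if not any(self.membership):
            raise ValueError("membership must be non-empty")

    @property
    def members(self) -> tuple[int, ...]:
        """Indices (0-based) of the member k-mers."""
        return tuple(i for i, b in enumerate(self.membership) if b)

    @property
    def weight(self) -> int:
        return sum(self.membership)

    def member_kmers(self, omega: ShortmerSet) -> tuple[str, ...]:
        return tuple(omega.kmers[i] for i in self.members)


def _members_to_membership(members, N: int) -> tuple[int, ...]:
    v = [0] * N
    for m in members:
        v[m] = 1
    return tuple(v)


def unrank_letter(value: int, alphabet: CombinatorialAlphabet) -> CombinatorialLetter:
    """Map an integer in [0, 2^r) to its letter.

    Binomial scheme: the ``value``-th K-subset in colexicographic order
    (combinatorial number system); unrank(0) is {X_1..X_K}. Binary scheme:
    membership integer value + 1 (bit i marks X_{i+1}).
    """
    if not 0 <= value < alphabet.n_values:
        raise ValueError(f"value {value} outside [0, {alphabet.n_values})")
    N = alphabet.N
    if alphabet.scheme == "binary":
        m = value + 1
        return CombinatorialLetter(tuple((m >> i) & 1 for i in range(N)), value)
    K = alphabet.K
    members = []
    v = value
    c = N - 1
    for i in range(K, 0, -1):
        while comb(c, i) > v:
            c -= 1
        members.append(c)
        v -= comb(c, i)
        c -= 1
    return CombinatorialLetter(_members_to_membership(members, N), value)


def rank_letter(letter: CombinatorialLetter | tuple[int, ...],
                alphabet: CombinatorialAlphabet) -> int:
    """Inverse of :func:`unrank_letter`; raises for reserved/invalid subsets."""
    membership = letter.membership if isinstance(letter, CombinatorialLetter) else tuple(letter)
    if len(membership) != alphabet.N:
        raise ValueError("membership length does not match alphabet N")
    members = [i for i, b in enumerate(membership) if b]
    if alphabet.scheme == "binary":
        m = 0
        for i in members:
            m |= 1 << i
        value = m - 1
    else:
        if len(members) != alphabet.K:
            raise ValueError(f"membership weight {len(members)} != K={alphabet.K}")
        value = sum(comb(c, i + 1) for i, c in enumerate(sorted(members)))
    if value >= alphabet.n_values:
        raise ValueError(f"subset ranks {value}, beyond the addressable 2^r values")
    return value


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_omega(omega: ShortmerSet, path: str | Path, fmt: str = "txt") -> None:
    """Write Omega one-k-mer-per-line (``txt``) or as FASTA (``fasta``)."""
    path = Path(path)
    if fmt == "txt":
        path.write_text("\n".join(omega.kmers) + "\n")
    elif fmt == "fasta":
        path.write_text(
            "".join(f">X{i + 1}\n{kmer}\n" for i, kmer in enumerate(omega.kmers))
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_omega(path: str | Path, d: int = 1) -> ShortmerSet:
    """Read Omega from one-k-mer-per-line or FASTA text; verifies distance d."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        kmers = tuple(ln.upper() for ln in lines if not ln.startswith(">"))
    else:
        kmers = tuple(ln.upper() for ln in lines)
    return ShortmerSet(kmers, d)
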