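"""Message reconstruction from a read pool.

Pipeline: decode the RS(6,8) barcode prefix of every read and group reads by
barcode (undecodable prefixes are routed to "No BC"); discard groups smaller
than 10% of the nominal sampling rate S; slice each surviving read at fixed
offsets into per-position k-mers (reads whose length differs from the design
by more than k-1 are discarded -- the Delta rule); assign each slice to its
nearest Omega member within a Hamming radius, or to the dummy pseudo-k-mer
X_dummy; call each position's letter as the K most common k-mers seen at
least t times; then run the 2D RS decode -- inner payload code per row (with
unresolved letters as erasures), dummy rows for missing barcodes, outer
column code per block (missing/failed rows as erasures) -- and strip padding.

Stage-wise normalized Levenshtein metrics (against a known design) follow the
simulation bookkeeping: stage iv before any RS, stage iii after the inner
payload code, stage ii after the full 2D decode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from . import ecc
from .alphabet import CombinatorialAlphabet, ShortmerSet, rank_letter
from .codec import (CombinatorialSequence, EncodingParams, generate_barcodes,
                    _strip_padding, _info_value)
from .simulator import ReadPool

__all__ = [
    "ReconstructionParams",
    "CountsMatrix",
    "ReconstructionMetrics",
    "ReconstructionError",
    "group_reads",
    "extract_position_kmers",
    "infer_letter",
    "counts_matrix",
    "reconstruct_message",
    "levenshtein",
    "normalized_levenshtein",
]

_B2 = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2[_b] = _i


class ReconstructionError(RuntimeError):
    """Raised in strict mode when a block exceeds outer correction capacity."""


@dataclass(frozen=True)
class ReconstructionParams:
    """Inference thresholds.

    ``t``: copies required per inferred k-mer. ``kmer_hamming_max``: slice
    assignment radius, default max(1, d//2); a slice is assigned only when its
    nearest member within the radius is unique, otherwise it becomes X_dummy.
    In a maximal d=2 trimer set every substituted k-mer ties between members,
    so substitutions are *detected* (dummy) rather than mis-assigned; sparser
    sets genuinely correct within the radius. ``group_min_frac``: groups below
    this fraction of the nominal per-sequence sampling rate S are discarded.
    """

    t: int = 1
    kmer_hamming_max: int | None = None
    group_min_frac: float = 0.10
    nominal_reads_per_seq: float | None = None   # S; inferred from pool if None
    levenshtein_denominator: str = "observed"    # "observed" (|O|) or "expected"

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.levenshtein_denominator not in ("observed", "expected"):
            raise ValueError("denominator must be 'observed' or 'expected'")

    def radius(self, omega: ShortmerSet) -> int:
        if self.kmer_hamming_max is not None:
            return self.kmer_hamming_max
        return max(1, omega.d // 2)


@dataclass
class CountsMatrix:
    """Per-position member-k-mer counts for one read group.

    ``counts`` is (positions, N+1); the last column is X_dummy (slices not
    assignable within the Hamming radius).
    """

    counts: np.ndarray
    n_reads: int = 0
    n_skipped: int = 0            # reads discarded by the Delta rule
    n_nonzero_distance: int = 0   # reads with >= 1 non-exact (or dummy) slice


@dataclass
class ReconstructionMetrics:
    """Stage-wise error accounting for one reconstruction run."""

    nl_pre_rs: float | None = None         # stage iv
    nl_post_payload_rs: float | None = None  # stage iii
    nl_post_2d_rs: float | None = None     # stage ii
    letter_error_rate: float | None = None
    dropout_count: int = 0
    n_groups: int = 0
    n_reads_no_barcode: int = 0
    n_groups_filtered: int = 0
    inner_decode_failures: int = 0
    outer_column_failures: int = 0


# ---------------------------------------------------------------------------
# k-mer lookup tables
# ---------------------------------------------------------------------------

def _kmer_tables(omega: ShortmerSet, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """For every possible k-mer (base-4 code): (assigned member index or N for
    X_dummy, Hamming distance to the assignment or k+1 for dummy).

    A k-mer is assigned only when its nearest member within ``radius`` is
    unique; ties and out-of-radius k-mers count as X_dummy.
    """
    k, N = omega.k, omega.N
    codes = np.arange(4 ** k)
    digits = (codes[:, None] // (4 ** np.arange(k - 1, -1, -1))[None, :]) % 4
    members = np.array([[_B2[ord(c)] for c in kmer] for kmer in omega.kmers])
    dists = (digits[:, None, :] != members[None, :, :]).sum(axis=2)  # (4^k, N)
    best = dists.min(axis=1)
    n_best = (dists == best[:, None]).sum(axis=1)
    assign = np.where((best <= radius) & (n_best == 1), dists.argmin(axis=1), N)
    dist = np.where(assign < N, best, k + 1)
    return assign.astype(np.int64), dist.astype(np.int64)


def _reads_to_codes(reads: list[str], bc_len: int, L: int, k: int) -> np.ndarray:
    """Base-4 codes of the L fixed-offset payload slices of same-length reads."""
    n = len(reads)
    buf = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(n, -1)
    payload = _B2[buf[:, bc_len:bc_len + k * L]].reshape(n, L, k).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    return payload @ weights


def extract_position_kmers(read: str, params: EncodingParams,
                           rparams: ReconstructionParams = ReconstructionParams()
                           ) -> list[int | None] | None:
    """Per-position Omega assignments of one read (None = X_dummy), or None
    if the read is discarded by the Delta rule."""
    omega = params.alphabet.omega
    k, L = omega.k, params.sequence_len
    bc_len = params.coded_barcode_len
    expected = bc_len + k * L
    delta = expected - len(read)
    if abs(delta) > k - 1:
        return None
    assign, _ = _kmer_tables(omega, rparams.radius(omega))
    out: list[int | None] = []
    for pos in range(L):
        start = bc_len + pos * k
        sl = read[start:start + k]
        if len(sl) < k:
            out.append(None)
            continue
        code = 0
        for ch in sl:
            b = _B2[ord(ch)]
            if b > 3:
                code = -1
                break
            code = code * 4 + int(b)
        a = int(assign[code]) if code >= 0 else omega.N
        out.append(None if a == omega.N else a)
    return out


def counts_matrix(reads: list[str], params: EncodingParams,
                  rparams: ReconstructionParams = ReconstructionParams()
                  ) -> CountsMatrix:
    """Per-position member counts over a read group (vectorized over the
    dominant exact-length reads; length-shifted survivors handled per read)."""
    omega = params.alphabet.omega
    k, N, L = omega.k, omega.N, params.sequence_len
    bc_len = params.coded_barcode_len
    expected = bc_len + k * L
    assign, dist = _kmer_tables(omega, rparams.radius(omega))

    counts = np.zeros((L, N + 1), dtype=np.int64)
    n_skipped = 0
    n_nonzero = 0
    exact: list[str] = []
    shifted: list[str] = []
    for r in reads:
        delta = expected - len(r)
        if abs(delta) > k - 1:
            n_skipped += 1
        elif delta == 0:
            exact.append(r)
        else:
            shifted.append(r)

    if exact:
        codes = _reads_to_codes(exact, bc_len, L, k)     # (n, L)
        a = assign[codes]
        flat = (np.arange(L)[None, :] * (N + 1) + a).ravel()
        counts += np.bincount(flat, minlength=L * (N + 1)).reshape(L, N + 1)
        n_nonzero += int(((dist[codes] > 0).any(axis=1)).sum())

    for r in shifted:
        nz = False
        avail = (len(r) - bc_len) // k
        for pos in range(min(L, avail)):
            sl = r[bc_len + pos * k: bc_len + (pos + 1) * k]
            code = 0
            ok = True
            for ch in sl:
                b = _B2[ord(ch)]
                if b > 3:
                    ok = False
                    break
                code = code * 4 + int(b)
            a = int(assign[code]) if ok else N
            counts[pos, a] += 1
            nz = nz or (not ok) or dist[code] > 0
        n_nonzero += nz

    return CountsMatrix(counts, n_reads=len(reads) - n_skipped,
                        n_skipped=n_skipped, n_nonzero_distance=n_nonzero)


# ---------------------------------------------------------------------------
# letter inference
# ---------------------------------------------------------------------------

def infer_letter(counts_row, K: int, t: int = 1
                 ) -> tuple[tuple[int, ...] | None, bool]:
    """The K most common member k-mers with count >= t.

    Returns ``(members, ambiguous)``; ``members`` is None when fewer than K
    k-mers reach the threshold (the letter stays unresolved and propagates as
    an erasure). Ties at the K-th rank break toward the lowest Omega index and
    set the ambiguity flag.
    """
    c = np.asarray(counts_row)
    if K > c.size:
        raise ValueError("K exceeds the number of candidate k-mers")
    order = np.lexsort((np.arange(c.size), -c))  # by count desc, then index
    top = order[:K]
    if c[top[-1]] < t:
        return None, False
    ambiguous = bool(K < c.size and c[order[K]] == c[top[-1]])
    return tuple(sorted(int(i) for i in top)), ambiguous


def _letter_value(members: tuple[int, ...] | None,
                  alphabet: CombinatorialAlphabet) -> int | None:
    """Letter value of an inferred member set; None when unresolved/reserved."""
    if members is None:
        return None
    membership = [0] * alphabet.N
    for m in members:
        membership[m] = 1
    try:
        return rank_letter(tuple(membership), alphabet)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _barcode_symbols(reads: list[str], bc_len: int) -> tuple[np.ndarray, np.ndarray]:
    """GF(2^4) symbol matrix of each read's barcode prefix; second array flags
    reads that are long enough and pure ACGT in the prefix."""
    n = len(reads)
    ok = np.array([len(r) >= bc_len for r in reads])
    prefix = "".join(r[:bc_len] if len(r) >= bc_len else "A" * bc_len for r in reads)
    buf = _B2[np.frombuffer(prefix.encode(), dtype=np.uint8)].reshape(n, bc_len)
    ok &= (buf <= 3).all(axis=1)
    buf = np.where(buf > 3, 0, buf)
    sym = (buf[:, 0::2].astype(np.int64) << 2) | buf[:, 1::2]
    return sym, ok


def group_reads(pool: ReadPool, barcodes: list[str],
                params: EncodingParams,
                rparams: ReconstructionParams = ReconstructionParams()
                ) -> tuple[dict[int, list[str]], ReconstructionMetrics]:
    """Group reads by decoded barcode.

    ``barcodes`` are the designed 12 nt data barcodes in row order. Returns
    ``{row_index: reads}`` (groups failing the 10%-of-S filter removed) plus
    partially filled metrics (No-BC and filter counts).
    """
    met = ReconstructionMetrics()
    groups: dict[int, list[str]] = {}
    row_of = {bc: i for i, bc in enumerate(barcodes)}
    if params.rs_barcode is None:
        bl = params.barcode_len
        for r in pool.reads:
            row = row_of.get(r[:bl])
            if row is None:
                met.n_reads_no_barcode += 1
            else:
                groups.setdefault(row, []).append(r)
    else:
        code = ecc.BARCODE_CODE
        bl = params.coded_barcode_len
        sym, ok = _barcode_symbols(pool.reads, bl)
        synd = np.zeros((len(pool.reads), code.parity), dtype=np.int64)
        if len(pool.reads):
            synd = ecc.rs_syndromes_batch(sym, code)
        clean = ok & (synd == 0).all(axis=1)
        for i, r in enumerate(pool.reads):
            if not ok[i]:
                met.n_reads_no_barcode += 1
                continue
            if clean[i]:
                bc12 = r[:12]
            else:
                try:
                    bc12, _ = ecc.decode_barcode(r[:bl])
                except ecc.RSDecodeFailure:
                    met.n_reads_no_barcode += 1
                    continue
            row = row_of.get(bc12)
            if row is None:
                met.n_reads_no_barcode += 1
            else:
                groups.setdefault(row, []).append(r)

    S = rparams.nominal_reads_per_seq
    if S is None:
        S = len(pool.reads) / max(1, len(barcodes))
    min_reads = rparams.group_min_frac * S
    kept = {}
    for row, rs in groups.items():
        if len(rs) < min_reads:
            met.n_groups_filtered += 1
        else:
            kept[row] = rs
    met.n_groups = len(kept)
    return kept, met


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

def _as_ints(seq) -> np.ndarray:
    if isinstance(seq, str):
        return np.frombuffer(seq.encode("utf-32-le"), dtype=np.uint32).astype(np.int64)
    if isinstance(seq, (bytes, bytearray)):
        return np.frombuffer(bytes(seq), dtype=np.uint8).astype(np.int64)
    return np.asarray(list(seq), dtype=np.int64)


def levenshtein(a, b) -> int:
    """Edit distance between two symbol sequences (strings, bytes, or ints)."""
    x, y = _as_ints(a), _as_ints(b)
    if x.size == 0 or y.size == 0:
        return int(x.size or y.size)
    prev = np.arange(y.size + 1, dtype=np.int64)
    idx = np.arange(y.size + 1, dtype=np.int64)
    for i in range(1, x.size + 1):
        tmp = np.minimum(prev[1:] + 1, prev[:-1] + (y != x[i - 1]))
        full = np.concatenate(([i], tmp))
        # fold in the left-to-right insertion chain:
        # cur[j] = min_{j0 <= j} (full[j0] + (j - j0))
        prev = np.minimum.accumulate(full - idx) + idx
    return int(prev[-1])


def normalized_levenshtein(observed, expected,
                           denominator: str = "observed") -> float:
    """Edit distance divided by |O| (or by |E| with denominator='expected')."""
    o, e = _as_ints(observed), _as_ints(expected)
    if o.size == 0:
        raise ValueError("observed sequence must be non-empty")
    denom = o.size if denominator == "observed" else e.size
    if denom == 0:
        raise ValueError("empty denominator sequence")
    return levenshtein(o, e) / denom


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _mean_nl(obs_rows, exp_rows, denominator) -> float:
    vals = [normalized_levenshtein(o, e, denominator)
            for o, e in zip(obs_rows, exp_rows)]
    return float(np.mean(vals)) if vals else 0.0


def reconstruct_message(pool: ReadPool, params: EncodingParams,
                        rparams: ReconstructionParams = ReconstructionParams(),
                        design: list[CombinatorialSequence] | None = None,
                        n_rows: int | None = None,
                        strict: bool = False
                        ) -> tuple[str, ReconstructionMetrics]:
    """Recover the stored bit string from a read pool.

    ``design`` (the encoder's output) supplies the barcode order and, when
    present, the reference rows for stage metrics; otherwise ``n_rows`` lets
    the deterministic barcode list be regenerated. With ``strict`` a block
    whose outer capacity is exceeded raises :class:`ReconstructionError`;
    otherwise uncorrectable columns are passed through and counted.
    """
    if design is not None:
        barcodes = [s.data_barcode for s in design]
    elif n_rows is not None:
        barcodes = generate_barcodes(n_rows, params.barcode_len,
                                     params.barcode_min_distance,
                                     params.barcode_seed)
    else:
        raise ValueError("need design or n_rows to order the barcodes")

    alphabet = params.alphabet
    L = params.sequence_len
    l = params.payload_len
    total = len(barcodes)
    denom = rparams.levenshtein_denominator

    groups, met = group_reads(pool, barcodes, params, rparams)

    observed = np.zeros((total, L), dtype=np.int64)
    unresolved = np.zeros((total, L), dtype=bool)
    row_missing = np.ones(total, dtype=bool)
    K = alphabet.K if alphabet.scheme == "binomial" else None
    for row, reads in groups.items():
        cm = counts_matrix(reads, params, rparams)
        row_missing[row] = False
        for pos in range(L):
            if K is not None:
                members, _ = infer_letter(cm.counts[pos, :alphabet.N], K, rparams.t)
            else:  # binary scheme: members = all k-mers with count >= t
                idx = np.flatnonzero(cm.counts[pos, :alphabet.N] >= rparams.t)
                members = tuple(int(i) for i in idx) if idx.size else None
            value = _letter_value(members, alphabet)
            if value is None:
                unresolved[row, pos] = True
            else:
                observed[row, pos] = value
    met.dropout_count = int(row_missing.sum())

    if design is not None:
        exp_rows = [list(s.payload) for s in design]
        met.nl_pre_rs = _mean_nl([observed[i] for i in range(total)], exp_rows, denom)
        err = (observed != np.array(exp_rows)) | unresolved
        met.letter_error_rate = float(err.mean())

    # inner (payload) RS decode, unresolved letters as erasures
    pc = params.payload_code
    inner = observed.copy()
    row_failed = row_missing.copy()
    if pc is not None:
        for i in range(total):
            if row_missing[i]:
                continue
            era = np.flatnonzero(unresolved[i]).tolist()
            try:
                inner[i, :l] = ecc.rs_decode(observed[i], pc, erasures=era)
                # re-encode so parity symbols are consistent for the outer code
                inner[i] = ecc.rs_encode(inner[i, :l], pc)
            except ecc.RSDecodeFailure:
                row_failed[i] = True
                met.inner_decode_failures += 1

    if design is not None:
        met.nl_post_payload_rs = _mean_nl(
            [inner[i, :l] for i in range(total)],
            [row[:l] for row in exp_rows], denom)

    # outer (block) RS decode, missing/failed rows as erasures
    bc = params.block_code
    if bc is not None:
        if total % bc.total_len:
            raise ValueError("barcode count is not a multiple of the coded block size")
        data_rows = []
        for start in range(0, total, bc.total_len):
            block = inner[start:start + bc.total_len]
            era = np.flatnonzero(row_failed[start:start + bc.total_len]).tolist()
            fixed = np.array(block[:bc.data_len], copy=True)
            for j in range(L):
                try:
                    fixed[:, j] = ecc.rs_decode(block[:, j], bc, erasures=era)
                except ecc.RSDecodeFailure:
                    met.outer_column_failures += 1
            if strict and met.outer_column_failures:
                raise ReconstructionError(
                    f"outer code exceeded in block starting at row {start}")
            data_rows.append(fixed)
        final = np.concatenate(data_rows, axis=0)
    else:
        final = inner

    final_data = final[:, :l]
    if design is not None:
        if bc is not None:  # design rows are block-ordered with parity rows interleaved
            data_idx = [b * bc.total_len + j
                        for b in range(total // bc.total_len)
                        for j in range(bc.data_len)]
        else:
            data_idx = list(range(final_data.shape[0]))
        met.nl_post_2d_rs = _mean_nl(
            [final_data[i] for i in range(final_data.shape[0])],
            [exp_rows[i][:l] for i in data_idx], denom)

    # strip padding and emit bits
    if bc is not None:
        info = _info_value(final_data[-1], params.r)
        rows = [final_data[i].tolist() for i in range(final_data.shape[0] - 1)]
        capacity = len(rows) * l * params.r
        max_pad = (params.r - 1) + params.r * ((l - 1) + l * (params.block_size - 1))
        if info > max_pad or info >= capacity:
            raise ValueError(f"inconsistent padding info: {info} bits")
        bits = _strip_padding(rows, params, capacity - info)
    else:
        raise ValueError("reconstruct_message requires the outer block code; "
                         "decode block-less layouts with codec.decode_message")
    return bits, met
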