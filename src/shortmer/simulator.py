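"""Synthesis, error, mixing and sampling simulation.

This module is the package's synthetic-data generator: it emulates the
physical channel of a combinatorial shortmer storage system.

* **Synthesis**: each designed sequence is synthesized in ``X ~ Normal(mu=1000,
  sd=10)`` copies (rounded, clamped at 0). Every copy independently draws one
  member k-mer uniformly at each payload position. Deletions (probability
  ``p_del`` per synthesized k-mer) and insertions (probability ``p_ins`` per
  cycle slot, inserting a uniformly random Omega k-mer before the slot, plus
  one terminal slot) happen at the k-mer level during elongation. Barcodes are
  standard DNA synthesis: error-free at the k-mer level, though an optional
  per-base indel rate can be enabled.
* **Sequencing errors**: substitutions at the single-base level, each base
  independently replaced with probability ``p_sub`` by one of the other three
  bases.
* **Mixing and sampling**: the pool is globally shuffled and
  ``round(Normal(S * n_sequences, sd=100))`` reads are drawn without
  replacement (clamped to the pool size).

All randomness flows from explicit seeds; identical seeds give identical
pools. Source labels ride along for diagnostics only -- reconstruction never
reads them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import CombinatorialAlphabet
from .codec import CombinatorialSequence

__all__ = [
    "ErrorRates",
    "SynthesisParams",
    "SamplingParams",
    "ReadPool",
    "synthesize",
    "apply_sequencing_errors",
    "mix_and_sample",
    "write_reads",
    "read_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorRates:
    """Channel error probabilities."""

    p_del: float = 0.0   # per synthesized k-mer
    p_ins: float = 0.0   # per cycle slot
    p_sub: float = 0.0   # per sequenced base
    barcode_indel_rate: float = 0.0  # per barcode base (standard synthesis)

    def __post_init__(self):
        for v in (self.p_del, self.p_ins, self.p_sub, self.barcode_indel_rate):
            if not 0 <= v <= 1:
                raise ValueError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class SynthesisParams:
    copies_mean: float = 1000.0
    copies_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.copies_mean <= 0 or self.copies_sd < 0:
            raise ValueError("need copies_mean > 0 and copies_sd >= 0")


@dataclass(frozen=True)
class SamplingParams:
    reads_mean: float         # S: mean reads per designed sequence
    reads_sd: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.reads_mean < 0 or self.reads_sd < 0:
            raise ValueError("need reads_mean >= 0 and reads_sd >= 0")


@dataclass
class ReadPool:
    """A multiset of DNA reads with optional diagnostic source labels."""

    reads: list[str]
    labels: np.ndarray | None = None  # designed-sequence index per read

    def __post_init__(self):
        if self.labels is not None and len(self.labels) != len(self.reads):
            raise ValueError("labels length must match reads")

    def __len__(self) -> int:
        return len(self.reads)


def _draw_count(rng, mean: float, sd: float) -> int:
    return max(0, int(round(rng.normal(mean, sd))))


def _molecules_for_sequence(seq: CombinatorialSequence,
                            alphabet: CombinatorialAlphabet,
                            copies: int, rates: ErrorRates, rng) -> list[str]:
    """All synthesized copies of one designed sequence."""
    if copies == 0:
        return []
    omega = alphabet.omega
    k = omega.k
    kmer_bytes = np.array([s.encode() for s in omega.kmers], dtype=f"S{k}")
    members = seq.member_matrix(alphabet)
    L = len(members)
    weights = {len(m) for m in members}
    if len(weights) == 1:  # binomial: fixed K, fully vectorized draw
        member_arr = np.array(members, dtype=np.int64)  # (L, K)
        choice = rng.integers(0, member_arr.shape[1], size=(copies, L))
        kmer_idx = member_arr[np.arange(L)[None, :], choice]  # (copies, L)
    else:  # binary scheme: ragged subsets, draw column by column
        kmer_idx = np.empty((copies, L), dtype=np.int64)
        for pos, mem in enumerate(members):
            mem_arr = np.array(mem, dtype=np.int64)
            kmer_idx[:, pos] = mem_arr[rng.integers(0, len(mem), size=copies)]

    barcode = seq.barcode
    if rates.barcode_indel_rate > 0:
        barcodes = [_indel_barcode(barcode, rates.barcode_indel_rate, rng)
                    for _ in range(copies)]
    else:
        barcodes = None

    if rates.p_del == 0 and rates.p_ins == 0:
        rows = kmer_bytes[kmer_idx]                       # (copies, L) of S<k>
        joined = np.ascontiguousarray(rows).view(f"S{k * L}").ravel()
        if barcodes is None:
            return [barcode + j.decode() for j in joined]
        return [b + j.decode() for b, j in zip(barcodes, joined)]

    del_mask = rng.random((copies, L)) < rates.p_del
    ins_mask = rng.random((copies, L + 1)) < rates.p_ins
    ins_kmer = rng.integers(0, omega.N, size=(copies, L + 1))
    dirty = del_mask.any(axis=1) | ins_mask.any(axis=1)

    out: list[str] = [""] * copies
    clean_idx = np.flatnonzero(~dirty)
    if clean_idx.size:
        rows = kmer_bytes[kmer_idx[clean_idx]]
        joined = np.ascontiguousarray(rows).view(f"S{k * L}").ravel()
        for i, j in zip(clean_idx, joined):
            out[i] = j.decode()
    kmers = omega.kmers
    for i in np.flatnonzero(dirty):
        parts: list[str] = []
        for pos in range(L):
            if ins_mask[i, pos]:
                parts.append(kmers[ins_kmer[i, pos]])
            if not del_mask[i, pos]:
                parts.append(kmers[kmer_idx[i, pos]])
        if ins_mask[i, L]:
            parts.append(kmers[ins_kmer[i, L]])
        out[i] = "".join(parts)

    if barcodes is None:
        return [barcode + s for s in out]
    return [b + s for b, s in zip(barcodes, out)]


def _indel_barcode(barcode: str, rate: float, rng) -> str:
    out = []
    for base in barcode:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append("ACGT"[rng.integers(0, 4)])  # insertion before the base
        out.append(base)
    return "".join(out)


def synthesize(sequences: list[CombinatorialSequence],
               alphabet: CombinatorialAlphabet,
               synthesis: SynthesisParams = SynthesisParams(),
               rates: ErrorRates = ErrorRates()) -> ReadPool:
    """Simulate combinatorial synthesis of the designed sequences.

    Returns the molecule pool (pre-sequencing), labelled by source sequence.
    """
    rng = np.random.default_rng(synthesis.seed)
    reads: list[str] = []
    labels: list[np.ndarray] = []
    for idx, seq in enumerate(sequences):
        copies = _draw_count(rng, synthesis.copies_mean, synthesis.copies_sd)
        mols = _molecules_for_sequence(seq, alphabet, copies, rates, rng)
        reads.extend(mols)
        labels.append(np.full(len(mols), idx, dtype=np.int64))
    return ReadPool(reads, np.concatenate(labels) if labels else np.empty(0, np.int64))


def apply_sequencing_errors(pool: ReadPool, p_sub: float, seed: int = 0) -> ReadPool:
    """Substitute each base independently with probability ``p_sub``
    (replacement uniform over the three other bases)."""
    if not 0 <= p_sub <= 1:
        raise ValueError("p_sub must be in [0, 1]")
    if p_sub == 0 or not pool.reads:
        return ReadPool(list(pool.reads),
                        None if pool.labels is None else pool.labels.copy())
    rng = np.random.default_rng(seed)
    lengths = np.fromiter((len(r) for r in pool.reads), dtype=np.int64,
                          count=len(pool.reads))
    buf = np.frombuffer("".join(pool.reads).encode(), dtype=np.uint8).copy()
    hit = rng.random(buf.size) < p_sub
    if hit.any():
        # base index 0..3; replacement = (idx + 1 + U{0,1,2}) mod 4
        code = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
        idx = code[buf[hit]]
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        buf[hit] = _BASES[(idx + shift) % 4]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    raw = buf.tobytes()
    reads = [raw[offsets[i]:offsets[i + 1]].decode() for i in range(len(lengths))]
    return ReadPool(reads, None if pool.labels is None else pool.labels.copy())


def mix_and_sample(pool: ReadPool, sampling: SamplingParams,
                   n_sequences: int | None = None) -> ReadPool:
    """Shuffle the pool and draw ``round(Normal(S * n_sequences, sd))`` reads
    without replacement (clamped to the pool size).

    ``n_sequences`` defaults to the number of distinct source labels.
    """
    rng = np.random.default_rng(sampling.seed)
    if n_sequences is None:
        if pool.labels is None or len(pool.labels) == 0:
            raise ValueError("n_sequences required when the pool has no labels")
        n_sequences = int(np.unique(pool.labels).size)
    want = _draw_count(rng, sampling.reads_mean * n_sequences, sampling.reads_sd)
    n = min(want, len(pool.reads))
    perm = rng.permutation(len(pool.reads))[:n]
    reads = [pool.reads[i] for i in perm]
    labels = pool.labels[perm] if pool.labels is not None else None
    return ReadPool(reads, labels)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_reads(pool: ReadPool, path: str | Path, fmt: str | None = None) -> None:
    """Write reads as FASTQ (constant placeholder qualities) or FASTA."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix in (".fa", ".fasta") else "fastq"
    records = []
    labels = pool.labels
    for i, r in enumerate(pool.reads):
        rid = f"read{i}" if labels is None else f"read{i}|src={int(labels[i])}"
        rec = SeqRecord(Seq(r), id=rid, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_reads(path: str | Path, fmt: str | None = None) -> ReadPool:
    """Read a FASTQ/FASTA file into a pool (sequences uppercased; source
    labels recovered from ids written by :func:`write_reads` when present)."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix in (".fa", ".fasta") else "fastq"
    reads: list[str] = []
    labels: list[int] = []
    have_labels = True
    for rec in SeqIO.parse(str(path), fmt):
        reads.append(str(rec.seq).upper())
        if have_labels and "|src=" in rec.id:
            labels.append(int(rec.id.rsplit("|src=", 1)[1]))
        else:
            have_labels = False
    return ReadPool(reads, np.array(labels, dtype=np.int64) if have_labels and reads else None)
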