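"""Binary message <-> combinatorial sequence conversion.

The encoding pipeline: zero-pad the bit stream to a multiple of r (bits per
letter), map each r-bit word to a letter value, chunk into payloads of l
letters, zero-letter-pad the last partial payload, add whole padding sequences
until the sequence count is B-1 (mod B), and append a single padding-info
sequence carrying the total number of padding bits -- completing the last
block. Each payload is then protected by the inner RS code, every block of B
rows by the column-wise outer RS code, and every row receives the next barcode
in order (RS(6,8)-coded to 16 nt).

Padding letters and sequences use letter value 0; the padding-info count is
written big-endian across the info sequence's letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import ecc
from .alphabet import (
    CombinatorialAlphabet,
    default_omega,
    hamming,
    rank_letter,
    unrank_letter,
)

__all__ = [
    "EncodingParams",
    "MessageLayout",
    "CombinatorialSequence",
    "encode_message",
    "decode_message",
    "encode_bytes",
    "decode_bytes",
    "generate_barcodes",
    "bytes_to_bits",
    "bits_to_bytes",
    "write_design",
    "read_design",
    "write_design_fasta",
    "default_params",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class EncodingParams:
    """Code and layout parameters of the storage system (defaults follow the
    RS(120,134) / RS(42,48) / RS(6,8) design)."""

    alphabet: CombinatorialAlphabet
    payload_len: int = 120            # l: data letters per sequence
    barcode_len: int = 12             # nt, pre-RS
    block_size: int = 42              # B: data sequences per block
    rs_payload: tuple[int, int] | None = (120, 134)
    rs_barcode: tuple[int, int] | None = (6, 8)
    rs_block: tuple[int, int] | None = (42, 48)
    barcode_min_distance: int = 5
    barcode_seed: int = 0

    def __post_init__(self):
        if self.rs_payload is not None and self.rs_payload[0] != self.payload_len:
            raise ValueError("rs_payload data length must equal payload_len")
        if self.rs_block is not None and self.rs_block[0] != self.block_size:
            raise ValueError("rs_block data length must equal block_size")
        if self.rs_barcode is not None:
            if self.barcode_len != 2 * self.rs_barcode[0]:
                raise ValueError("barcode_len must be 2 * rs_barcode data symbols")
        for rs in (self.rs_payload, self.rs_block, self.rs_barcode):
            if rs is not None and rs[1] <= rs[0]:
                raise ValueError("RS total length must exceed data length")

    @property
    def r(self) -> int:
        return self.alphabet.bits_per_letter

    @property
    def sequence_len(self) -> int:
        """Letters per sequence after inner coding."""
        return self.rs_payload[1] if self.rs_payload else self.payload_len

    @property
    def coded_barcode_len(self) -> int:
        return 2 * self.rs_barcode[1] if self.rs_barcode else self.barcode_len

    @property
    def payload_code(self) -> ecc.RSCode | None:
        if self.rs_payload is None:
            return None
        return ecc.RSCode(self.r, *self.rs_payload)

    @property
    def block_code(self) -> ecc.RSCode | None:
        if self.rs_block is None:
            return None
        return ecc.RSCode(self.r, *self.rs_block)

    @property
    def read_len(self) -> int:
        """Expected molecule length in nt: coded barcode + k per coded letter."""
        return self.coded_barcode_len + self.alphabet.omega.k * self.sequence_len


def default_params(K: int = 5, **overrides) -> EncodingParams:
    """Default system: binomial(16, K) over the greedy trimer set."""
    alphabet = CombinatorialAlphabet.binomial(default_omega(), K)
    return EncodingParams(alphabet=alphabet, **overrides)


@dataclass(frozen=True)
class MessageLayout:
    """Padding bookkeeping for one encoded message."""

    message_bits: int
    bit_padding: int
    letter_padding: int
    pad_sequences: int
    n_data_sequences: int
    n_rows: int          # synthesized rows incl. padding-info and outer parity
    r: int               # bits per letter
    payload_len: int     # l

    @property
    def total_padding_bits(self) -> int:
        return self.bit_padding + self.r * (
            self.letter_padding + self.payload_len * self.pad_sequences)


@dataclass(frozen=True)
class CombinatorialSequence:
    """One synthesizable unit: a coded barcode plus a payload of letter values."""

    barcode: str                 # coded (on-molecule) barcode, e.g. 16 nt
    data_barcode: str            # pre-RS barcode, e.g. 12 nt
    payload: tuple[int, ...]     # letter values, coded length after inner RS

    def member_matrix(self, alphabet: CombinatorialAlphabet) -> list[tuple[int, ...]]:
        """Per-position member k-mer indices."""
        return [unrank_letter(v, alphabet).members for v in self.payload]


# ---------------------------------------------------------------------------
# bit helpers
# ---------------------------------------------------------------------------

def bytes_to_bits(data: bytes) -> str:
    return "".join(f"{b:08b}" for b in data)


def bits_to_bytes(bits: str) -> bytes:
    if len(bits) % 8:
        raise ValueError("bit string length must be a multiple of 8")
    return bytes(int(bits[i:i + 8], 2) for i in range(0, len(bits), 8))


def _coerce_bits(bits) -> str:
    if isinstance(bits, (bytes, bytearray)):
        return bytes_to_bits(bytes(bits))
    if isinstance(bits, str):
        if set(bits) - {"0", "1"}:
            raise ValueError("bit string may contain only '0'/'1'")
        return bits
    return "".join("1" if int(b) else "0" for b in bits)


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def generate_barcodes(n: int, length: int = 12, min_distance: int = 5,
                      seed: int = 0) -> list[str]:
    """n unique barcodes of the given length with pairwise Hamming distance >=
    min_distance; deterministic for a given seed. Raises when infeasible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_distance > length:
        raise ValueError("min_distance cannot exceed length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    if length <= 8:  # small space: exhaustive shuffled greedy is exact
        space = 4 ** length
        order = rng.permutation(space)
        for idx in order:
            cand = "".join(_BASES[(int(idx) >> (2 * i)) & 3] for i in range(length))
            if all(hamming(cand, a) >= min_distance for a in accepted):
                accepted.append(cand)
                if len(accepted) == n:
                    return accepted
        raise ValueError(f"infeasible: only {len(accepted)} barcodes of length "
                         f"{length} at distance {min_distance}")
    failures = 0
    while len(accepted) < n:
        cand = "".join(_BASES[b] for b in rng.integers(0, 4, length))
        if all(hamming(cand, a) >= min_distance for a in accepted):
            accepted.append(cand)
            failures = 0
        else:
            failures += 1
            if failures > 20000:
                raise ValueError(
                    f"infeasible: could not extend beyond {len(accepted)} barcodes "
                    f"(length {length}, distance {min_distance})")
    return accepted


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------

def _letters_from_bits(bits: str, r: int) -> tuple[list[int], int]:
    bit_padding = (-len(bits)) % r
    padded = bits + "0" * bit_padding
    letters = [int(padded[i:i + r], 2) for i in range(0, len(padded), r)]
    return letters, bit_padding


def _info_letters(total_padding_bits: int, r: int, l: int) -> list[int]:
    """total_padding_bits written big-endian in base 2^r across l letters."""
    digits = []
    v = total_padding_bits
    for _ in range(l):
        digits.append(v & ((1 << r) - 1))
        v >>= r
    if v:
        raise ValueError("padding count does not fit in the info sequence")
    return digits[::-1]


def _info_value(letters, r: int) -> int:
    v = 0
    for x in letters:
        v = (v << r) | int(x)
    return v


def encode_message(bits, params: EncodingParams) -> tuple[list[CombinatorialSequence], MessageLayout]:
    """Encode a binary message into barcoded, RS-protected combinatorial rows."""
    bits = _coerce_bits(bits)
    if not bits:
        raise ValueError("message must be non-empty")
    r, l = params.r, params.payload_len
    letters, bit_padding = _letters_from_bits(bits, r)
    letter_padding = (-len(letters)) % l
    letters += [0] * letter_padding
    rows = [letters[i:i + l] for i in range(0, len(letters), l)]
    n_data = len(rows)

    pad_sequences = 0
    if params.rs_block is not None:
        B = params.block_size
        pad_sequences = (B - 1 - (n_data % B)) % B
        rows += [[0] * l for _ in range(pad_sequences)]
        total_pad = bit_padding + r * (letter_padding + l * pad_sequences)
        rows.append(_info_letters(total_pad, r, l))

    # inner (payload) code
    pc = params.payload_code
    if pc is not None:
        rows = [list(ecc.rs_encode(row, pc)) for row in rows]

    # outer (block) code
    bc = params.block_code
    if bc is not None:
        coded_rows: list[list[int]] = []
        B = params.block_size
        for start in range(0, len(rows), B):
            block = np.array(rows[start:start + B], dtype=np.int64)
            coded_rows.extend(ecc.encode_block(block, bc).tolist())
        rows = coded_rows

    barcodes = generate_barcodes(len(rows), params.barcode_len,
                                 params.barcode_min_distance, params.barcode_seed)
    sequences = []
    for row, bcode in zip(rows, barcodes):
        coded_bc = ecc.encode_barcode(bcode) if params.rs_barcode else bcode
        sequences.append(CombinatorialSequence(coded_bc, bcode, tuple(int(x) for x in row)))

    layout = MessageLayout(len(bits), bit_padding, letter_padding,
                           pad_sequences, n_data, len(sequences), r, l)
    return sequences, layout


def _strip_padding(data_rows: list[list[int]], params: EncodingParams,
                   message_bits: int) -> str:
    r = params.r
    bits = "".join(f"{int(v):0{r}b}" for row in data_rows for v in row)
    if message_bits > len(bits):
        raise ValueError("inconsistent padding info: message longer than capacity")
    return bits[:message_bits]


def decode_message(sequences: list[CombinatorialSequence] | list[tuple[int, ...]],
                   params: EncodingParams,
                   layout: MessageLayout | None = None) -> str:
    """Invert :func:`encode_message` on a clean (error-free) set of rows.

    Rows must be ordered by barcode rank. With the outer code enabled the
    padding-info sequence is self-describing; without it a ``layout`` must be
    supplied. (Noisy channels go through ``reconstruct.reconstruct_message``.)
    """
    rows = [list(s.payload) if isinstance(s, CombinatorialSequence) else list(s)
            for s in sequences]
    r, l = params.r, params.payload_len
    if any(v >= params.alphabet.n_values or v < 0 for row in rows for v in row):
        raise ValueError(f"invalid letter value >= 2^{r}")

    bc = params.block_code
    if bc is not None:
        if len(rows) % bc.total_len:
            raise ValueError("row count is not a multiple of the coded block size")
        inner_rows: list[list[int]] = []
        for start in range(0, len(rows), bc.total_len):
            block = np.array(rows[start:start + bc.total_len], dtype=np.int64)
            inner_rows.extend(ecc.decode_block(block, bc).tolist())
        rows = inner_rows

    pc = params.payload_code
    if pc is not None:
        rows = [list(ecc.rs_decode(row, pc)) for row in rows]

    if bc is not None:
        info = _info_value(rows[-1], r)
        data_rows = rows[:-1]
        capacity = len(data_rows) * l * r
        max_pad = (r - 1) + r * ((l - 1) + l * (params.block_size - 1))
        if info > max_pad or info >= capacity:
            raise ValueError(f"inconsistent padding info: {info} bits")
        message_bits = capacity - info
    else:
        if layout is None:
            raise ValueError("layout required when the outer block code is disabled")
        data_rows = rows
        message_bits = layout.message_bits
    return _strip_padding(data_rows, params, message_bits)


def encode_bytes(data: bytes, params: EncodingParams):
    return encode_message(bytes_to_bits(data), params)


def decode_bytes(sequences, params: EncodingParams,
                 layout: MessageLayout | None = None) -> bytes:
    return bits_to_bytes(decode_message(sequences, params, layout))


# ---------------------------------------------------------------------------
# design file IO
# ---------------------------------------------------------------------------

def write_design(sequences: list[CombinatorialSequence],
                 alphabet: CombinatorialAlphabet, path: str | Path) -> None:
    """Tab-separated design file: coded barcode, data barcode, then per
    position the semicolon-joined member k-mers."""
    lines = []
    for s in sequences:
        cols = [s.barcode, s.data_barcode]
        for v in s.payload:
            cols.append(";".join(unrank_letter(v, alphabet).member_kmers(alphabet.omega)))
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_design(path: str | Path,
                alphabet: CombinatorialAlphabet) -> list[CombinatorialSequence]:
    sequences = []
    omega = alphabet.omega
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cols = line.split("\t")
        barcode, data_barcode, payload_cols = cols[0], cols[1], cols[2:]
        values = []
        for col in payload_cols:
            members = tuple(omega.index(kmer) for kmer in col.split(";"))
            membership = [0] * omega.N
            for m in members:
                membership[m] = 1
            values.append(rank_letter(tuple(membership), alphabet))
        sequences.append(CombinatorialSequence(barcode, data_barcode, tuple(values)))
    return sequences


def write_design_fasta(sequences: list[CombinatorialSequence],
                       alphabet: CombinatorialAlphabet, path: str | Path) -> None:
    """FASTA of each row's expected full-length concatenation (one molecule
    variant per member choice is not enumerated; member k-mers are joined by
    ';' within a position -- this is the expected *composition*, not a single
    molecule)."""
    omega = alphabet.omega
    with open(path, "w") as fh:
        for i, s in enumerate(sequences):
            body = s.barcode + "".join(
                "(" + ";".join(unrank_letter(v, alphabet).member_kmers(omega)) + ")"
                for v in s.payload)
            fh.write(f">seq{i}|{s.data_barcode}\n{body}\n")
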