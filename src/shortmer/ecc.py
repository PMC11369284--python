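"""Systematic Reed-Solomon codes and the 2D protection scheme.

Three codes protect a stored message:

* a barcode code -- RS(6,8) over GF(2^4), mapping each 12 nt barcode to 16 nt
  (two bases per field symbol);
* an inner payload code -- RS(120,134) over GF(2^12) by default -- along each
  sequence's combinatorial letters;
* an outer block code -- RS(42,48) by default -- applied column-wise across
  the sequences of a block, protecting against whole-sequence dropouts.

Note the (data,total) parameter order used throughout: RS(120,134) means 120
data symbols extended to 134, i.e. 14 parity symbols. Decoding corrects any
combination of e errors and s erasures with 2e + s <= parity, and raises
:class:`RSDecodeFailure` (never silently returns a non-codeword) beyond that.

Because both the inner and outer codes are linear over the same field, the
outer parity rows of a block of inner codewords are themselves valid inner
codewords; the decoder exploits this by inner-decoding every row of a block.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._gf import GF, gf

__all__ = [
    "RSCode",
    "RSDecodeFailure",
    "rs_encode",
    "rs_decode",
    "rs_syndromes_batch",
    "BARCODE_CODE",
    "encode_barcode",
    "decode_barcode",
    "encode_block",
    "decode_block",
]

# First consecutive root of the generator polynomial: g(x) has roots
# alpha^FCR .. alpha^(FCR+parity-1).
_FCR = 1


class RSDecodeFailure(ValueError):
    """Raised when a received word is beyond the code's correction capacity."""


@dataclass(frozen=True)
class RSCode:
    """A systematic RS code with ``data_len`` data and ``total_len`` total symbols."""

    field_bits: int
    data_len: int
    total_len: int

    def __post_init__(self):
        if not 1 <= self.data_len < self.total_len:
            raise ValueError("need 1 <= data_len < total_len")
        if self.total_len > (1 << self.field_bits) - 1:
            raise ValueError(
                f"total_len {self.total_len} exceeds field bound "
                f"{(1 << self.field_bits) - 1} for GF(2^{self.field_bits})"
            )

    @property
    def parity(self) -> int:
        return self.total_len - self.data_len

    @property
    def field(self) -> GF:
        return gf(self.field_bits)


@lru_cache(maxsize=None)
def _generator_poly(field_bits: int, parity: int) -> tuple[int, ...]:
    """g(x) = prod_{j=FCR}^{FCR+parity-1} (x - alpha^j), low-degree first."""
    F = gf(field_bits)
    g = [1]
    for j in range(parity):
        g = F.poly_mul(g, [F.pow_alpha(_FCR + j), 1])
    return tuple(g)


def _check_symbols(symbols: np.ndarray, code: RSCode) -> None:
    if symbols.size and (symbols.min() < 0 or symbols.max() >= (1 << code.field_bits)):
        raise ValueError(f"symbols out of range for GF(2^{code.field_bits})")


def rs_encode(symbols, code: RSCode) -> np.ndarray:
    """Systematically encode ``data_len`` symbols into a ``total_len`` codeword.

    The data symbols appear unchanged as the codeword prefix.
    """
    msg = np.asarray(symbols, dtype=np.int64)
    if msg.shape != (code.data_len,):
        raise ValueError(f"expected {code.data_len} data symbols, got {msg.shape}")
    _check_symbols(msg, code)
    F = code.field
    g = _generator_poly(code.field_bits, code.parity)
    # Synthetic division of msg(x) * x^parity by the monic generator.
    rem = [0] * code.parity
    for s in msg:
        coef = int(s) ^ rem[-1]
        rem = [0] + rem[:-1]
        if coef:
            lc = F.log[coef]
            for i in range(code.parity):
                if g[i]:
                    rem[i] ^= int(F.exp[lc + F.log[g[i]]])
    parity = rem[::-1]  # highest-degree remainder coefficient first
    return np.concatenate([msg, np.array(parity, dtype=np.int64)])


def _syndromes(cw: np.ndarray, code: RSCode) -> list[int]:
    """S_j = c(alpha^(j+FCR)), j = 0..parity-1, for codeword coefficients
    ordered highest-degree (data) first."""
    F = code.field
    n = code.total_len
    out = []
    for j in range(code.parity):
        root = F.pow_alpha(_FCR + j)
        acc = 0
        for c in cw:
            acc = F.mul(acc, root) ^ int(c)
        out.append(acc)
    return out


def rs_syndromes_batch(words: np.ndarray, code: RSCode) -> np.ndarray:
    """Syndromes for many received words at once: (n_words, parity) array.

    A row of zeros means the word is a valid codeword. Used to screen large
    read pools cheaply before running the full decoder on the dirty ones.
    """
    words = np.asarray(words, dtype=np.int64)
    F = code.field
    n = code.total_len
    if words.ndim != 2 or words.shape[1] != n:
        raise ValueError(f"expected (n_words, {n}) array")
    # power matrix: alpha^((n-1-i)*(j+FCR)) for position i, syndrome j
    exps = np.outer(n - 1 - np.arange(n), np.arange(_FCR, _FCR + code.parity))
    powers = F.exp[exps % (F.order - 1)]
    logs = F.log[words]  # (n_words, n); log of 0 is garbage, masked below
    nz = words != 0
    out = np.zeros((words.shape[0], code.parity), dtype=np.int64)
    for j in range(code.parity):
        terms = F.exp[(logs + F.log[powers[:, j]]) % (F.order - 1)]
        terms = np.where(nz, terms, 0)
        acc = np.zeros(words.shape[0], dtype=np.int64)
        for i in range(n):
            acc ^= terms[:, i]
        out[:, j] = acc
    return out


def _berlekamp_massey(synd: list[int], F: GF) -> list[int]:
    """Error locator polynomial (lowest degree first) from a syndrome sequence."""
    lam = [1]
    prev = [1]
    L = 0
    m = 1
    b = 1
    for n, s in enumerate(synd):
        d = s
        for i in range(1, L + 1):
            if i < len(lam) and lam[i]:
                d ^= F.mul(lam[i], synd[n - i])
        if d == 0:
            m += 1
            continue
        coef = F.div(d, b)
        shifted = [0] * m + [F.mul(coef, c) for c in prev]
        new = [a ^ b2 for a, b2 in
               zip(lam + [0] * (len(shifted) - len(lam)),
                   shifted + [0] * (len(lam) - len(shifted)))]
        if 2 * L <= n:
            prev = lam
            b = d
            L = n + 1 - L
            m = 1
        else:
            m += 1
        lam = new
    # strip trailing zeros
    while len(lam) > 1 and lam[-1] == 0:
        lam.pop()
    if len(lam) - 1 != L:
        raise RSDecodeFailure("inconsistent error locator degree")
    return lam


def rs_decode(symbols, code: RSCode, erasures=()) -> np.ndarray:
    """Correct a received word; return its ``data_len`` data symbols.

    ``erasures`` are known-bad positions (0-based indices into the word).
    Raises :class:`RSDecodeFailure` when 2*errors + erasures exceeds parity or
    the corrected word fails re-verification.
    """
    word = np.array(symbols, dtype=np.int64).copy()
    if word.shape != (code.total_len,):
        raise ValueError(f"expected {code.total_len} symbols, got {word.shape}")
    _check_symbols(word, code)
    F = code.field
    n = code.total_len
    p = code.parity
    erasures = sorted(set(int(e) for e in erasures))
    if any(e < 0 or e >= n for e in erasures):
        raise ValueError("erasure position out of range")
    if len(erasures) > p:
        raise RSDecodeFailure(f"{len(erasures)} erasures exceed parity {p}")
    # Zero-fill erased positions so their content cannot mislead the syndromes.
    for e in erasures:
        word[e] = 0

    synd = _syndromes(word, code)
    if not any(synd):
        return word[: code.data_len]

    # Location value of position i is X_i = alpha^(n-1-i).
    Xs_era = [F.pow_alpha(n - 1 - e) for e in erasures]
    gamma = [1]
    for X in Xs_era:
        gamma = F.poly_mul(gamma, [1, X])  # (1 + X x)
    # Forney syndromes: T = (S(x) * Gamma(x) mod x^p) shifted by s.
    t_full = F.poly_mul(synd, gamma)[:p]
    t = t_full[len(erasures):]

    if t and any(t):
        lam = _berlekamp_massey(t, F)
    else:
        lam = [1]
    n_err = len(lam) - 1
    if 2 * n_err + len(erasures) > p:
        raise RSDecodeFailure("error count exceeds correction capacity")

    # Chien search for error positions.
    err_pos = []
    if n_err:
        for i in range(n):
            Xinv = F.pow_alpha(-(n - 1 - i))
            if F.poly_eval(lam, Xinv) == 0:
                err_pos.append(i)
        if len(err_pos) != n_err:
            raise RSDecodeFailure("error locator has wrong number of roots")

    positions = sorted(set(erasures) | set(err_pos))
    psi = [1]
    Xs = []
    for pos in positions:
        X = F.pow_alpha(n - 1 - pos)
        Xs.append(X)
        psi = F.poly_mul(psi, [1, X])
    omega = F.poly_mul(synd, psi)[:p]
    # Formal derivative of psi: odd-degree terms only.
    dpsi = [psi[i] for i in range(1, len(psi), 2)]

    for pos, X in zip(positions, Xs):
        Xinv = F.inv(X)
        denom = F.poly_eval(dpsi, F.mul(Xinv, Xinv))  # psi'(Xinv)
        if denom == 0:
            raise RSDecodeFailure("Forney denominator vanished")
        num = F.poly_eval(omega, Xinv)
        mag = F.div(num, denom)  # FCR = 1: no extra X power needed
        word[pos] ^= mag

    if any(_syndromes(word, code)):
        raise RSDecodeFailure("correction failed re-verification")
    return word[: code.data_len]


# ---------------------------------------------------------------------------
# Barcode code: 12 nt <-> 6 GF(2^4) symbols, RS(6,8), 16 nt on the molecule.
# ---------------------------------------------------------------------------

BARCODE_CODE = RSCode(field_bits=4, data_len=6, total_len=8)

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_BASE = "ACGT"


def _dna_to_symbols(seq: str) -> list[int]:
    """Two bases per GF(2^4) symbol; first base holds the high bits."""
    if len(seq) % 2:
        raise ValueError("DNA length must be even for dinucleotide symbols")
    try:
        return [(_BASE_BITS[seq[i]] << 2) | _BASE_BITS[seq[i + 1]]
                for i in range(0, len(seq), 2)]
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in {seq!r}") from None


def _symbols_to_dna(symbols) -> str:
    return "".join(_BITS_BASE[(int(s) >> 2) & 3] + _BITS_BASE[int(s) & 3]
                   for s in symbols)


def encode_barcode(barcode: str) -> str:
    """Encode a 12 nt barcode into its 16 nt RS(6,8)-protected form."""
    if len(barcode) != 12:
        raise ValueError("barcode must be exactly 12 nt")
    return _symbols_to_dna(rs_encode(_dna_to_symbols(barcode), BARCODE_CODE))


def decode_barcode(coded: str) -> tuple[str, bool]:
    """Decode a 16 nt read prefix back to the 12 nt barcode.

    Returns ``(barcode, corrected)``; raises :class:`RSDecodeFailure` for
    undecodable prefixes (the caller routes such reads to "No BC").
    """
    if len(coded) != 16:
        raise ValueError("coded barcode must be exactly 16 nt")
    received = _dna_to_symbols(coded)
    data = rs_decode(received, BARCODE_CODE)
    corrected = list(rs_encode(data, BARCODE_CODE)) != received
    return _symbols_to_dna(data), bool(corrected)


# ---------------------------------------------------------------------------
# Outer block code over sequence rows.
# ---------------------------------------------------------------------------

def encode_block(rows: np.ndarray, code: RSCode) -> np.ndarray:
    """Column-wise RS over a (data_len, L) matrix of letter values.

    Returns the full (total_len, L) block; the appended parity rows carry the
    column parities and (by linearity) are valid inner codewords whenever the
    data rows are.
    """
    rows = np.asarray(rows, dtype=np.int64)
    if rows.ndim != 2 or rows.shape[0] != code.data_len:
        raise ValueError(f"expected {code.data_len} rows, got {rows.shape}")
    out = np.zeros((code.total_len, rows.shape[1]), dtype=np.int64)
    for j in range(rows.shape[1]):
        out[:, j] = rs_encode(rows[:, j], code)
    return out


def decode_block(rows: np.ndarray, code: RSCode, row_erasures=(),
                 symbol_erasures: np.ndarray | None = None) -> np.ndarray:
    """Column-wise RS decode of a (total_len, L) block.

    ``row_erasures`` flags whole missing/failed rows; ``symbol_erasures`` is an
    optional boolean (total_len, L) mask of individually unresolved letters.
    Returns the corrected (data_len, L) data rows.
    """
    rows = np.asarray(rows, dtype=np.int64)
    if rows.ndim != 2 or rows.shape[0] != code.total_len:
        raise ValueError(f"expected {code.total_len} rows, got {rows.shape}")
    row_erasures = sorted(set(int(e) for e in row_erasures))
    out = np.zeros((code.data_len, rows.shape[1]), dtype=np.int64)
    for j in range(rows.shape[1]):
        era = set(row_erasures)
        if symbol_erasures is not None:
            era |= set(np.flatnonzero(symbol_erasures[:, j]).tolist())
        try:
            out[:, j] = rs_decode(rows[:, j], code, erasures=sorted(era))
        except RSDecodeFailure as exc:
            raise RSDecodeFailure(f"outer decode failed on column {j}: {exc}") from exc
    return out
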