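"""Arithmetic over GF(2^m) via exp/log tables.

Supports the field sizes used by the storage codes (m = 4 for barcodes,
m = 9/12/13 for combinatorial letter payloads). Tables are built once per
field order and cached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# Primitive polynomials (including the x^m term) for the field orders we use.
PRIMITIVE_POLY = {
    4: 0x13,      # x^4 + x + 1
    8: 0x11D,     # x^8 + x^4 + x^3 + x^2 + 1
    9: 0x211,     # x^9 + x^4 + 1
    12: 0x1053,   # x^12 + x^6 + x^4 + x + 1
    13: 0x201B,   # x^13 + x^4 + x^3 + x + 1
}


class GF:
    """The finite field GF(2^m) with generator alpha = x (the class is cached;
    use :func:`gf` rather than constructing directly)."""

    def __init__(self, m: int, primitive_poly: int | None = None):
        if primitive_poly is None:
            try:
                primitive_poly = PRIMITIVE_POLY[m]
            except KeyError:
                raise ValueError(f"no default primitive polynomial for GF(2^{m})")
        self.m = m
        self.poly = primitive_poly
        self.order = 1 << m
        n = self.order - 1
        exp = np.zeros(2 * n, dtype=np.int64)
        log = np.zeros(self.order, dtype=np.int64)
        x = 1
        for i in range(n):
            exp[i] = x
            log[x] = i
            x <<= 1
            if x & self.order:
                x ^= primitive_poly
        if x != 1:  # polynomial not primitive: alpha's order < 2^m - 1
            raise ValueError(f"0x{primitive_poly:x} is not primitive for GF(2^{m})")
        exp[n:] = exp[:n]  # doubled table: mul without modular reduction of logs
        self.exp = exp
        self.log = log

    # -- scalar ops -------------------------------------------------------
    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return int(self.exp[self.log[a] + self.log[b]])

    def div(self, a: int, b: int) -> int:
        if b == 0:
            raise ZeroDivisionError("division by zero in GF(2^m)")
        if a == 0:
            return 0
        return int(self.exp[self.log[a] - self.log[b] + (self.order - 1)])

    def inv(self, a: int) -> int:
        if a == 0:
            raise ZeroDivisionError("zero has no inverse")
        return int(self.exp[(self.order - 1) - self.log[a]])

    def pow_alpha(self, e: int) -> int:
        """alpha**e for any integer e (reduced mod 2^m - 1)."""
        return int(self.exp[e % (self.order - 1)])

    # -- vector ops -------------------------------------------------------
    def mul_vec(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        out = self.exp[self.log[a] + self.log[b]]
        return np.where((a == 0) | (b == 0), 0, out)

    def scale_vec(self, a: np.ndarray, s: int) -> np.ndarray:
        if s == 0:
            return np.zeros_like(np.asarray(a, dtype=np.int64))
        a = np.asarray(a, dtype=np.int64)
        out = self.exp[self.log[a] + self.log[s]]
        return np.where(a == 0, 0, out)

    # -- polynomial ops (coefficient lists, lowest degree first) ----------
    def poly_mul(self, p: list[int], q: list[int]) -> list[int]:
        out = [0] * (len(p) + len(q) - 1)
        for i, a in enumerate(p):
            if a == 0:
                continue
            la = self.log[a]
            for j, b in enumerate(q):
                if b:
                    out[i + j] ^= int(self.exp[la + self.log[b]])
        return out

    def poly_eval(self, p: list[int], x: int) -> int:
        """Evaluate sum p[i] * x^i (Horner from the top coefficient)."""
        acc = 0
        for c in reversed(p):
            acc = self.mul(acc, x) ^ c
        return acc

    def __repr__(self) -> str:  # pragma: no cover
        return f"GF(2^{self.m}, poly=0x{self.poly:x})"


@lru_cache(maxsize=None)
def gf(m: int, primitive_poly: int | None = None) -> GF:
    return GF(m, primitive_poly)
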