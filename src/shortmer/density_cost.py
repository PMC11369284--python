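"""Logical-density accounting and the synthesis-vs-sequencing cost model.

Logical density is measured in message bits per synthesis cycle. One
combinatorial cycle appends one k-mer (whatever k is), one standard-DNA cycle
appends one nucleotide, so a full sequence costs
``coded_barcode_nt + coded_payload_letters`` cycles (16 + 134 = 150 with the
default codes) in every scheme. All densities here use 1 GB = 8e9 bits.

The cost model compares schemes on storing 1 GB: synthesis cost is the total
number of cycles; sequencing cost is the total number of reads, i.e. the
per-sequence depth (from an exact coupon-collector tail) times the number of
synthesized sequences. Totals are mixed with a synthesis:sequencing cost
ratio and normalized to the standard-DNA scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, comb

import pandas as pd

from .alphabet import bits_per_letter as _alphabet_bits

__all__ = [
    "DensityReport",
    "density_report",
    "table_of_densities",
    "coupon_failure_prob",
    "sequencing_depth",
    "cost_curves",
    "COMPARISON_SCHEMES",
]

GB_BITS = 8 * 10 ** 9

# (N, K) binomial schemes compared in the cost analysis; None = standard DNA.
COMPARISON_SCHEMES: list[tuple[int, int] | None] = [
    None, (8, 4), (16, 3), (16, 5), (16, 7), (32, 10), (32, 16), (64, 32), (96, 32),
]


@dataclass(frozen=True)
class DensityReport:
    """One logical-density table row."""

    scheme: str
    N: int | None
    K: int | None
    bits_per_letter: int
    alphabet_size: int            # addressable: 2^bits_per_letter
    bits_per_sequence: int
    n_sequences: int
    n_sequences_with_rs: int
    synthesis_cycles: int
    bits_per_cycle_payload_only: float
    bits_per_cycle: float
    fold_increase: float


def _scheme_bits(N: int | None, K: int | None) -> tuple[str, int]:
    if N is None:
        return "standard", 2  # one nucleotide per cycle, 2 bits
    return f"binomial({N},{K})", _alphabet_bits("binomial", N, K)


def density_report(N: int | None = None, K: int | None = None,
                   message_bits: int = GB_BITS,
                   payload_len: int = 120, coded_payload_len: int = 134,
                   block_size: int = 42, coded_block_size: int = 48,
                   barcode_cycles: int = 16) -> DensityReport:
    """Density accounting for one scheme; ``N=None`` is standard DNA.

    ``barcode_cycles + coded_payload_len`` is the per-sequence cycle cost
    (150 with defaults, for every scheme).
    """
    if message_bits <= 0:
        raise ValueError("message_bits must be positive")
    scheme, bits = _scheme_bits(N, K)
    bits_per_seq = bits * payload_len
    n_seq = ceil(message_bits / bits_per_seq)
    n_blocks = ceil(n_seq / block_size)
    n_seq_rs = n_blocks * coded_block_size
    cycles_per_seq = barcode_cycles + coded_payload_len
    cycles = n_seq_rs * cycles_per_seq
    bpc = message_bits / cycles
    bpc_payload = message_bits / (n_seq_rs * coded_payload_len)

    std_cycles = (ceil(message_bits / (2 * payload_len)) + block_size - 1
                  ) // block_size * coded_block_size * cycles_per_seq
    fold = bpc / (message_bits / std_cycles)

    return DensityReport(
        scheme=scheme, N=N, K=K,
        bits_per_letter=bits,
        alphabet_size=1 << bits,
        bits_per_sequence=bits_per_seq,
        n_sequences=n_seq,
        n_sequences_with_rs=n_seq_rs,
        synthesis_cycles=cycles,
        bits_per_cycle_payload_only=bpc_payload,
        bits_per_cycle=bpc,
        fold_increase=fold,
    )


def table_of_densities(schemes=( None, (16, 3), (16, 5), (16, 7) ),
                       **kwargs) -> pd.DataFrame:
    """Density table for several schemes (default: the four headline rows)."""
    rows = []
    for sch in schemes:
        rep = density_report(*(sch or (None, None)), **kwargs)
        rows.append(rep.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequencing depth: exact coupon-collector tail
# ---------------------------------------------------------------------------

def coupon_failure_prob(R: int, K: int) -> float:
    """P(some of K uniform coupons unseen after R draws), by inclusion-exclusion:
    sum_{i=1}^{K-1} (-1)^(i+1) C(K,i) ((K-i)/K)^R."""
    if R < 0 or K < 1:
        raise ValueError("need R >= 0 and K >= 1")
    if K == 1:
        return 0.0 if R >= 1 else 1.0
    return sum((-1) ** (i + 1) * comb(K, i) * ((K - i) / K) ** R
               for i in range(1, K))


def sequencing_depth(K: int, l: int, target_error: float = 1e-4) -> int:
    """Smallest per-sequence read count R with l * P_fail(R; K) <= target_error."""
    if not 0 < target_error < 1:
        raise ValueError("target_error must be in (0, 1)")
    R = max(1, K)
    while l * coupon_failure_prob(R, K) > target_error:
        R += 1
    return R


# ---------------------------------------------------------------------------
# cost curves
# ---------------------------------------------------------------------------

def cost_curves(schemes=tuple(COMPARISON_SCHEMES),
                ratios=(500, 1000, 2000),
                target_error: float = 1e-4,
                **density_kwargs) -> pd.DataFrame:
    """Synthesis/sequencing/total cost per scheme, totals normalized to the
    standard scheme at each synthesis:sequencing cost ratio."""
    rows = []
    for sch in schemes:
        N, K = sch if sch is not None else (None, None)
        rep = density_report(N, K, **density_kwargs)
        depth = sequencing_depth(K if K is not None else 1,
                                 density_kwargs.get("coded_payload_len", 134),
                                 target_error)
        reads = depth * rep.n_sequences_with_rs
        rows.append({
            "scheme": rep.scheme,
            "bits_per_letter": rep.bits_per_letter,
            "synthesis_cost": rep.synthesis_cycles,
            "sequencing_depth": depth,
            "sequencing_cost": reads,
        })
    df = pd.DataFrame(rows)
    std = df[df.scheme == "standard"]
    if std.empty:
        raise ValueError("scheme list must include the standard scheme for normalization")
    for ratio in ratios:
        total = ratio * df.synthesis_cost + df.sequencing_cost
        std_total = ratio * std.synthesis_cost.iloc[0] + std.sequencing_cost.iloc[0]
        df[f"normalized_total_{ratio}:1"] = total / std_total
    return df
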