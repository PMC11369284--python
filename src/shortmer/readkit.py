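"""Analysis pipeline for assembly-based combinatorial reads.

Models a proof-of-concept experiment in which combinatorial synthesis is
imitated by assembling 20 bp fragments: each 220 bp read tiles eleven 20 bp
segments -- a 5' anchor, a barcode, then four (universal, payload) segment
pairs, and a 3' anchor. Payload segments are drawn from 16 candidate
fragments with large pairwise Hamming distance; each sequence's letter at a
cycle is a K-subset of the candidates.

The pipeline: keep reads of exactly the designed length; assign every segment
to its nearest candidate, discarding reads with any segment beyond a Hamming
threshold (default 3); count candidate occurrences per barcode and cycle; and
call each cycle's letter as the K most common candidates seen at least t
times. ``subsample_study`` resamples the pool to measure how many reads
letter- and sequence-level reconstruction need as a function of t.

The design generator also emulates the cross-contamination ("leakage")
between co-assembled sequences that makes multiplicities t > 1 useful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconstruct import infer_letter
from .simulator import ReadPool, apply_sequencing_errors

__all__ = [
    "ExperimentDesign",
    "MatchedPool",
    "SubsampleStats",
    "generate_experiment_design",
    "simulate_experiment_reads",
    "filter_by_length",
    "match_segments",
    "match_pool",
    "reconstruct_experiment",
    "subsample_study",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ExperimentDesign:
    """Geometry and content of one assembly experiment.

    Reads tile: anchor5 | barcode | (universal_i | payload_i) * n_cycles |
    anchor3, each segment ``seg_len`` bp.
    """

    candidates: tuple[str, ...]                 # payload fragments (e.g. 16)
    barcodes: tuple[str, ...]                   # one per sequence
    universals: tuple[str, ...]                 # one per cycle
    anchors: tuple[str, str]
    members: tuple[tuple[tuple[int, ...], ...], ...]  # [seq][cycle] -> K indices
    seg_len: int = 20

    @property
    def n_sequences(self) -> int:
        return len(self.barcodes)

    @property
    def n_cycles(self) -> int:
        return len(self.universals)

    @property
    def K(self) -> int:
        return len(self.members[0][0])

    @property
    def read_len(self) -> int:
        return self.seg_len * (3 + 2 * self.n_cycles)

    def segment_offsets(self) -> dict[str, int]:
        s = self.seg_len
        off = {"anchor5": 0, "barcode": s}
        for c in range(self.n_cycles):
            off[f"universal{c}"] = s * (2 + 2 * c)
            off[f"payload{c}"] = s * (3 + 2 * c)
        off["anchor3"] = s * (2 + 2 * self.n_cycles)
        return off

    def expected_read(self, seq_idx: int, choice: list[int]) -> str:
        parts = [self.anchors[0], self.barcodes[seq_idx]]
        for c in range(self.n_cycles):
            parts.append(self.universals[c])
            parts.append(self.candidates[choice[c]])
        parts.append(self.anchors[1])
        return "".join(parts)


def _random_fragments(rng, n: int, length: int, min_distance: int,
                      against: list[str] | None = None) -> list[str]:
    out: list[str] = []
    pool = list(against or [])
    tries = 0
    while len(out) < n:
        cand = "".join(_BASES[b] for b in rng.integers(0, 4, length))
        if all(sum(x != y for x, y in zip(cand, o)) >= min_distance
               for o in pool):
            out.append(cand)
            pool.append(cand)
        tries += 1
        if tries > 10000 * n:
            raise ValueError("could not generate fragments at the requested distance")
    return out


def generate_experiment_design(seed: int = 0, n_sequences: int = 2,
                               n_cycles: int = 4, n_candidates: int = 16,
                               K: int = 5, seg_len: int = 20,
                               min_distance: int = 8) -> ExperimentDesign:
    """A synthetic stand-in design with the experiment's geometry (220 bp
    reads, 20 bp segments, 16 well-separated candidates, K=5 members per
    cycle; member sets of different sequences may partially overlap)."""
    rng = np.random.default_rng(seed)
    candidates = _random_fragments(rng, n_candidates, seg_len, min_distance)
    rest = _random_fragments(rng, n_sequences + n_cycles + 2, seg_len,
                             min_distance, against=candidates)
    barcodes = rest[:n_sequences]
    universals = rest[n_sequences:n_sequences + n_cycles]
    anchors = (rest[-2], rest[-1])
    members = tuple(
        tuple(tuple(sorted(rng.choice(n_candidates, size=K, replace=False).tolist()))
              for _ in range(n_cycles))
        for _ in range(n_sequences))
    return ExperimentDesign(tuple(candidates), tuple(barcodes),
                            tuple(universals), anchors, members, seg_len)


def simulate_experiment_reads(design: ExperimentDesign, n_reads: int,
                              p_sub: float = 0.0, p_leak: float = 0.0,
                              seed: int = 0) -> ReadPool:
    """Simulated sequencing of the assembled pool.

    Each read picks a source sequence uniformly; each cycle draws a member
    fragment uniformly, except with probability ``p_leak`` it leaks a member
    of another sequence (cross-contamination between co-assembled products).
    Base substitutions are applied at rate ``p_sub``.
    """
    rng = np.random.default_rng(seed)
    src = rng.integers(0, design.n_sequences, size=n_reads)
    reads = []
    for i in range(n_reads):
        s = int(src[i])
        choice = []
        for c in range(design.n_cycles):
            if design.n_sequences > 1 and rng.random() < p_leak:
                other = int(rng.integers(0, design.n_sequences - 1))
                other += other >= s
                mem = design.members[other][c]
            else:
                mem = design.members[s][c]
            choice.append(int(mem[rng.integers(0, len(mem))]))
        reads.append(design.expected_read(s, choice))
    pool = ReadPool(reads, src)
    if p_sub > 0:
        pool = apply_sequencing_errors(pool, p_sub, seed=seed + 1)
    return pool


# ---------------------------------------------------------------------------
# filtering and matching
# ---------------------------------------------------------------------------

def filter_by_length(reads: list[str], expected_len: int) -> list[str]:
    """Keep exactly the reads of the designed length."""
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    return [r for r in reads if len(r) == expected_len]


@dataclass
class MatchedPool:
    """Per-read segment assignments for a filtered pool.

    ``barcode`` is -1 when the barcode segment is unattributable; ``payload``
    holds -1 for unmappable segments; ``usable`` flags reads with every
    segment within the Hamming threshold.
    """

    barcode: np.ndarray      # (n,)
    payload: np.ndarray      # (n, n_cycles)
    distance: np.ndarray     # (n, n_cycles) payload distances
    usable: np.ndarray       # (n,)


def _segment_codes(reads: list[str], offset: int, seg_len: int) -> np.ndarray:
    buf = np.frombuffer("".join(reads).encode(), dtype=np.uint8)
    buf = buf.reshape(len(reads), -1)[:, offset:offset + seg_len]
    return buf


def _nearest(seg_bytes: np.ndarray, candidates: tuple[str, ...]
             ) -> tuple[np.ndarray, np.ndarray]:
    cand = np.frombuffer("".join(candidates).encode(), dtype=np.uint8)
    cand = cand.reshape(len(candidates), -1)
    dists = (seg_bytes[:, None, :] != cand[None, :, :]).sum(axis=2)
    return dists.argmin(axis=1), dists.min(axis=1)


def match_pool(reads: list[str], design: ExperimentDesign,
               max_hamming: int = 3) -> MatchedPool:
    """Vectorized segment matching of an already length-filtered pool."""
    n = len(reads)
    off = design.segment_offsets()
    s = design.seg_len
    if n == 0:
        z = np.zeros((0,), dtype=np.int64)
        return MatchedPool(z, z.reshape(0, design.n_cycles) if design.n_cycles else z,
                           z.reshape(0, design.n_cycles), np.zeros(0, dtype=bool))
    ok = np.ones(n, dtype=bool)

    for name, cands in (("anchor5", (design.anchors[0],)),
                        ("anchor3", (design.anchors[1],))):
        _, d = _nearest(_segment_codes(reads, off[name], s), cands)
        ok &= d <= max_hamming
    bc_idx, bc_d = _nearest(_segment_codes(reads, off["barcode"], s), design.barcodes)
    bc = np.where(bc_d <= max_hamming, bc_idx, -1)
    ok &= bc >= 0

    payload = np.zeros((n, design.n_cycles), dtype=np.int64)
    pdist = np.zeros((n, design.n_cycles), dtype=np.int64)
    for c in range(design.n_cycles):
        _, d = _nearest(_segment_codes(reads, off[f"universal{c}"], s),
                        (design.universals[c],))
        ok &= d <= max_hamming
        idx, d = _nearest(_segment_codes(reads, off[f"payload{c}"], s),
                          design.candidates)
        payload[:, c] = np.where(d <= max_hamming, idx, -1)
        pdist[:, c] = d
        ok &= payload[:, c] >= 0
    return MatchedPool(bc, payload, pdist, ok)


def match_segments(read: str, design: ExperimentDesign,
                   max_hamming: int = 3) -> dict | None:
    """Segment assignment of a single read, or None when discarded."""
    if len(read) != design.read_len:
        return None
    mp = match_pool([read], design, max_hamming)
    if not mp.usable[0]:
        return None
    return {
        "barcode": int(mp.barcode[0]),
        "payload": tuple(int(x) for x in mp.payload[0]),
        "payload_distances": tuple(int(x) for x in mp.distance[0]),
    }


# ---------------------------------------------------------------------------
# reconstruction and subsampling
# ---------------------------------------------------------------------------

def reconstruct_experiment(reads: list[str], design: ExperimentDesign,
                           K: int | None = None, t: int = 1,
                           max_hamming: int = 3):
    """Count candidates per (barcode, cycle) and call the letters.

    Returns ``(counts, inferred, matches)``: counts is a
    (n_sequences, n_cycles, n_candidates) heatmap array, ``inferred`` the
    member sets (None when unresolved), ``matches`` booleans vs the design.
    """
    K = K or design.K
    mp = match_pool(reads, design, max_hamming)
    counts = np.zeros((design.n_sequences, design.n_cycles,
                       len(design.candidates)), dtype=np.int64)
    use = mp.usable
    for c in range(design.n_cycles):
        np.add.at(counts, (mp.barcode[use], c, mp.payload[use, c]), 1)
    inferred = []
    matches = []
    for s in range(design.n_sequences):
        row_inf, row_match = [], []
        for c in range(design.n_cycles):
            members, _ = infer_letter(counts[s, c], K, t)
            row_inf.append(members)
            row_match.append(members == tuple(sorted(design.members[s][c])))
        inferred.append(tuple(row_inf))
        matches.append(tuple(row_match))
    return counts, tuple(inferred), tuple(matches)


@dataclass
class SubsampleStats:
    """Resampling summary; one row per t in ``table``."""

    table: pd.DataFrame
    n_resamples: int


def subsample_study(reads: list[str], design: ExperimentDesign,
                    K: int | None = None, t_values=(1, 2, 3, 4),
                    n_resamples: int = 500, seed: int = 0,
                    barcode: int = 0, letter_cycle: int = -1,
                    max_hamming: int = 3) -> SubsampleStats:
    """Reads-to-reconstruction statistics under random read ordering.

    For each resample the (pre-matched) pool is reshuffled and reads of the
    target barcode are consumed one by one until K distinct candidates have
    been seen >= t times -- at one cycle (``letter_cycle``, the last by
    default) for the letter-level statistic and at every cycle for the
    sequence-level one. Unmappable reads of the target barcode count as
    analyzed-but-skipped; reads whose barcode cannot be attributed are
    ignored. A reconstruction fails when the called member set differs from
    the design (or the pool runs out).
    """
    K = K or design.K
    mp = match_pool(reads, design, max_hamming)
    mine = np.flatnonzero(mp.barcode == barcode)
    if mine.size == 0:
        raise ValueError("no reads attributable to the target barcode")
    cyc = letter_cycle % design.n_cycles
    truth = [set(design.members[barcode][c]) for c in range(design.n_cycles)]
    n_cand = len(design.candidates)
    rng = np.random.default_rng(seed)
    rows = []
    for t in t_values:
        stats = {"letter": [], "sequence": []}
        for _ in range(n_resamples):
            order = mine[rng.permutation(mine.size)]
            counts = np.zeros((design.n_cycles, n_cand), dtype=np.int64)
            done_cycles = np.zeros(design.n_cycles, dtype=bool)
            analyzed = skipped = nonzero = 0
            letter_rec = None
            seq_rec = None
            for ridx in order:
                analyzed += 1
                if not mp.usable[ridx]:
                    skipped += 1
                else:
                    if (mp.distance[ridx] > 0).any():
                        nonzero += 1
                    for c in range(design.n_cycles):
                        counts[c, mp.payload[ridx, c]] += 1
                        if not done_cycles[c]:
                            done_cycles[c] = (counts[c] >= t).sum() >= K
                if letter_rec is None and done_cycles[cyc]:
                    members, _ = infer_letter(counts[cyc], K, t)
                    letter_rec = (analyzed, skipped, nonzero,
                                  set(members) != truth[cyc])
                if seq_rec is None and done_cycles.all():
                    fail = False
                    for c in range(design.n_cycles):
                        members, _ = infer_letter(counts[c], K, t)
                        fail = fail or set(members) != truth[c]
                    seq_rec = (analyzed, skipped, nonzero, fail)
                    break
            if letter_rec is None:
                letter_rec = (analyzed, skipped, nonzero, True)
            if seq_rec is None:
                seq_rec = (analyzed, skipped, nonzero, True)
            stats["letter"].append(letter_rec)
            stats["sequence"].append(seq_rec)
        for scope in ("letter", "sequence"):
            arr = np.array(stats[scope], dtype=float)
            rows.append({
                "t": t, "scope": scope,
                "mean_reads": arr[:, 0].mean(),
                "mean_skipped": arr[:, 1].mean(),
                "mean_nonzero_hamming": arr[:, 2].mean(),
                "failure_rate": arr[:, 3].mean(),
            })
    return SubsampleStats(pd.DataFrame(rows), n_resamples)
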