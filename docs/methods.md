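# Methods

## Model

A stored message is a bit string. The codec maps it to rows of a letter
matrix: bits are zero-padded to a multiple of r = ⌊log₂|Σ|⌋, split into r-bit
words, and each word becomes a letter value. Letter values map to K-subsets of
the building-block set Ω through the combinatorial number system in
colexicographic order — value 0 is {X₁…X_K}, and rank/unrank run in O(K)
without lookup tables. Only the first 2^r subsets are addressable; the
remaining C(N,K) − 2^r subsets are reserved and treated as invalid (an
erasure) if they ever appear on decode.

The default Ω is the greedy (k = 3, N = 16, d = 2) set: walk the 64 trimers in
lexicographic order and accept each one at Hamming distance ≥ 2 from all
accepted so far. The greedy walk reaches exactly 16, which is the maximum for
d = 2 (Singleton bound 4^{k−d+1}). Construction filters (GC window, maximum
homopolymer run) are available but off by default; any filtering shrinks the
achievable N and hence the density.

### Padding and layout

Payloads hold l = 120 letters. The last partial payload is filled with letter
value 0; whole zero sequences are added until the sequence count is B − 1
(mod B), and a final *padding-info* sequence — the total number of padding
bits, written big-endian across its l letters — completes the block. The
padding-info content is therefore self-describing on decode:
message_bits = (rows − 1)·l·r − padding. A worked instance: an 824-bit message
at r = 9, l = 12, B = 10 pads 4 bits + 4 letters + 12 letters = 148 bits.

### Error correction

Three systematic Reed–Solomon codes (all named data,total):

| code | field | protects | capacity |
|---|---|---|---|
| RS(6,8) | GF(2⁴) | 12 nt barcode → 16 nt (2 nt/symbol) | 1 symbol error |
| RS(120,134) | GF(2^r) | each payload row | 2e + s ≤ 14 |
| RS(42,48) | GF(2^r) | each block, column-wise | 2e + s ≤ 6 |

RS symbols are the letter *values*, so the payload field is GF(2^r): GF(2^12)
for binomial(16,5), GF(2^9) for (16,3), GF(2^13) for (16,7). Field
construction uses fixed primitive polynomials (x⁴+x+1, x⁹+x⁴+1,
x¹²+x⁶+x⁴+x+1, x¹³+x⁴+x³+x+1) and generator roots α¹…α^p; decoding is
Berlekamp–Massey with Forney syndromes for erasure support, Chien search and
the Forney algorithm, followed by a syndrome re-check so that an overloaded
word raises a failure instead of silently returning a non-codeword.

Because the inner and outer codes are linear over the same field, the outer
parity rows of a block of inner codewords are themselves inner codewords. The
decoder uses this: every row (data or parity) is inner-decoded first, with
unresolved letters as erasures; rows that fail (or whose barcode never
appears) become column erasures for the outer decode. Erasure handling is the
default because known-position losses cost half as much parity as errors.

## The channel simulator

The simulator is also the package's synthetic-data generator; its defaults
are the study conditions used throughout the tests.

* **Copy number**: X ~ Normal(μ = 1000, σ = 10) molecules per sequence,
  rounded and clamped at zero. (The sampling stage uses σ = 100; the two
  widths are deliberately different and both configurable.)
* **Member draws**: at each position every molecule takes one member k-mer
  uniformly at random — the source of the coupon-collector behaviour.
* **Indels** are synthesis events at the k-mer level: each synthesized k-mer
  is deleted with probability P_d; before each cycle slot (plus one terminal
  slot, at most one insertion per slot) a uniformly random Ω k-mer is inserted
  with probability P_I. Barcodes are standard synthesis: no k-mer indels (a
  per-base indel option exists, default 0).
* **Substitutions** are sequencing events at the base level: each base is
  replaced with probability P_s by one of the other three bases, uniformly.
* **Mixing/sampling**: a seeded global shuffle, then a draw of
  round(Normal(S·n_sequences, σ = 100)) reads without replacement, clamped to
  the pool.

What the generator does *not* emulate: polymerase- or sequencer-specific
error profiles, quality scores, PCR amplification bias, strand effects, or
length-dependent dropout. Passing tests therefore demonstrate the coding and
inference machinery under idealized iid errors, not performance on any
particular instrument's reads.

## Reconstruction choices

* **Grouping**: barcode prefixes are RS-decoded (a vectorized syndrome screen
  fast-paths clean reads); undecodable or unknown barcodes are "No BC".
  Groups smaller than 10% of the nominal per-sequence sampling rate S are
  discarded; S is the nominal parameter, not the realized group mean.
* **Δ rule**: reads whose length differs from the design by more than k − 1
  are discarded. Surviving reads are sliced at fixed offsets — no alignment;
  a net-zero indel pair inside a read contributes frame-shifted noise that
  the counting threshold and RS absorb.
* **k-mer assignment**: a slice maps to the nearest Ω member if that nearest
  member is unique and within radius max(1, ⌊d/2⌋); otherwise it counts as
  X_dummy. A counting argument shows that in a *maximal* d = 2 trimer set
  every substituted k-mer is at distance 1 from exactly three members
  (16 codewords × 9 neighbours over 48 non-codewords), so substitutions there
  are detected (dummy) rather than mis-assigned — the distance-2 design makes
  substitution errors lossy, never confusable. In sparser sets (e.g. d = 3)
  the radius genuinely corrects single-base substitutions.
* **Letter call**: the K highest-count members with count ≥ t; ties at the
  K-th rank break to the lowest Ω index and set an ambiguity flag (a
  deterministic choice; the flag lets callers treat ties as erasures if they
  prefer). Fewer than K members at threshold ⇒ unresolved ⇒ erasure.
* **Metrics**: normalized
  Levenshtein distance = edit distance / |O| with O the observed sequence
  (a switch selects |E| instead, since the two conventions appear side by
  side in the literature), measured before any RS (stage iv), after the
  payload code (iii) and after the full 2D decode (ii). The edit distance is
  an O(nm) DP over arbitrary integer-symbol sequences (letter values exceed
  one byte, so byte-oriented libraries don't apply; `edlib` serves as the
  oracle in tests).

## Theory module

Exact rational arithmetic for K·Har(K); the Chebyshev chain
Var(R) < (π²/6)K² ⇒ P(|R − K·Har(K)| ≥ cK) ≤ π²/(6c²) ⇒ per-sequence bound
(1 − π²/(6c²))^l ⇒ c = π/√(6(1 − (1−δ)^{1/l})). Read requirements are
reported both as reals and as ceilings; guarantees use the ceiling. The bound
is intentionally loose (simulated success at the budget is far above 1 − δ,
which the tests assert as an inequality). Requirements for t > 1 copies per
member have no closed form here; they are measured empirically by the
simulator and the subsampling study.

## Density and cost accounting

Logical density uses 1 GB = 8×10⁹ bits and 150 cycles per sequence (16
barcode cycles + 134 payload cycles — one combinatorial cycle appends one
k-mer regardless of k, one barcode cycle one nucleotide). Sequences per
message: ⌈bits / (r·120)⌉, padded up to blocks of 42 and multiplied by 48/42
for the outer code. With these conventions standard DNA gives 1.40 bits/cycle
and binomial(16,3)/(16,5)/(16,7) give 6.30/8.40/9.10 — folds 4.5/6.0/6.5.

Sequencing depth per sequence is the smallest R with l·P_fail(R;K) ≤ 10⁻⁴,
using the exact inclusion–exclusion coupon tail
P_fail(R;K) = Σᵢ (−1)^{i+1} C(K,i)((K−i)/K)^R — a reimplementation of the
standard coupon-depth model, pluggable if a different depth rule is wanted.
Synthesis cost is total cycles; sequencing cost is total reads
(depth × sequences); totals mix at C_syn:C_seq ∈ {500, 1000, 2000}:1 and are
normalized to the standard scheme. Whether sequencing is counted in reads or
bases only rescales one axis by a constant; the scheme ordering is unchanged.

## Assembly-experiment analysis (readkit)

The experiment geometry: 220 bp reads of eleven 20 bp segments — anchor,
barcode, and four (universal, payload) pairs, then a closing anchor — with 16
candidate payload fragments at pairwise Hamming distance ≥ 8. The shipped
design is *synthetic*: `generate_experiment_design` draws fragments with the
same geometry and separation, since no reference fragment set ships with the
package. Reads are length-filtered (exactly 220 bp), every segment is matched
to its nearest candidate with a Hamming threshold of 3, and letters are
called as in the main pipeline.

The simulated pool includes a per-cycle *leakage* probability (default 0.01):
a read occasionally carries another sequence's member fragment, emulating the
minor cross-contamination seen between co-assembled products. Leakage is what
makes the multiplicity threshold t informative — without it a wrong candidate
essentially never accumulates reads. The subsampling study reshuffles the
matched pool (without replacement within a resample), consumes reads of the
target barcode until K distinct candidates reach t copies at one cycle
(letter level, default the last cycle) or at all cycles (sequence level), and
records reads analyzed, unmappable reads (skipped, still counted as
analyzed), reads with non-zero Hamming distance, and whether the called set
matches the design. With the default pool the failure rate falls from a few
percent at t = 1 to zero at t ≥ 3 while the read cost grows roughly linearly
in t.

## Problem sizes used by the test suite

Fast unit tests run miniature systems (8-letter payloads, 4-row blocks) that
exercise every code path; the acceptance-grade checks use the full default
geometry: null-channel identity for all three default alphabets at l = 120,
RS(120,134), blocks 42→48, μ = 1000 copies; 30 replicates of 10,000-byte
messages through a 1% insertion channel at 100 reads/sequence; 500 randomized
RS capacity trials per code; 10⁵-trial Monte-Carlo coupon statistics; and a
500-resample t-threshold study on a 10,000-read pool. Randomness always flows
from explicit seeds; identical seeds give identical results.

## Known limitations

* No insertion/deletion-correcting code at the letter level: indels are
  handled by discarding length-shifted reads and absorbing residual noise in
  counts and RS, so very high indel rates waste coverage quickly.
* Fixed-offset slicing means a read with compensating indels contributes
  noise (not errors) — fine at low rates, wasteful at high ones.
* The binary (2^N − 1) scheme is encoded/decoded but the reconstruction
  threshold rule for it is the simple "every member with ≥ t counts" — there
  is no K constraint to lean on, so it is markedly less robust than the
  binomial scheme at equal coverage.
* Barcode assignment is deterministic by row order; random access (primer
  design, selective retrieval) is out of scope.
* Cost figures are unitless ratios, not currency; they inherit the depth
  model's idealizations.
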