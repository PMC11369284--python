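"""Reconstruction: letter inference, slicing rules, grouping, metrics, and
end-to-end identity."""

import edlib
import numpy as np
import pytest

from shortmer.alphabet import CombinatorialAlphabet, build_shortmer_set, default_omega
from shortmer.codec import (
    EncodingParams,
    bits_to_bytes,
    encode_bytes,
    encode_message,
)
from shortmer.reconstruct import (
    ReconstructionParams,
    counts_matrix,
    extract_position_kmers,
    group_reads,
    infer_letter,
    levenshtein,
    normalized_levenshtein,
    reconstruct_message,
)
from shortmer.simulator import (
    ErrorRates,
    ReadPool,
    SamplingParams,
    SynthesisParams,
    apply_sequencing_errors,
    mix_and_sample,
    synthesize,
)
from conftest import random_bits


# -- letter inference ---------------------------------------------------------

def test_infer_letter_takes_top_k():
    counts = [9, 7, 5, 3, 2] + [0] * 11
    members, ambiguous = infer_letter(counts, K=5, t=1)
    assert members == (0, 1, 2, 3, 4)
    assert not ambiguous


def test_infer_letter_threshold_semantics():
    counts = [9, 7, 5, 3, 1, 1] + [0] * 10
    members, _ = infer_letter(counts, K=5, t=2)
    assert members is None  # only four k-mers reach two copies
    members, ambiguous = infer_letter(counts, K=5, t=1)
    assert members == (0, 1, 2, 3, 4)
    assert ambiguous  # the fifth rank is tied between indices 4 and 5


def test_infer_letter_matches_brute_force(rng):
    """Exhaustive check against a direct top-K-with-threshold selection."""
    for _ in range(2000):
        counts = rng.integers(0, 6, 16)
        t = int(rng.integers(1, 4))
        members, _ = infer_letter(counts, K=5, t=t)
        order = sorted(range(16), key=lambda i: (-counts[i], i))[:5]
        expected = tuple(sorted(order)) if all(counts[i] >= t for i in order) else None
        assert members == expected


# -- slicing and assignment ----------------------------------------------------

@pytest.fixture(scope="module")
def mini_params():
    alphabet = CombinatorialAlphabet.binomial(default_omega(), 5)
    return EncodingParams(alphabet=alphabet, payload_len=4,
                          rs_payload=None, rs_block=None)


def _designed_read(seq, alphabet, which=0):
    omega = alphabet.omega
    return seq.barcode + "".join(omega.kmers[m[which]]
                                 for m in seq.member_matrix(alphabet))


def test_exact_read_maps_at_distance_zero(mini_params, rng):
    seqs, _ = encode_message(random_bits(rng, 48), mini_params)
    seq = seqs[0]
    read = _designed_read(seq, mini_params.alphabet)
    assign = extract_position_kmers(read, mini_params)
    expected = [m[0] for m in seq.member_matrix(mini_params.alphabet)]
    assert assign == expected


def test_substituted_kmer_in_dense_d2_set_becomes_dummy(mini_params, rng):
    """In a maximal d=2 trimer set a substituted k-mer ties between several
    members, so it is counted as X_dummy rather than mis-assigned."""
    omega = mini_params.alphabet.omega
    seqs, _ = encode_message(random_bits(rng, 48), mini_params)
    seq = seqs[0]
    read = _designed_read(seq, mini_params.alphabet)
    bc_len = mini_params.coded_barcode_len
    original = read[bc_len]
    sub = "C" if original != "C" else "G"
    corrupted = read[:bc_len] + sub + read[bc_len + 1:]
    assign = extract_position_kmers(corrupted, mini_params)
    assert assign[0] is None
    # and it never lands on a *wrong* member: the tie is detected
    assert assign[1:] == [m[0] for m in seq.member_matrix(mini_params.alphabet)][1:]


def test_substitution_corrected_in_sparse_d3_set():
    """With a d=3 set the nearest member within radius 1 is unique, so a
    single-base substitution maps back to the intended member."""
    omega3 = build_shortmer_set(3, 4, 3)  # AAA, CCC-like spread
    alphabet = CombinatorialAlphabet.binomial(omega3, 1)
    params = EncodingParams(alphabet=alphabet, payload_len=2,
                            rs_payload=None, rs_block=None)
    seqs, _ = encode_message("10", params)
    seq = seqs[0]
    read = _designed_read(seq, alphabet)
    bc_len = params.coded_barcode_len
    true_kmer = read[bc_len:bc_len + 3]
    sub = "C" if true_kmer[0] != "C" else "G"
    corrupted = read[:bc_len] + sub + read[bc_len + 1:]
    assign = extract_position_kmers(corrupted, params)
    assert assign[0] == omega3.kmers.index(true_kmer)


def test_delta_rule_discards_frame_shifted_reads(mini_params, rng):
    seqs, _ = encode_message(random_bits(rng, 48), mini_params)
    read = _designed_read(seqs[0], mini_params.alphabet)
    assert extract_position_kmers(read[:-4], mini_params) is None      # |D|=4 > 2
    assert extract_position_kmers(read[:-2], mini_params) is not None  # |D|=2
    cm = counts_matrix([read, read[:-4], read + "ACGT"], mini_params)
    assert cm.n_skipped == 2
    assert cm.n_reads == 1


# -- grouping -----------------------------------------------------------------

def test_grouping_error_free_pool(mini_params, rng):
    seqs, _ = encode_message(random_bits(rng, 96), mini_params)
    pool = synthesize(seqs, mini_params.alphabet, SynthesisParams(30, 0, seed=1))
    rparams = ReconstructionParams(nominal_reads_per_seq=30)
    groups, met = group_reads(pool, [s.data_barcode for s in seqs],
                              mini_params, rparams)
    assert set(groups) == set(range(len(seqs)))
    assert all(len(v) == 30 for v in groups.values())
    assert met.n_reads_no_barcode == 0


def test_small_groups_filtered_by_ten_percent_rule(mini_params):
    barcodes = ["ACGTACGTACGT", "TTTTCCCCGGGG"]
    from shortmer.ecc import encode_barcode
    reads = [encode_barcode(barcodes[0]) + "A" * 12] * 9 \
        + [encode_barcode(barcodes[1]) + "A" * 12] * 50
    pool = ReadPool(reads)
    rparams = ReconstructionParams(nominal_reads_per_seq=100)
    groups, met = group_reads(pool, barcodes, mini_params, rparams)
    assert 0 not in groups        # 9 reads < 10% of S=100
    assert 1 in groups            # 50 reads pass
    assert met.n_groups_filtered == 1


def test_barcode_substitution_still_groups(mini_params, rng):
    seqs, _ = encode_message(random_bits(rng, 48), mini_params)
    read = _designed_read(seqs[0], mini_params.alphabet)
    corrupted = ("T" if read[0] != "T" else "A") + read[1:]
    pool = ReadPool([corrupted] * 5)
    rparams = ReconstructionParams(nominal_reads_per_seq=5)
    groups, _ = group_reads(pool, [s.data_barcode for s in seqs],
                            mini_params, rparams)
    assert groups == {0: [corrupted] * 5}


# -- Levenshtein ---------------------------------------------------------------

def test_normalized_levenshtein_basics():
    assert normalized_levenshtein("ACGT", "ACGT") == 0.0
    seq = list(range(134))
    other = seq.copy()
    other[7] = 999
    assert normalized_levenshtein(seq, other) == pytest.approx(1 / 134)
    with pytest.raises(ValueError):
        normalized_levenshtein("", "ACGT")


def test_levenshtein_agrees_with_edlib_oracle(rng):
    bases = "ACGT"
    for _ in range(400):
        a = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(1, 60)))
        b = "".join(bases[i] for i in rng.integers(0, 4, rng.integers(1, 60)))
        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]


def test_denominator_switch():
    # one deletion: distance 1, |O| = 3, |E| = 4
    assert normalized_levenshtein("ACG", "ACGT") == pytest.approx(1 / 3)
    assert normalized_levenshtein("ACG", "ACGT", "expected") == pytest.approx(1 / 4)


# -- end-to-end ----------------------------------------------------------------

@pytest.mark.parametrize("K", [3, 5, 7])
def test_null_channel_end_to_end_identity(K, rng):
    """No errors + exhaustive sampling: reconstruct(simulate(encode(m))) == m."""
    alphabet = CombinatorialAlphabet.binomial(default_omega(), K)
    params = EncodingParams(alphabet=alphabet, payload_len=8, block_size=4,
                            rs_payload=(8, 12), rs_block=(4, 6))
    data = rng.integers(0, 256, 150).astype("uint8").tobytes()
    seqs, _ = encode_bytes(data, params)
    # copies high enough that every member of every K=7 letter is seen:
    # P(miss) = K (1-1/K)^copies ~ 1e-10 at 150 copies
    pool = synthesize(seqs, alphabet, SynthesisParams(150, 2, seed=K))
    rparams = ReconstructionParams(nominal_reads_per_seq=150)
    bits, met = reconstruct_message(pool, params, rparams, design=seqs)
    assert bits_to_bytes(bits) == data
    assert met.nl_pre_rs == met.nl_post_payload_rs == met.nl_post_2d_rs == 0.0
    assert met.letter_error_rate == 0.0 and met.dropout_count == 0


def test_reconstruct_without_design_regenerates_barcodes(small_params, rng):
    data = rng.integers(0, 256, 60).astype("uint8").tobytes()
    seqs, layout = encode_bytes(data, small_params)
    pool = synthesize(seqs, small_params.alphabet, SynthesisParams(30, 0, seed=3))
    rparams = ReconstructionParams(nominal_reads_per_seq=30)
    bits, _ = reconstruct_message(pool, small_params, rparams, n_rows=layout.n_rows)
    assert bits_to_bytes(bits) == data


def test_six_dropped_rows_recovered_by_outer_erasures(rng):
    params = EncodingParams(alphabet=CombinatorialAlphabet.binomial(default_omega(), 5),
                            payload_len=8, block_size=42,
                            rs_payload=(8, 12), rs_block=(42, 48))
    # 490 bytes -> 41 data rows; with the padding-info row the block is exactly 42
    data = rng.integers(0, 256, 490).astype("uint8").tobytes()
    seqs, _ = encode_bytes(data, params)
    assert len(seqs) == 48
    pool = synthesize(seqs, params.alphabet, SynthesisParams(30, 0, seed=4))
    dropped = set(rng.choice(len(seqs), size=6, replace=False).tolist())
    keep = [i for i in range(len(pool)) if int(pool.labels[i]) not in dropped]
    pool = ReadPool([pool.reads[i] for i in keep], pool.labels[keep])
    rparams = ReconstructionParams(nominal_reads_per_seq=30)
    bits, met = reconstruct_message(pool, params, rparams, design=seqs)
    assert bits_to_bytes(bits) == data
    assert met.dropout_count == 6
    assert met.nl_post_2d_rs == 0.0


def test_stage_metrics_are_ordered_under_noise(rng):
    """RS never hurts: metric(iv) >= metric(iii) >= metric(ii)."""
    params = EncodingParams(alphabet=CombinatorialAlphabet.binomial(default_omega(), 5),
                            payload_len=20, block_size=10,
                            rs_payload=(20, 26), rs_block=(10, 14))
    data = rng.integers(0, 256, 400).astype("uint8").tobytes()
    seqs, _ = encode_bytes(data, params)
    pool = synthesize(seqs, params.alphabet, SynthesisParams(400, 10, seed=5),
                      ErrorRates(p_ins=0.01))
    pool = mix_and_sample(pool, SamplingParams(60, 10, seed=6))
    pool = apply_sequencing_errors(pool, 0.005, seed=7)
    rparams = ReconstructionParams(nominal_reads_per_seq=60)
    bits, met = reconstruct_message(pool, params, rparams, design=seqs)
    assert met.nl_pre_rs > 0.0
    assert met.nl_pre_rs >= met.nl_post_payload_rs >= met.nl_post_2d_rs


def test_sampling_rate_dominates_post_rs_error(rng):
    """Expected post-2D-RS error is non-increasing in the sampling rate S."""
    params = EncodingParams(alphabet=CombinatorialAlphabet.binomial(default_omega(), 5),
                            payload_len=8, block_size=4,
                            rs_payload=(8, 12), rs_block=(4, 6))
    data = rng.integers(0, 256, 100).astype("uint8").tobytes()
    seqs, _ = encode_bytes(data, params)
    base = synthesize(seqs, params.alphabet, SynthesisParams(400, 10, seed=8),
                      ErrorRates(p_ins=0.01))
    means = []
    for S in (3, 10, 50, 200):
        vals = []
        for rep in range(12):
            pool = mix_and_sample(base, SamplingParams(S, 1, seed=1000 + 31 * rep + S))
            rparams = ReconstructionParams(nominal_reads_per_seq=S)
            _, met = reconstruct_message(pool, params, rparams, design=seqs)
            vals.append(met.nl_post_2d_rs)
        means.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))
    assert means[-1] == 0.0
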