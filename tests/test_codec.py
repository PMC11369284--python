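"""Message <-> sequence conversion: padding arithmetic, roundtrips, barcodes,
design-file IO."""

from math import ceil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortmer.alphabet import CombinatorialAlphabet, default_omega, hamming
from shortmer.codec import (
    EncodingParams,
    bits_to_bytes,
    bytes_to_bits,
    decode_bytes,
    decode_message,
    default_params,
    encode_bytes,
    encode_message,
    generate_barcodes,
    read_design,
    write_design,
    write_design_fasta,
)
from conftest import random_bits


def test_toy_96_bit_message_fills_two_four_letter_sequences(rng, alphabet16_5):
    # 96 bits at 12 bits/letter and 4 letters/sequence -> 8 letters, 2 rows
    params = EncodingParams(alphabet=alphabet16_5, payload_len=4,
                            rs_payload=None, rs_block=None)
    bits = random_bits(rng, 96)
    seqs, layout = encode_message(bits, params)
    assert len(seqs) == 2
    assert layout.n_data_sequences == 2
    assert layout.bit_padding == layout.letter_padding == 0
    assert decode_message(seqs, params, layout) == bits


def test_worked_padding_example_824_bits(rng, alphabet16_3):
    """824 bits at r=9: padded to 828 = 92*9, split into 12-letter payloads in
    10-sequence blocks; the total padding is 148 bits."""
    params = EncodingParams(alphabet=alphabet16_3, payload_len=12, block_size=10,
                            rs_payload=(12, 18), rs_block=(10, 15))
    bits = random_bits(rng, 824)
    seqs, layout = encode_message(bits, params)
    assert layout.bit_padding == 4
    assert (824 + layout.bit_padding) == 828 == 92 * 9
    assert layout.letter_padding == 4
    assert layout.pad_sequences == 1
    assert layout.total_padding_bits == 148 == 4 + 4 * 9 + 12 * 9
    assert layout.n_data_sequences == 8
    assert len(seqs) == 15  # one 10-row block -> 15 rows after the outer code
    assert decode_message(seqs, params) == bits


@pytest.mark.parametrize("K", [3, 5, 7])
@pytest.mark.parametrize("n_bits", [1, 7, 96, 1441, 40000])
def test_roundtrip_identity_across_alphabets_and_sizes(K, n_bits, rng):
    alphabet = CombinatorialAlphabet.binomial(default_omega(), K)
    params = EncodingParams(alphabet=alphabet, payload_len=8, block_size=4,
                            rs_payload=(8, 12), rs_block=(4, 6))
    bits = random_bits(rng, n_bits)
    seqs, layout = encode_message(bits, params)
    assert decode_message(seqs, params) == bits


def test_default_parameters_roundtrip_10kb(rng):
    params = default_params(5)
    data = rng.integers(0, 256, 10_000).astype("uint8").tobytes()
    seqs, layout = encode_bytes(data, params)
    assert layout.n_data_sequences == ceil(80_000 / (12 * 120))
    assert len(seqs) % 48 == 0
    assert decode_bytes(seqs, params) == data


def test_single_bit_message_maximal_padding(small_params):
    seqs, layout = encode_message("1", small_params)
    assert layout.message_bits == 1
    assert decode_message(seqs, small_params) == "1"


def test_sequence_count_formula(rng, small_params):
    """data sequences == ceil(message_bits / (r*l)) (pre-padding)."""
    r, l = small_params.r, small_params.payload_len
    for n_bits in (1, 5, 95, 96, 97, 700):
        bits = random_bits(rng, n_bits)
        _, layout = encode_message(bits, small_params)
        assert layout.n_data_sequences == ceil(n_bits / (r * l))


def test_blocks_are_complete_before_outer_coding(rng, small_params):
    B, B_rs = small_params.block_size, small_params.rs_block[1]
    for n_bits in (1, 96, 500, 2000):
        seqs, layout = encode_message(random_bits(rng, n_bits), small_params)
        assert len(seqs) % B_rs == 0
        n_pre = layout.n_data_sequences + layout.pad_sequences + 1
        assert n_pre % B == 0


def test_empty_message_rejected(small_params):
    with pytest.raises(ValueError):
        encode_message("", small_params)


def test_invalid_letter_value_rejected_on_decode(small_params):
    seqs, layout = encode_message("1010", small_params)
    rows = [list(s.payload) for s in seqs]
    rows[0][0] = small_params.alphabet.n_values  # out of the addressable range
    with pytest.raises(ValueError, match="invalid letter"):
        decode_message(rows, small_params)


def test_inconsistent_padding_info_rejected(alphabet16_5):
    """A padding count exceeding what one block can absorb must be refused."""
    from shortmer import ecc
    from shortmer.codec import _info_letters, generate_barcodes as gen
    params = EncodingParams(alphabet=alphabet16_5, payload_len=4, block_size=2,
                            rs_payload=(4, 6), rs_block=(2, 4))
    r, l = params.r, params.payload_len
    bogus = r * l * params.block_size + 17  # beyond max possible padding
    rows = [[0] * l, _info_letters(bogus, r, l)]
    coded = [list(ecc.rs_encode(row, params.payload_code)) for row in rows]
    block = ecc.encode_block(np.array(coded), params.block_code)
    with pytest.raises(ValueError, match="padding"):
        decode_message([tuple(r) for r in block.tolist()], params)


def test_bit_byte_helpers_roundtrip(rng):
    data = rng.integers(0, 256, 64).astype("uint8").tobytes()
    assert bits_to_bytes(bytes_to_bits(data)) == data
    with pytest.raises(ValueError):
        bits_to_bytes("1010101")  # not a byte multiple


# -- barcodes ---------------------------------------------------------------

def test_barcode_set_98_of_length_12_distance_5():
    bcs = generate_barcodes(98, 12, 5, seed=7)
    assert len(set(bcs)) == 98
    for i in range(98):
        for j in range(i + 1, 98):
            assert hamming(bcs[i], bcs[j]) >= 5


def test_two_fully_distinct_barcodes():
    bcs = generate_barcodes(2, 12, 12, seed=0)
    assert hamming(bcs[0], bcs[1]) == 12


def test_barcode_infeasible_request():
    with pytest.raises(ValueError, match="infeasible"):
        generate_barcodes(5, 1, 1)


def test_barcodes_deterministic_per_seed():
    assert generate_barcodes(10, 12, 5, seed=3) == generate_barcodes(10, 12, 5, seed=3)
    assert generate_barcodes(10, 12, 5, seed=3) != generate_barcodes(10, 12, 5, seed=4)


# -- design files -----------------------------------------------------------

def test_design_file_roundtrip(tmp_path, rng, small_params):
    seqs, _ = encode_message(random_bits(rng, 300), small_params)
    path = tmp_path / "design.tsv"
    write_design(seqs, small_params.alphabet, path)
    back = read_design(path, small_params.alphabet)
    assert [s.payload for s in back] == [s.payload for s in seqs]
    assert [s.barcode for s in back] == [s.barcode for s in seqs]
    assert [s.data_barcode for s in back] == [s.data_barcode for s in seqs]


def test_design_fasta_written(tmp_path, rng, small_params):
    seqs, _ = encode_message(random_bits(rng, 50), small_params)
    path = tmp_path / "design.fasta"
    write_design_fasta(seqs, small_params.alphabet, path)
    text = path.read_text()
    assert text.count(">") == len(seqs)
    assert seqs[0].barcode in text


@settings(max_examples=25, deadline=None)
@given(n_bits=st.integers(min_value=1, max_value=600),
       seed=st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_roundtrip_property(small_params, n_bits, seed):
    bits = random_bits(np.random.default_rng(seed), n_bits)
    seqs, _ = encode_message(bits, small_params)
    assert decode_message(seqs, small_params) == bits
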