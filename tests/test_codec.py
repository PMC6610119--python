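"""Byte <-> oligo codec: scrambling, inner/outer codes, file round trips."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from porestore.codec import (FileParams, UnrecoverableFileError,
                             decode_file_full, decode_index_prefix,
                             encode_file, inner_decode, inner_encode,
                             outer_decode, outer_encode, scramble)
from porestore.dna import max_run_length


# ---------------------------------------------------------------------------
# scrambling

@given(st.binary(min_size=1, max_size=300), st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True)
def test_scramble_is_involution(data, seed):
    assert scramble(scramble(data, seed), seed) == data
    assert len(scramble(data, seed)) == len(data)


def test_scramble_of_zeros_is_keystream():
    z = bytes(64)
    ks = scramble(z, 5)
    assert scramble(ks, 5) == z  # XOR with itself restores zeros
    assert ks != z


def test_scrambled_bytes_uniform():
    """10 kB of random data stays byte-uniform after scrambling."""
    rng = np.random.Generator(np.random.PCG64(42))
    data = rng.integers(0, 256, 10_240, dtype=np.uint8).tobytes()
    out = np.frombuffer(scramble(data, 9), dtype=np.uint8)
    counts = np.bincount(out, minlength=256)
    assert stats.chisquare(counts).pvalue > 0.01


# ---------------------------------------------------------------------------
# inner code

def test_direct_mapping_is_two_bits_per_base():
    bits = [0, 0, 0, 1, 1, 0, 1, 1]
    assert inner_encode(bits, "direct") == "ACGT"


@pytest.mark.parametrize("mode,step", [("direct", 2),
                                       ("homopolymer_free", 4)])
def test_inner_roundtrip(mode, step):
    rng = random.Random(7)
    for _ in range(200):
        bits = [rng.randint(0, 1) for _ in range(step * rng.randint(1, 40))]
        seq = inner_encode(bits, mode)
        assert inner_decode(seq, mode).tolist() == bits


def test_homopolymer_free_never_repeats():
    rng = random.Random(3)
    for _ in range(100):
        bits = [rng.randint(0, 1) for _ in range(4 * rng.randint(1, 50))]
        seq = inner_encode(bits, "homopolymer_free")
        assert max_run_length(seq) == 1


# ---------------------------------------------------------------------------
# outer code

def test_outer_zero_redundancy_is_identity():
    blocks = [bytes([i] * 8) for i in range(5)]
    assert outer_encode(blocks, 0.0) == blocks


def test_outer_twenty_blocks_quarter_redundancy():
    """20 data blocks at 0.25 become 25; any 5 erasures recover."""
    rng = random.Random(0)
    blocks = [bytes(rng.randrange(256) for _ in range(16))
              for _ in range(20)]
    enc = outer_encode(blocks, 0.25)
    assert len(enc) == 25
    for _ in range(15):
        erased = set(rng.sample(range(25), 5))
        damaged = [None if i in erased else enc[i] for i in range(25)]
        dec, _ = outer_decode(damaged, 0.25, n_data=20)
        assert dec == blocks


def test_outer_single_block_half_redundancy():
    blocks = [b"\x42" * 4]
    enc = outer_encode(blocks, 0.5)
    assert len(enc) == 2
    for erase in (0, 1):
        damaged = [None if i == erase else enc[i] for i in range(2)]
        dec, _ = outer_decode(damaged, 0.5, n_data=1)
        assert dec == blocks


def test_outer_corrects_symbol_errors():
    rng = random.Random(5)
    blocks = [bytes(rng.randrange(256) for _ in range(12))
              for _ in range(30)]
    enc = outer_encode(blocks, 0.25)
    n_parity = len(enc) - 30
    damaged = [bytearray(b) for b in enc]
    wrong = rng.sample(range(len(enc)), n_parity // 2)
    for i in wrong:
        damaged[i] = bytearray(rng.randrange(256) for _ in range(12))
    dec, corrected = outer_decode([bytes(b) for b in damaged], 0.25,
                                  n_data=30)
    assert dec == blocks


# ---------------------------------------------------------------------------
# whole files

@pytest.mark.parametrize("mode", ["direct", "homopolymer_free"])
@pytest.mark.parametrize("redundancy", [0.0, 0.1, 0.25, 0.5])
def test_file_roundtrip(file_ids, mode, redundancy):
    p = FileParams(file_id_front=file_ids[0], file_id_back=file_ids[1],
                   redundancy_fraction=redundancy, inner_mode=mode,
                   scramble_seed=2)
    rng = np.random.Generator(np.random.PCG64(21))
    data = rng.integers(0, 256, 1536, dtype=np.uint8).tobytes()
    enc = encode_file(data, p)
    assert all(len(o.sequence) == 150 for o in enc.oligos)
    assert all(o.sequence == p.file_id_front + o.payload + p.file_id_back
               for o in enc.oligos)
    pairs = [(o.index, o.payload) for o in enc.oligos]
    out, report = decode_file_full(pairs, p, n_oligos=enc.n_oligos)
    assert out == data
    assert report.erased_indices == []


def test_oligo_count_matches_capacity_formula(file_ids):
    """Oligo count agrees with independent payload-capacity arithmetic."""
    p = FileParams(file_id_front=file_ids[0], file_id_back=file_ids[1],
                   redundancy_fraction=0.25)
    size = 5000
    data = bytes(size)
    enc = encode_file(data, p)
    bits_per_payload = 2 * 110          # direct inner code
    block_bytes = (bits_per_payload - p.index_bits) // 8
    n_data = math.ceil((size + 8) / block_bytes)  # 8-byte length header
    assert enc.n_data_blocks == n_data
    assert enc.n_parity_blocks >= math.floor(n_data * 0.25)
    assert enc.n_oligos == enc.n_data_blocks + enc.n_parity_blocks


def test_homopolymer_free_payloads_have_no_runs(file_ids):
    p = FileParams(file_id_front=file_ids[0], file_id_back=file_ids[1],
                   inner_mode="homopolymer_free")
    rng = np.random.Generator(np.random.PCG64(4))
    enc = encode_file(rng.integers(0, 256, 2000, dtype=np.uint8).tobytes(),
                      p)
    assert all(max_run_length(o.payload) < 3 for o in enc.oligos)


def test_index_prefix_decodes(small_encoded, params):
    _, enc = small_encoded
    for o in enc.oligos[::7]:
        assert decode_index_prefix(o.payload, params) == o.index


def test_erasure_sharpness(file_ids):
    """Exactly n_parity erased oligos recover; one more does not."""
    p = FileParams(file_id_front=file_ids[0], file_id_back=file_ids[1],
                   redundancy_fraction=0.25, scramble_seed=1)
    rng = np.random.Generator(np.random.PCG64(8))
    data = rng.integers(0, 256, 600, dtype=np.uint8).tobytes()
    enc = encode_file(data, p)
    n_parity = enc.n_parity_blocks
    pairs = [(o.index, o.payload) for o in enc.oligos]
    random.Random(1).shuffle(pairs)
    ok, _ = decode_file_full(pairs[n_parity:], p, n_oligos=enc.n_oligos)
    assert ok == data
    with pytest.raises(UnrecoverableFileError):
        decode_file_full(pairs[n_parity + 1:], p, n_oligos=enc.n_oligos)


def test_erasure_sweep_around_threshold(file_ids):
    """Random erasures below the redundancy fraction always recover."""
    p = FileParams(file_id_front=file_ids[0], file_id_back=file_ids[1],
                   redundancy_fraction=0.25, scramble_seed=6)
    rng = np.random.Generator(np.random.PCG64(17))
    data = rng.integers(0, 256, 1200, dtype=np.uint8).tobytes()
    enc = encode_file(data, p)
    pyrng = random.Random(3)
    for frac in (0.05, 0.15):
        drop = set(pyrng.sample(range(enc.n_oligos),
                                int(frac * enc.n_oligos)))
        pairs = [(o.index, o.payload) for o in enc.oligos
                 if o.index not in drop]
        out, _ = decode_file_full(pairs, p, n_oligos=enc.n_oligos)
        assert out == data


def test_empty_file_rejected(params):
    with pytest.raises(ValueError):
        encode_file(b"", params)
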