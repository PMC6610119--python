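"""File <-> oligo codec for DNA data storage.

Bytes are mapped to a pool of 150-nt oligos, each carrying a 20-nt front
file ID, a 110-nt payload and a 20-nt back file ID.  The encoding
pipeline is

    randomize (XOR keystream) -> outer Reed-Solomon code over blocks
    -> per-block inner code (bits -> bases) with an explicit index
       prefix -> flank with file IDs

and decoding inverts each stage.  The outer code treats each oligo
payload as one byte block; whole-block losses are erasures and wrong
consensus payloads are symbol errors, both corrected by the
errors-and-erasures Reed-Solomon decoder (up to ``e + 2t <= n_parity``
per stripe).

Two inner codes are provided: ``direct`` packs 2 bits/base
(A=00, C=01, G=10, T=11); ``homopolymer_free`` packs 4 bits into 3
bases through a rotating quaternary code that never repeats a base, for
pools where homopolymer runs must be avoided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import rs
from .dna import indices_to_seq, seq_to_indices

__all__ = [
    "FileParams",
    "OligoRecord",
    "EncodedFile",
    "DecodeReport",
    "UnrecoverableFileError",
    "scramble",
    "outer_encode",
    "outer_decode",
    "inner_encode",
    "inner_decode",
    "encode_file",
    "decode_file",
    "decode_file_full",
    "decode_index_prefix",
    "make_file_ids",
]

_LEN_HEADER = 8  # bytes, little-endian payload byte count


class UnrecoverableFileError(Exception):
    """Decoding failed: losses exceed the outer-code budget."""

    def __init__(self, message, n_missing=None, bad_stripes=None):
        super().__init__(message)
        self.n_missing = n_missing
        self.bad_stripes = bad_stripes or []


@dataclass(frozen=True)
class FileParams:
    """Geometry and codec configuration for one encoded file."""

    file_id_front: str
    file_id_back: str
    payload_len: int = 110
    index_bits: int = 24
    redundancy_fraction: float = 0.25
    inner_mode: str = "direct"  # or "homopolymer_free"
    scramble_seed: int = 0

    def __post_init__(self):
        if len(self.file_id_front) != 20 or len(self.file_id_back) != 20:
            raise ValueError("file IDs must be 20 nt")
        if not 0 <= self.redundancy_fraction < 1:
            raise ValueError("redundancy_fraction must be in [0, 1)")
        if self.inner_mode not in ("direct", "homopolymer_free"):
            raise ValueError(f"unknown inner_mode {self.inner_mode!r}")
        if self.index_bits % 4 != 0:
            raise ValueError("index_bits must be a multiple of 4")

    @property
    def oligo_len(self) -> int:
        return 40 + self.payload_len

    @property
    def payload_bit_capacity(self) -> int:
        """Usable bits per payload under the inner code."""
        if self.inner_mode == "direct":
            return 2 * self.payload_len
        return 4 * (self.payload_len // 3)

    @property
    def block_size(self) -> int:
        """Data bytes carried per oligo after the index prefix."""
        return (self.payload_bit_capacity - self.index_bits) // 8

    @property
    def max_oligos(self) -> int:
        return 1 << self.index_bits


@dataclass(frozen=True)
class OligoRecord:
    index: int
    sequence: str
    payload: str


@dataclass
class EncodedFile:
    params: FileParams
    oligos: list
    n_data_blocks: int
    n_parity_blocks: int

    @property
    def n_oligos(self) -> int:
        return len(self.oligos)


@dataclass
class DecodeReport:
    n_expected: int
    erased_indices: list = field(default_factory=list)
    corrected_indices: list = field(default_factory=list)
    n_duplicates_dropped: int = 0
    n_undecodable_payloads: int = 0


# ---------------------------------------------------------------------------
# randomization

def scramble(data: bytes, seed: int) -> bytes:
    """XOR ``data`` with a PCG64 keystream; an involution for fixed seed."""
    ks = np.random.Generator(np.random.PCG64(seed)).integers(
        0, 256, len(data), dtype=np.uint8)
    return (np.frombuffer(data, dtype=np.uint8) ^ ks).tobytes()


# ---------------------------------------------------------------------------
# outer Reed-Solomon code over byte blocks

def _stripe_layout(n_data: int, redundancy_fraction: float):
    """Partition ``n_data`` blocks into stripes with n <= 255 codewords.

    Returns a list of (n_data_in_stripe, n_parity_in_stripe).  Parity
    per stripe is ceil(n_data_stripe * r), matching one parity block per
    1/r data blocks.
    """
    if n_data < 1:
        raise ValueError("need at least one data block")
    r = redundancy_fraction
    if r == 0:
        # still must respect nothing; single conceptual stripe, no parity
        return [(n_data, 0)]
    # largest stripe data count d with d + ceil(d*r) <= 255
    d_max = 1
    for d in range(1, 256):
        if d + math.ceil(d * r) <= 255:
            d_max = d
    n_stripes = math.ceil(n_data / d_max)
    base = n_data // n_stripes
    extra = n_data % n_stripes
    layout = []
    for s in range(n_stripes):
        d = base + (1 if s < extra else 0)
        layout.append((d, math.ceil(d * r)))
    return layout


def outer_encode(blocks: Sequence[bytes], redundancy_fraction: float):
    """Append Reed-Solomon parity blocks to ``blocks``.

    Codewords run across blocks: byte j of every block in a stripe forms
    one RS codeword.  Returns data blocks (original order) followed by
    parity blocks, stripe by stripe.
    """
    blocks = [bytes(b) for b in blocks]
    if not blocks:
        raise ValueError("no blocks to encode")
    blen = len(blocks[0])
    if any(len(b) != blen for b in blocks):
        raise ValueError("blocks must have equal length")
    if redundancy_fraction == 0:
        return list(blocks)
    layout = _stripe_layout(len(blocks), redundancy_fraction)
    out = list(blocks)
    start = 0
    for n_d, n_p in layout:
        stripe = blocks[start:start + n_d]
        start += n_d
        parity = [bytearray(blen) for _ in range(n_p)]
        for j in range(blen):
            col = [b[j] for b in stripe]
            cw = rs.rs_encode(col, n_p)
            for i in range(n_p):
                parity[i][j] = cw[n_d + i]
        out.extend(bytes(p) for p in parity)
    return out


def outer_decode(blocks: Sequence[Optional[bytes]],
                 redundancy_fraction: float,
                 n_data: int):
    """Recover the ``n_data`` data blocks from a damaged encoded set.

    ``blocks`` is the full encoded layout (data then per-stripe parity)
    with ``None`` marking erased blocks; present blocks may carry symbol
    errors.  Raises :class:`UnrecoverableFileError` when any stripe is
    beyond its budget.
    """
    layout = _stripe_layout(n_data, redundancy_fraction)
    if redundancy_fraction == 0:
        missing = [i for i, b in enumerate(blocks[:n_data]) if b is None]
        if missing:
            raise UnrecoverableFileError(
                f"{len(missing)} blocks missing with no redundancy",
                n_missing=len(missing))
        return list(blocks[:n_data]), []
    blen = next(len(b) for b in blocks if b is not None)
    data_out = []
    corrected = []
    d_start, p_start = 0, n_data
    bad = []
    for s, (n_d, n_p) in enumerate(layout):
        stripe = list(blocks[d_start:d_start + n_d]) + \
            list(blocks[p_start:p_start + n_p])
        erase_pos = [i for i, b in enumerate(stripe) if b is None]
        if len(erase_pos) > n_p:
            bad.append((s, len(erase_pos), n_p))
            data_out.extend([None] * n_d)
            d_start += n_d
            p_start += n_p
            continue
        rows = [bytearray(b) if b is not None else bytearray(blen)
                for b in stripe]
        changed = [False] * len(stripe)
        try:
            for j in range(blen):
                col = [row[j] for row in rows]
                dec, cw = rs.rs_decode(col, n_p, erase_pos=erase_pos)
                for i in range(len(stripe)):
                    if cw[i] != col[i]:
                        changed[i] = True
                        rows[i][j] = cw[i]
        except rs.RSDecodeError:
            bad.append((s, len(erase_pos), n_p))
            data_out.extend([None] * n_d)
            d_start += n_d
            p_start += n_p
            continue
        for i in range(n_d):
            if i not in erase_pos and changed[i]:
                corrected.append(d_start + i)
        data_out.extend(bytes(rows[i]) for i in range(n_d))
        d_start += n_d
        p_start += n_p
    if bad:
        n_missing = sum(1 for b in blocks if b is None)
        raise UnrecoverableFileError(
            f"{len(bad)} stripe(s) beyond correction budget "
            f"({n_missing} blocks missing in total)",
            n_missing=n_missing, bad_stripes=bad)
    return data_out, corrected


# ---------------------------------------------------------------------------
# inner code: bits <-> bases

_NIBBLE_TO_TRITS = np.array(
    [(v // 9, (v // 3) % 3, v % 3) for v in range(16)], dtype=np.uint8)
_TRITS_TO_NIBBLE = np.full((3, 3, 3), 255, dtype=np.uint8)
for _v in range(16):
    _t = _NIBBLE_TO_TRITS[_v]
    _TRITS_TO_NIBBLE[_t[0], _t[1], _t[2]] = _v


def _bits_to_array(bits) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1 or (arr.size and arr.max() > 1):
        raise ValueError("bits must be a flat 0/1 array")
    return arr


def inner_encode(bits, mode: str) -> str:
    """Convert a bit array to DNA.

    ``direct``: 2 bits/base (length must be even).
    ``homopolymer_free``: 4 bits -> 3 bases (length must be a multiple
    of 4) through a rotating code; consecutive bases always differ.
    """
    arr = _bits_to_array(bits)
    if mode == "direct":
        if arr.size % 2:
            raise ValueError("direct mode needs an even number of bits")
        pairs = arr.reshape(-1, 2)
        idx = (pairs[:, 0] << 1) | pairs[:, 1]
        return indices_to_seq(idx)
    if mode == "homopolymer_free":
        if arr.size % 4:
            raise ValueError(
                "homopolymer_free mode needs a multiple of 4 bits")
        nib = arr.reshape(-1, 4)
        vals = (nib[:, 0] << 3) | (nib[:, 1] << 2) | (nib[:, 2] << 1) \
            | nib[:, 3]
        trits = _NIBBLE_TO_TRITS[vals].reshape(-1)
        # rotate: base_k = (base_{k-1} + 1 + trit_k) mod 4, base_{-1}=3
        idx = (np.cumsum(trits.astype(np.int64) + 1) + 3) % 4
        return indices_to_seq(idx.astype(np.uint8))
    raise ValueError(f"unknown inner mode {mode!r}")


def inner_decode(seq: str, mode: str) -> np.ndarray:
    """Invert :func:`inner_encode`; raises ValueError on invalid input."""
    idx = seq_to_indices(seq).astype(np.int64)
    if mode == "direct":
        bits = np.empty(2 * idx.size, dtype=np.uint8)
        bits[0::2] = idx >> 1
        bits[1::2] = idx & 1
        return bits
    if mode == "homopolymer_free":
        if idx.size % 3:
            raise ValueError("length must be a multiple of 3 bases")
        prev = np.concatenate(([3], idx[:-1]))
        trits = (idx - prev - 1) % 4
        if (trits > 2).any():
            raise ValueError("repeated base: not a rotating-code word")
        t = trits.reshape(-1, 3).astype(np.uint8)
        vals = _TRITS_TO_NIBBLE[t[:, 0], t[:, 1], t[:, 2]]
        if (vals > 15).any():
            raise ValueError("invalid trit chunk")
        bits = np.empty(4 * vals.size, dtype=np.uint8)
        bits[0::4] = vals >> 3
        bits[1::4] = (vals >> 2) & 1
        bits[2::4] = (vals >> 1) & 1
        bits[3::4] = vals & 1
        return bits
    raise ValueError(f"unknown inner mode {mode!r}")


def _int_to_bits(value: int, width: int) -> np.ndarray:
    return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=np.uint8)


def _bits_to_int(bits: np.ndarray) -> int:
    v = 0
    for b in bits:
        v = (v << 1) | int(b)
    return v


def _index_mask(params: FileParams) -> np.ndarray:
    """Whitening mask for the index prefix bits.

    Raw indices are small integers, so their high bits are almost all
    zero; coded directly they would open every payload with a long
    homopolymer run (a hotspot for correlated nanopore deletions) and
    make index prefixes nearly identical across oligos.  XORing a
    seeded pseudo-random mask randomizes the prefix; the XOR is its
    own inverse.
    """
    rng = np.random.Generator(
        np.random.PCG64(params.scramble_seed ^ 0x9E3779B9))
    return rng.integers(0, 2, params.index_bits, dtype=np.uint8)


def _pad_bases(seq: str, target_len: int, mode: str) -> str:
    """Deterministic base padding preserving the no-repeat property."""
    if len(seq) >= target_len:
        return seq[:target_len]
    pad = []
    order = "ACGT"
    prev = seq[-1] if seq else "T"
    while len(seq) + len(pad) < target_len:
        nxt = order[(order.index(prev) + 1) % 4]
        pad.append(nxt)
        prev = nxt
    return seq + "".join(pad)


def _encode_payload(index: int, block: bytes, params: FileParams) -> str:
    bits = np.concatenate([
        _int_to_bits(index, params.index_bits) ^ _index_mask(params),
        np.unpackbits(np.frombuffer(block, dtype=np.uint8)),
    ])
    seq = inner_encode(bits, params.inner_mode)
    return _pad_bases(seq, params.payload_len, params.inner_mode)


def _decode_payload(payload: str, params: FileParams):
    """Payload window -> (index, block bytes); ValueError if undecodable."""
    if params.inner_mode == "direct":
        n_bases = (params.index_bits + 8 * params.block_size) // 2
    else:
        n_bases = 3 * (params.index_bits + 8 * params.block_size) // 4
    if len(payload) < n_bases:
        raise ValueError("payload window too short")
    bits = inner_decode(payload[:n_bases], params.inner_mode)
    index = _bits_to_int(bits[:params.index_bits] ^ _index_mask(params))
    block = np.packbits(bits[params.index_bits:
                             params.index_bits + 8 * params.block_size])
    return index, block.tobytes()


def decode_index_prefix(payload: str, params: FileParams) -> int:
    """Decode only the index prefix of a payload window.

    Used for index-first clustering; raises ValueError when the prefix
    is not a valid inner-code word.
    """
    if params.inner_mode == "direct":
        n_bases = params.index_bits // 2
    else:
        n_bases = 3 * params.index_bits // 4
    if len(payload) < n_bases:
        raise ValueError("window shorter than index prefix")
    bits = inner_decode(payload[:n_bases], params.inner_mode)
    return _bits_to_int(bits[:params.index_bits] ^ _index_mask(params))


# ---------------------------------------------------------------------------
# whole-file encode / decode

def encode_file(data: bytes, params: FileParams) -> EncodedFile:
    """Encode ``data`` into a pool of 150-nt oligos."""
    if not data:
        raise ValueError("cannot encode an empty file")
    header = len(data).to_bytes(_LEN_HEADER, "little")
    stream = scramble(header + data, params.scramble_seed)
    bs = params.block_size
    n_blocks = math.ceil(len(stream) / bs)
    stream = stream.ljust(n_blocks * bs, b"\0")
    blocks = [stream[i * bs:(i + 1) * bs] for i in range(n_blocks)]
    encoded = outer_encode(blocks, params.redundancy_fraction)
    n_parity = len(encoded) - n_blocks
    if len(encoded) > params.max_oligos:
        raise ValueError(
            f"{len(encoded)} blocks exceed index capacity "
            f"2^{params.index_bits}")
    oligos = []
    for i, block in enumerate(encoded):
        payload = _encode_payload(i, block, params)
        seq = params.file_id_front + payload + params.file_id_back
        oligos.append(OligoRecord(index=i, sequence=seq, payload=payload))
    return EncodedFile(params=params, oligos=oligos,
                       n_data_blocks=n_blocks, n_parity_blocks=n_parity)


def decode_file_full(consensus_payloads: Iterable,
                     params: FileParams,
                     n_oligos: Optional[int] = None):
    """Decode (index, payload) pairs back to bytes, with a report.

    ``consensus_payloads`` yields (index, 110-nt window) pairs; the
    index embedded in the payload takes precedence over the supplied
    one when both decode (they agree for correct consensus sequences).
    ``n_oligos`` fixes the encoded pool size; if omitted it is inferred
    from the largest decodable index.
    """
    by_index = {}
    n_dups = 0
    n_bad = 0
    for given_index, payload in consensus_payloads:
        try:
            index, block = _decode_payload(payload, params)
        except ValueError:
            n_bad += 1
            continue
        if index in by_index:
            n_dups += 1
            continue
        by_index[index] = block
    if not by_index:
        raise UnrecoverableFileError("no decodable payloads", n_missing=None)

    if n_oligos is None:
        n_oligos = max(by_index) + 1
    # recover (n_data, n_parity) from total count and redundancy
    r = params.redundancy_fraction
    n_data = n_oligos
    if r > 0:
        for cand in range(n_oligos, 0, -1):
            if cand + sum(p for _, p in _stripe_layout(cand, r)) == n_oligos:
                n_data = cand
                break
        else:
            raise UnrecoverableFileError(
                f"no stripe layout matches pool size {n_oligos}")
    blocks = [by_index.get(i) for i in range(n_oligos)]
    erased = [i for i in range(n_data) if blocks[i] is None]
    data_blocks, corrected = outer_decode(
        blocks, r, n_data)
    stream = b"".join(data_blocks)
    stream = scramble(stream, params.scramble_seed)
    length = int.from_bytes(stream[:_LEN_HEADER], "little")
    if length > len(stream) - _LEN_HEADER:
        raise UnrecoverableFileError(
            f"corrupt length header ({length} > {len(stream)})")
    report = DecodeReport(n_expected=n_oligos, erased_indices=erased,
                          corrected_indices=corrected,
                          n_duplicates_dropped=n_dups,
                          n_undecodable_payloads=n_bad)
    return stream[_LEN_HEADER:_LEN_HEADER + length], report


def decode_file(consensus_payloads: Iterable,
                params: FileParams,
                n_oligos: Optional[int] = None) -> bytes:
    data, _ = decode_file_full(consensus_payloads, params, n_oligos)
    return data


# ---------------------------------------------------------------------------

def make_file_ids(seed: int, n_pairs: int = 1, gc_bounds=(0.4, 0.6),
                  min_pair_dist: int = 10):
    """Generate (front, back) 20-nt file-ID pairs.

    IDs satisfy GC bounds, contain no homopolymer run >= 4, and every
    pair of generated IDs differs by more than ``min_pair_dist`` edits,
    so anchor search cannot confuse them.
    """
    import edlib

    from .dna import gc_fraction, max_run_length, random_seq
    rng = np.random.Generator(np.random.PCG64(seed))
    ids = []
    while len(ids) < 2 * n_pairs:
        s = random_seq(rng, 20)
        if not gc_bounds[0] <= gc_fraction(s) <= gc_bounds[1]:
            continue
        if max_run_length(s) >= 4:
            continue
        if any(edlib.align(s, t)["editDistance"] <= min_pair_dist
               for t in ids):
            continue
        ids.append(s)
    return [(ids[2 * i], ids[2 * i + 1]) for i in range(n_pairs)]
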