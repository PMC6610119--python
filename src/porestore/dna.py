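"""Small DNA sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# uint8 ASCII code -> base index lookup
_ASCII_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_TO_IDX.items():
    _ASCII_TO_IDX[ord(_b)] = _i
    _ASCII_TO_IDX[ord(_b.lower())] = _i
_IDX_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def seq_to_indices(seq: str) -> np.ndarray:
    """ACGT string -> uint8 array of base indices (A=0..T=3)."""
    arr = _ASCII_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def indices_to_seq(arr: np.ndarray) -> str:
    return _IDX_TO_ASCII[np.asarray(arr, dtype=np.uint8)].tobytes().decode()


def random_seq(rng: np.random.Generator, n: int) -> str:
    return indices_to_seq(rng.integers(0, 4, n, dtype=np.uint8))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def find_runs(seq: str, min_len: int = 1):
    """Maximal homopolymer runs of length >= min_len as (start, length)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def max_run_length(seq: str) -> int:
    runs = find_runs(seq, 1)
    return max((l for _, l in runs), default=0)
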