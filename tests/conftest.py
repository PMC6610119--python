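import numpy as np
import pytest

from porestore.codec import FileParams, encode_file, make_file_ids


@pytest.fixture(scope="session")
def file_ids():
    return make_file_ids(7)[0]


@pytest.fixture(scope="session")
def params(file_ids):
    front, back = file_ids
    return FileParams(file_id_front=front, file_id_back=back,
                      redundancy_fraction=0.25, scramble_seed=3)


@pytest.fixture(scope="session")
def small_encoded(params):
    rng = np.random.Generator(np.random.PCG64(11))
    data = rng.integers(0, 256, 2048, dtype=np.uint8).tobytes()
    return data, encode_file(data, params)


def edit_distance_oracle(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance, independent of edlib."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (a[i - 1] != b[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


def semiglobal_distance_oracle(read: str, anchor: str) -> int:
    """Min edit distance of anchor vs any substring of read
    (free gaps at both read ends)."""
    best = len(anchor)
    n = len(read)
    for i in range(n + 1):
        # DP of anchor against read[i:], allowing any end
        prev = [0] * (n - i + 1)
        for k, c in enumerate(anchor, start=1):
            cur = [k] + [0] * (n - i)
            for j in range(1, n - i + 1):
                cur[j] = min(prev[j - 1] + (c != read[i + j - 1]),
                             prev[j] + 1, cur[j - 1] + 1)
            prev = cur
        if prev:
            best = min(best, min(prev))
    return best
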