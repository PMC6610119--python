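"""Clustering and pointer/plurality consensus with out-of-sync recovery."""

from collections import Counter

import numpy as np
import pytest

from porestore.consensus import (ConsensusParams,
                                 classify_disagreement,
                                 cluster_observations, consensus_sequence,
                                 plurality_vote, resync)
from porestore.dna import find_runs, random_seq
from porestore.extract import PayloadObservation
from porestore.simulate import ErrorProfile, apply_channel


def _obs(window, rid="r", pos=0):
    return PayloadObservation(read_id=rid, window=window,
                              position_in_read=pos, source_strand="+")


# ---------------------------------------------------------------------------
# plurality vote

def test_plurality_examples():
    assert plurality_vote(["A", "A", "G"]) == ("A", 1)
    assert plurality_vote(["A", "G"]) == ("A", 0)  # tie -> A < G
    assert plurality_vote(["T"] * 5) == ("T", 5)


def test_plurality_matches_counting_oracle():
    rng = np.random.default_rng(1)
    for _ in range(200):
        symbols = [("ACGT")[i] for i in rng.integers(0, 4, rng.integers(1, 12))]
        base, margin = plurality_vote(symbols)
        counts = Counter(symbols)
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        assert base == winners[0]
        others = [c for b, c in counts.items() if b != base]
        assert margin == top - (max(others) if others else 0)


# ---------------------------------------------------------------------------
# disagreement classification (constructed fixtures, all error types)

TRUTH = "ACGTTGCAGATCCATGGTAC"


@pytest.mark.parametrize("pos", [3, 8, 12])
@pytest.mark.parametrize("base", "ACGT")
def test_classify_substitution(pos, base):
    if base == TRUTH[pos]:
        pytest.skip("not a substitution")
    member = TRUTH[:pos] + base + TRUTH[pos + 1:]
    context = TRUTH[pos + 1:pos + 6]
    assert classify_disagreement(member, pos, TRUTH[pos], context) \
        == "substitution"


@pytest.mark.parametrize("pos", [3, 8, 12])
@pytest.mark.parametrize("base", "ACGT")
def test_classify_insertion(pos, base):
    member = TRUTH[:pos] + base + TRUTH[pos:]
    if member[pos] == TRUTH[pos]:
        pytest.skip("insertion invisible at this step")
    context = TRUTH[pos + 1:pos + 6]
    assert classify_disagreement(member, pos, TRUTH[pos], context) \
        == "insertion"


@pytest.mark.parametrize("pos", [3, 8, 12])
def test_classify_deletion(pos):
    member = TRUTH[:pos] + TRUTH[pos + 1:]
    if member[pos] == TRUTH[pos]:
        pytest.skip("deletion invisible at this step")
    context = TRUTH[pos + 1:pos + 6]
    assert classify_disagreement(member, pos, TRUTH[pos], context) \
        == "deletion"


def test_classify_garbled_region_unknown():
    member = TRUTH[:5] + "TTT" + TRUTH[8:]
    assert member[5] != TRUTH[5]
    context = TRUTH[6:11]
    assert classify_disagreement(member, 5, TRUTH[5], context) == "unknown"


# ---------------------------------------------------------------------------
# resync

def test_resync_after_deletion_burst():
    """A 2-base deletion burst re-anchors the pointer 2 left of the
    naive offset; verified by exhaustive offset search."""
    truth = random_seq(np.random.default_rng(2), 110)
    member = truth[:40] + truth[42:]  # 2-base deletion burst
    params = ConsensusParams()
    built = truth[:60]
    suffix = built[-params.resync_suffix_len:]
    hint = 60  # naive offset had the member tracked no deletions
    got = resync(member, hint, suffix, params)
    # exhaustive search for the true suffix location
    expected = member.index(suffix) + len(suffix)
    assert got == expected == hint - 2


def test_resync_failure_keeps_label():
    params = ConsensusParams()
    assert resync("ACGT" * 20, 40, "TTTTTT", params) is None


def test_resync_nearest_match_wins():
    params = ConsensusParams(resync_window=6)
    window = "AAAAAA" + "CCGGTT" + "ACGTAC" + "CCGGTT" + "AAAAAA"
    # matches end at 12 and 24; hint 14 -> nearest end is 12
    assert resync(window, 14, "CCGGTT", params) == 12


# ---------------------------------------------------------------------------
# consensus

def test_consensus_of_identical_copies_any_size():
    truth = random_seq(np.random.default_rng(3), 110)
    for size in (1, 2, 5, 9):
        res = consensus_sequence([truth] * size)
        assert res.sequence == truth
        assert res.margins == [size] * 110
        assert res.members_used == size
        assert not res.padded


def test_consensus_recovers_single_deletion():
    truth = random_seq(np.random.default_rng(4), 110)
    damaged = truth[:50] + truth[51:]
    res = consensus_sequence([truth, truth, damaged])
    assert res.sequence == truth
    assert res.members_used == 3


def test_consensus_length_always_expected(params):
    rng = np.random.default_rng(5)
    profile = ErrorProfile()
    for k in range(10):
        truth = random_seq(rng, 110)
        copies = [apply_channel(truth, profile, rng).sequence
                  for _ in range(6)]
        res = consensus_sequence(copies)
        assert len(res.sequence) == 110


@pytest.fixture(scope="module")
def reconstruction_rates():
    """Exact-reconstruction rate per cluster size for both variants,
    on homopolymer-free truths (the codec's hp-free mode emits none)."""
    rng = np.random.default_rng(6)
    profile = ErrorProfile()
    sizes = (3, 5, 10, 20)
    n_truths = 60
    rates = {"oos": {}, "drop": {}}
    truths = []
    while len(truths) < n_truths:
        t = random_seq(rng, 110)
        if not find_runs(t, 5):
            truths.append(t)
    for size in sizes:
        ok = {"oos": 0, "drop": 0}
        for ti, t in enumerate(truths):
            copies = [apply_channel(t, profile, rng).sequence
                      for _ in range(size)]
            for name, flag in (("oos", False), ("drop", True)):
                if consensus_sequence(copies,
                                      drop_on_desync=flag).sequence == t:
                    ok[name] += 1
        for name in ok:
            rates[name][size] = ok[name] / n_truths
    return rates


def test_reconstruction_monotone_in_cluster_size(reconstruction_rates):
    r = reconstruction_rates["oos"]
    assert r[3] <= r[5] <= r[10] <= r[20]


def test_out_of_sync_beats_drop_variant(reconstruction_rates):
    oos, drop = (reconstruction_rates[k] for k in ("oos", "drop"))
    assert all(oos[s] >= drop[s] for s in oos)
    assert any(oos[s] > drop[s] for s in oos)


# ---------------------------------------------------------------------------
# clustering

def test_single_payload_copies_form_one_cluster(params):
    truth = random_seq(np.random.default_rng(7), 110)
    copies = [truth, truth[:30] + "T" + truth[31:],
              truth[:80] + truth[81:]]
    clusters = cluster_observations([_obs(c) for c in copies],
                                    cluster_radius=15, strategy="distance")
    assert len(clusters) == 1
    assert len(clusters[0].members) == 3


def test_distant_payloads_split(params):
    rng = np.random.default_rng(8)
    a, b = random_seq(rng, 110), random_seq(rng, 110)
    clusters = cluster_observations([_obs(a), _obs(b)],
                                    cluster_radius=15, strategy="distance")
    assert len(clusters) == 2


def test_cluster_purity_on_simulated_file(params, small_encoded):
    """At ~30x coverage and default noise, >= 99% of clusters hold
    copies of a single true payload."""
    from porestore.assembly import build_reference_products, plan_gibson
    from porestore.extract import extract_payloads
    from porestore.simulate import simulate_run
    data, enc = small_encoded
    truth_of = {}
    pool = [o.sequence for o in enc.oligos]
    payload_owner = {o.payload: o.index for o in enc.oligos}
    plan = plan_gibson([6], seed=9)
    import math
    n_reads = math.ceil(30 * enc.n_oligos / 6)
    refs = build_reference_products(plan, pool, n_reads, rng_seed=10)
    reads = simulate_run(refs, n_reads, ErrorProfile(), seed=11)
    obs = [o for r in reads
           for o in extract_payloads(r, params.file_id_front,
                                     params.file_id_back)]
    # ground truth per observation: nearest payload by edit distance
    import edlib
    def owner(window):
        best, bi = 1e9, None
        for p, i in payload_owner.items():
            d = edlib.align(window, p, k=30)["editDistance"]
            if 0 <= d < best:
                best, bi = d, i
        return bi
    clusters = cluster_observations(obs, params=params,
                                    n_payloads=enc.n_oligos)
    pure = 0
    for c in clusters:
        owners = {owner(m.window) for m in c.members}
        pure += len(owners) == 1
    assert pure / len(clusters) >= 0.99
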