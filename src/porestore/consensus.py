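"""Trace reconstruction: cluster payload observations and rebuild each
original 110-nt payload by pointer/plurality consensus.

Each cluster holds noisy copies of one payload.  A per-member pointer
sweeps left to right; at every step the next consensus base is elected
by plurality over the in-sync members' pointed bases.  Members that
disagree are diagnosed by comparing their local context against the
lookahead context voted by the agreeing members:

    substitution -> pointer advances 1 (bad base consumed)
    insertion    -> pointer advances 2 (skips the inserted base)
    deletion     -> pointer stays (the member is missing this base)

When the disagreement cannot be classified the member is labeled
out-of-sync rather than dropped.  It sits out ``oos_ignore_steps``
steps, after which the last ``resync_suffix_len`` consensus bases are
searched for within a +/- ``resync_window`` neighbourhood of the
member's expected offset; an exact match re-anchors the pointer and
clears the label.  Re-using these members instead of discarding them
is what lets decoding succeed at lower coverage; the discard behaviour
remains available as ``drop_on_desync`` for comparison.

Clustering is index-first: windows whose inner-coded index prefix
decodes cleanly are bucketed by index and verified against a bucket
medoid within ``cluster_radius`` edits; the remainder is greedily
star-clustered by edit distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import edlib

from .codec import FileParams, decode_index_prefix
from .extract import PayloadObservation

__all__ = [
    "Cluster",
    "ConsensusParams",
    "ConsensusResult",
    "cluster_observations",
    "plurality_vote",
    "classify_disagreement",
    "resync",
    "consensus_sequence",
]

_BASE_ORDER = "ACGT"  # fixed tie-break order


@dataclass
class Cluster:
    members: List[PayloadObservation]
    provisional_index: Optional[int] = None

    def windows(self) -> List[str]:
        return [m.window for m in self.members]


@dataclass(frozen=True)
class ConsensusParams:
    context_len: int = 5
    oos_ignore_steps: int = 8
    resync_suffix_len: int = 6
    resync_window: int = 6
    expected_len: int = 110

    def __post_init__(self):
        if self.resync_suffix_len > self.oos_ignore_steps + self.context_len:
            raise ValueError(
                "resync suffix longer than the skipped region it anchors")


@dataclass
class ConsensusResult:
    sequence: str
    margins: List[int]
    members_used: int
    padded: bool = False


def _edit_distance(a: str, b: str, k: int = -1) -> int:
    d = edlib.align(a, b, k=k)["editDistance"]
    return d if d >= 0 else k + 1


# ---------------------------------------------------------------------------
# clustering

_ATTACH_K = 16  # k-mer width for leftover-to-cluster attachment


def cluster_observations(observations: Sequence[PayloadObservation],
                         cluster_radius: int = 15,
                         strategy: str = "index_first",
                         params: Optional[FileParams] = None,
                         attach_remainder: bool = True,
                         n_payloads: Optional[int] = None,
                         min_bucket_size: int = 3
                         ) -> List[Cluster]:
    """Group payload observations into per-payload clusters.

    ``index_first`` (needs codec ``params``): bucket windows by their
    decoded index prefix.  An errored prefix still decodes to *some*
    index, so only buckets that look real — in range (when
    ``n_payloads`` is known) and with at least ``min_bucket_size``
    members — are kept, each verified against a medoid seed to eject
    impostors whose index merely aliased under errors.  Everything
    else is attached to the verified cluster sharing an exact
    ``_ATTACH_K``-mer (within ``cluster_radius`` edits of its seed)
    and the remainder is greedily star-clustered.  ``distance`` skips
    the index stage entirely.
    """
    if not observations:
        raise ValueError("no observations to cluster")
    clusters: List[Cluster] = []
    seeds: List[str] = []
    leftovers: List[PayloadObservation] = []
    if strategy == "index_first":
        if params is None:
            raise ValueError("index_first clustering needs codec params")
        buckets: dict = {}
        for obs in observations:
            try:
                idx = decode_index_prefix(obs.window, params)
            except ValueError:
                leftovers.append(obs)
                continue
            if n_payloads is not None and idx >= n_payloads:
                leftovers.append(obs)
                continue
            buckets.setdefault(idx, []).append(obs)
        for idx in sorted(buckets):
            group = buckets[idx]
            if len(group) < min_bucket_size:
                leftovers.extend(group)
                continue
            seed = _medoid_window(group)
            members, rejected = [], []
            for obs in group:
                if _edit_distance(obs.window, seed,
                                  k=cluster_radius) <= cluster_radius:
                    members.append(obs)
                else:
                    rejected.append(obs)
            if members:
                # a quick consensus sits ~one channel-noise radius from
                # every true copy (the medoid sits ~two), so it is the
                # better representative for attachment
                rep = consensus_sequence(
                    [m.window for m in members[:12]]).sequence
                clusters.append(Cluster(members=members,
                                        provisional_index=idx))
                seeds.append(rep)
                leftovers.extend(rejected)
            else:
                leftovers.extend(group)
    elif strategy == "distance":
        leftovers = list(observations)
    else:
        raise ValueError(f"unknown clustering strategy {strategy!r}")

    if attach_remainder and clusters and leftovers:
        leftovers = _attach_to_clusters(leftovers, clusters, seeds,
                                        cluster_radius)

    # greedy star clustering of the remainder
    remaining = leftovers
    while remaining:
        seed_obs = remaining[0]
        members = [seed_obs]
        rest = []
        for obs in remaining[1:]:
            if _edit_distance(obs.window, seed_obs.window,
                              k=cluster_radius) <= cluster_radius:
                members.append(obs)
            else:
                rest.append(obs)
        clusters.append(Cluster(members=members, provisional_index=None))
        remaining = rest
    return clusters


def _attach_to_clusters(leftovers, clusters, seeds, cluster_radius):
    """Assign leftover windows to verified clusters via shared k-mers.

    Candidate clusters are those whose seed shares an exact k-mer with
    the window (errors leave long clean stretches, so true copies
    almost always share one); the nearest seed within
    ``cluster_radius`` edits wins.
    """
    kmer_index: dict = {}
    for ci, seed in enumerate(seeds):
        for p in range(len(seed) - _ATTACH_K + 1):
            kmer_index.setdefault(seed[p:p + _ATTACH_K], set()).add(ci)
    unassigned = []
    for obs in leftovers:
        w = obs.window
        votes = Counter()
        for p in range(len(w) - _ATTACH_K + 1):
            for ci in kmer_index.get(w[p:p + _ATTACH_K], ()):
                votes[ci] += 1
        best_ci, best_d = None, None
        for ci, _ in votes.most_common(3):
            d = _edit_distance(w, seeds[ci], k=cluster_radius)
            if d <= cluster_radius and (best_d is None or d < best_d):
                best_ci, best_d = ci, d
        if best_ci is not None:
            clusters[best_ci].members.append(obs)
        else:
            unassigned.append(obs)
    return unassigned


def _medoid_window(group: Sequence[PayloadObservation],
                   sample: int = 5) -> str:
    """Window minimizing total edit distance to a small sample."""
    if len(group) == 1:
        return group[0].window
    probes = [g.window for g in group[:sample]]
    best, best_cost = None, None
    for g in group[: 3 * sample]:
        cost = sum(_edit_distance(g.window, p) for p in probes)
        if best_cost is None or cost < best_cost:
            best, best_cost = g.window, cost
    return best


# ---------------------------------------------------------------------------
# consensus building blocks

def plurality_vote(symbols: Sequence[str]):
    """Most frequent base; ties broken A<C<G<T.  Margin is the lead of
    the winner over the runner-up (the full count when unopposed)."""
    if not symbols:
        raise ValueError("empty vote")
    counts = Counter(symbols)
    ranked = sorted(counts.items(),
                    key=lambda kv: (-kv[1], _BASE_ORDER.index(kv[0])))
    top_base, top_count = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0
    return top_base, top_count - runner


def _context_matches(window: str, start: int, context: str) -> bool:
    """The member's bases from ``start`` agree with the expected
    lookahead context (over the overlap; empty overlap fails)."""
    if not context or start >= len(window):
        return False
    seg = window[start:start + len(context)]
    return seg == context[:len(seg)]


def classify_disagreement(member_window: str, pointer: int,
                          voted_base: str, context: str) -> str:
    """Diagnose why ``member_window[pointer]`` disagrees with the vote.

    ``context`` is the expected consensus continuation *after* the
    voted base (lookahead voted by the agreeing members).  Returns one
    of ``substitution``, ``insertion``, ``deletion``, ``unknown``.
    """
    if pointer >= len(member_window):
        return "unknown"
    if _context_matches(member_window, pointer + 1, context):
        return "substitution"
    if (pointer + 1 < len(member_window)
            and member_window[pointer + 1] == voted_base
            and _context_matches(member_window, pointer + 2, context)):
        return "insertion"
    if _context_matches(member_window, pointer, context):
        return "deletion"
    return "unknown"


_POINTER_ADVANCE = {"substitution": 1, "insertion": 2, "deletion": 0}


def resync(member_window: str, pointer_hint: int, built_suffix: str,
           params: ConsensusParams) -> Optional[int]:
    """Re-anchor an out-of-sync member.

    Searches ``member_window`` for an exact occurrence of
    ``built_suffix`` whose end lies within ``pointer_hint`` +/-
    ``resync_window``; returns the offset just past the nearest match
    (ties -> leftmost), or ``None``.
    """
    if not built_suffix:
        return None
    lo = max(0, pointer_hint - params.resync_window - len(built_suffix))
    hi = min(len(member_window),
             pointer_hint + params.resync_window)
    candidates = []
    start = lo
    while True:
        m = member_window.find(built_suffix, start, hi)
        if m == -1:
            break
        end = m + len(built_suffix)
        if abs(end - pointer_hint) <= params.resync_window:
            candidates.append(end)
        start = m + 1
    if not candidates:
        return None
    return min(candidates, key=lambda e: (abs(e - pointer_hint), e))


# ---------------------------------------------------------------------------
# full consensus

_SYNC, _OOS, _DROPPED = 0, 1, 2


def consensus_sequence(cluster, params: ConsensusParams = ConsensusParams(),
                       drop_on_desync: bool = False) -> ConsensusResult:
    """Reconstruct the cluster's payload.

    ``cluster`` is a :class:`Cluster` or a sequence of window strings.
    With ``drop_on_desync`` the unclassifiable members are discarded
    (the older algorithm) instead of parked and re-anchored.
    """
    if isinstance(cluster, Cluster):
        windows = cluster.windows()
    else:
        windows = list(cluster)
    if not windows:
        raise ValueError("empty cluster")
    n = len(windows)
    ptr = [0] * n
    state = [_SYNC] * n
    oos_at = [0] * n       # built length when the member desynced
    oos_ptr = [0] * n      # pointer at that moment
    next_try = [0] * n
    used = [False] * n
    built: List[str] = []
    margins: List[int] = []
    padded = False

    while len(built) < params.expected_len:
        pos = len(built)
        # periodic resync offers
        for i in range(n):
            if state[i] != _OOS or pos < next_try[i]:
                continue
            if pos < params.resync_suffix_len:
                continue
            suffix = "".join(built[-params.resync_suffix_len:])
            hint = oos_ptr[i] + (pos - oos_at[i])
            new_ptr = resync(windows[i], hint, suffix, params)
            if new_ptr is not None and new_ptr >= ptr[i]:
                ptr[i] = new_ptr
                state[i] = _SYNC
            else:
                next_try[i] = pos + params.oos_ignore_steps
        voters = [i for i in range(n)
                  if state[i] == _SYNC and ptr[i] < len(windows[i])]
        if not voters:
            # exhausted: pad from whatever members still have bases at
            # their expected offsets
            fallback = []
            for i in range(n):
                if state[i] == _DROPPED:
                    continue
                p = ptr[i] if state[i] == _SYNC \
                    else oos_ptr[i] + (pos - oos_at[i])
                if 0 <= p < len(windows[i]):
                    fallback.append(windows[i][p])
                    ptr[i] = p + 1
                    state[i] = _SYNC
            if fallback:
                base, margin = plurality_vote(fallback)
            else:
                base, margin = "A", 0
            built.append(base)
            margins.append(margin)
            padded = True
            continue
        symbols = [windows[i][ptr[i]] for i in voters]
        base, margin = plurality_vote(symbols)
        built.append(base)
        margins.append(margin)
        agree = [i for i in voters if windows[i][ptr[i]] == base]
        context = _vote_context(windows, ptr, agree, params.context_len)
        for i in voters:
            used[i] = True
            if windows[i][ptr[i]] == base:
                ptr[i] += 1
                continue
            cls = classify_disagreement(windows[i], ptr[i], base, context)
            if cls == "unknown":
                if drop_on_desync:
                    state[i] = _DROPPED
                else:
                    state[i] = _OOS
                    oos_at[i] = len(built)
                    oos_ptr[i] = ptr[i]
                    next_try[i] = len(built) + params.oos_ignore_steps
            else:
                ptr[i] += _POINTER_ADVANCE[cls]
    return ConsensusResult(sequence="".join(built), margins=margins,
                           members_used=sum(used), padded=padded)


def _vote_context(windows, ptr, agree, context_len: int) -> str:
    """Lookahead context voted over the members that agreed with the
    current plurality (their bases after the pointed one)."""
    out = []
    for d in range(1, context_len + 1):
        symbols = [windows[i][ptr[i] + d] for i in agree
                   if ptr[i] + d < len(windows[i])]
        if not symbols:
            break
        out.append(plurality_vote(symbols)[0])
    return "".join(out)
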