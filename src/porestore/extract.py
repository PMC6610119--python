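"""Payload recovery from concatemer reads.

Each assembled amplicon carries many 150-nt units, so a single read
holds many payload copies separated by file-ID anchors and overhangs.
Payloads are recovered by approximate (edit-distance) search for the
20-nt front and back file IDs and cutting the window between each
front hit and its nearest downstream back hit.

Anchor search runs a banded-free semi-global dynamic program
(Sellers algorithm) over the read: the last DP row gives, for every
read position, the minimum edit distance of the anchor to a substring
ending there.  Candidate ends below ``max_edits`` are grouped into
occurrences (lowest edit count, then leftmost, wins) and hit start
coordinates are resolved by a reverse DP.  All coordinates are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .dna import revcomp, seq_to_indices

__all__ = [
    "AnchorHit",
    "PayloadObservation",
    "find_anchors",
    "extract_payloads",
    "alignments_per_read",
]


@dataclass(frozen=True)
class AnchorHit:
    start: int
    end: int  # exclusive
    edits: int
    strand: str  # '+' or '-'
    anchor_role: str = ""


@dataclass(frozen=True)
class PayloadObservation:
    read_id: str
    window: str
    position_in_read: int
    source_strand: str


def _end_scores(read_idx: np.ndarray, anchor_idx: np.ndarray) -> np.ndarray:
    """Semi-global DP: score[j] = min edits of anchor vs a substring of
    the read ending at position j (exclusive)."""
    n = read_idx.size
    j = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i, a in enumerate(anchor_idx, start=1):
        body = np.minimum(prev[:-1] + (read_idx != a), prev[1:] + 1)
        arr = np.concatenate(([np.int32(i)], body))
        prev = np.minimum.accumulate(arr - j) + j
    return prev


def _resolve_start(read_idx: np.ndarray, anchor_idx: np.ndarray,
                   end: int, max_edits: int) -> int:
    """Find the start of the best occurrence ending at ``end`` via a
    reverse DP over the preceding window."""
    lo = max(0, end - anchor_idx.size - max_edits)
    seg = read_idx[lo:end][::-1]
    rev_anchor = anchor_idx[::-1]
    scores = _end_scores(seg, rev_anchor)
    # scores[m] = edits vs the last m bases of the segment; the best
    # (then longest, i.e. leftmost start) wins
    best = int(scores.min())
    m = int(np.flatnonzero(scores == best)[-1])
    return end - m


def find_anchors(read: str, anchor: str, max_edits: int,
                 anchor_role: str = "", search_rc: bool = True
                 ) -> List[AnchorHit]:
    """All non-overlapping occurrences of ``anchor`` in ``read`` within
    ``max_edits`` edits, on both strands."""
    if len(anchor) < 10:
        raise ValueError("anchors shorter than 10 nt are unreliable")
    read_idx = seq_to_indices(read)
    candidates = []
    strands = [("+", anchor)]
    if search_rc:
        strands.append(("-", revcomp(anchor)))
    for strand, a in strands:
        a_idx = seq_to_indices(a)
        scores = _end_scores(read_idx, a_idx)
        ends = np.flatnonzero(scores <= max_edits)
        gap = 2 * max_edits + 2
        group: list = []
        for e in list(ends) + [None]:
            if e is not None and (not group or e - group[-1] <= gap):
                group.append(e)
                continue
            if group:
                g_scores = scores[group]
                best = g_scores.min()
                end = int(group[int(np.flatnonzero(g_scores == best)[0])])
                start = _resolve_start(read_idx, a_idx, end, max_edits)
                candidates.append(AnchorHit(
                    start=start, end=end, edits=int(best), strand=strand,
                    anchor_role=anchor_role))
            group = [e] if e is not None else []
    # overlap resolution: lowest edits, then leftmost
    candidates.sort(key=lambda h: (h.edits, h.start, h.strand))
    chosen: List[AnchorHit] = []
    for h in candidates:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen


def _extract_oriented(seq: str, read_id: str, front_id: str, back_id: str,
                      payload_len: int, max_edits: int, indel_slack: int,
                      strand: str) -> List[PayloadObservation]:
    fronts = find_anchors(seq, front_id, max_edits,
                          anchor_role="front", search_rc=False)
    backs = find_anchors(seq, back_id, max_edits,
                         anchor_role="back", search_rc=False)
    obs = []
    bi = 0
    last_end = -1
    ordinal = 0
    for f in fronts:
        if f.start < last_end:
            continue
        while bi < len(backs) and backs[bi].start < f.end:
            bi += 1
        if bi == len(backs):
            break
        b = backs[bi]
        window = seq[f.end:b.start]
        if abs(len(window) - payload_len) <= indel_slack:
            obs.append(PayloadObservation(
                read_id=read_id, window=window, position_in_read=ordinal,
                source_strand=strand))
            ordinal += 1
            last_end = b.end
            bi += 1
    return obs


def extract_payloads(read, front_id: str, back_id: str,
                     payload_len: int = 110, max_edits: int = 4,
                     indel_slack: int = 15) -> List[PayloadObservation]:
    """Cut payload windows out of one read.

    ``read`` is a :class:`~porestore.simulate.ReadRecord` or a plain
    (read_id, sequence) pair / string.  Both orientations are tried and
    the one yielding more observations is kept (a read reports a single
    molecule, so its payloads share one orientation); windows from the
    reverse strand are returned in payload orientation.
    """
    if hasattr(read, "sequence"):
        read_id, seq = read.read_id, read.sequence
    elif isinstance(read, tuple):
        read_id, seq = read
    else:
        read_id, seq = "read", read
    fwd = _extract_oriented(seq, read_id, front_id, back_id,
                            payload_len, max_edits, indel_slack, "+")
    rev = _extract_oriented(revcomp(seq), read_id, front_id, back_id,
                            payload_len, max_edits, indel_slack, "-")
    return rev if len(rev) > len(fwd) else fwd


def alignments_per_read(observations: Sequence[PayloadObservation],
                        reads: Sequence) -> dict:
    """Mean payload observations per read plus a per-read histogram."""
    n_reads = len(reads)
    counts: dict = {}
    for o in observations:
        counts[o.read_id] = counts.get(o.read_id, 0) + 1
    per_read = [counts.get(getattr(r, "read_id", r), 0) for r in reads]
    histogram: dict = {}
    for c in per_read:
        histogram[c] = histogram.get(c, 0) + 1
    mean = len(observations) / n_reads if n_reads else 0.0
    return {"mean": mean, "histogram": histogram, "n_reads": n_reads,
            "n_observations": len(observations)}
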