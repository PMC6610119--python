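"""Sequencing-run statistics: alignment-based error breakdown, Phred
summaries, payload coverage, and the sequence-until stopping rule.

Observed payload windows are globally aligned to their reference
payloads (unit-cost edit distance); insertion, deletion and
substitution events are aggregated per reference base to give the
total per-base error rate and the observed substitution matrix.
Coverage is counted as payload observations per reference payload,
including payloads never observed; the module also reports what the
same read count would have yielded with one payload per read (the
no-assembly equivalent) and how many reads a target coverage would
need.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import edlib
import numpy as np

from .dna import BASES
from .simulate import error_prob_from_phred, phred_from_error_prob

__all__ = [
    "EditScript",
    "ErrorBreakdown",
    "CoverageStats",
    "align_observation",
    "profile_errors",
    "phred_summary",
    "coverage_stats",
    "sequence_until",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class EditScript:
    matches: int
    substitutions: int
    insertions: int
    deletions: int
    distance: int
    cigar: str

    # per-reference-base event counts, keyed by base then op
    per_base: Dict[str, Dict[str, int]] = field(default_factory=dict)
    sub_pairs: List[tuple] = field(default_factory=list)  # (ref, obs)


def align_observation(window: str, reference_payload: str) -> EditScript:
    """Global (NW) alignment of an observation to its reference.

    Substitution/indel events are attributed to reference bases while
    walking the CIGAR; an insertion is charged to the next reference
    base (or the last one at the end).
    """
    if not window or not reference_payload:
        raise ValueError("empty sequence")
    res = edlib.align(window, reference_payload, mode="NW", task="path")
    cigar = res["cigar"]
    per_base = {b: {"substitution": 0, "insertion": 0, "deletion": 0}
                for b in BASES}
    sub_pairs = []
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    qi = ri = 0
    for num, op in _CIGAR_RE.findall(cigar):
        num = int(num)
        counts[op] += num
        if op == "=":
            qi += num
            ri += num
        elif op == "X":
            for _ in range(num):
                per_base[reference_payload[ri]]["substitution"] += 1
                sub_pairs.append((reference_payload[ri], window[qi]))
                qi += 1
                ri += 1
        elif op == "D":  # reference base absent from the observation
            for _ in range(num):
                per_base[reference_payload[ri]]["deletion"] += 1
                ri += 1
        elif op == "I":  # extra observed base
            anchor = reference_payload[min(ri, len(reference_payload) - 1)]
            per_base[anchor]["insertion"] += num
            qi += num
    return EditScript(
        matches=counts["="], substitutions=counts["X"],
        insertions=counts["I"], deletions=counts["D"],
        distance=res["editDistance"], cigar=cigar,
        per_base=per_base, sub_pairs=sub_pairs)


@dataclass
class ErrorBreakdown:
    total_error_rate: float
    sub_rate: float
    ins_rate: float
    del_rate: float
    per_base_rates: Dict[str, Dict[str, float]]
    sub_matrix_observed: np.ndarray
    n_aligned_bases: int
    n_observations: int
    n_unaligned: int


def profile_errors(observations: Sequence, references,
                   index_fn: Optional[Callable] = None,
                   max_dist_fraction: float = 0.3) -> ErrorBreakdown:
    """Aggregate alignment error statistics over observations.

    ``references`` maps index -> payload string.  ``index_fn`` assigns
    an observation to a reference index (e.g. decoding its embedded
    index); when it is absent or fails, the best reference by edit
    distance is used.  Observations farther than
    ``max_dist_fraction * len(ref)`` from every reference are excluded
    from the rates and counted as unaligned.
    """
    refs = dict(references) if not hasattr(references, "items") \
        else dict(references.items())
    event_counts = {b: {"substitution": 0, "insertion": 0, "deletion": 0}
                    for b in BASES}
    sub_counts = np.zeros((4, 4), dtype=int)
    base_counts = {b: 0 for b in BASES}
    n_sub = n_ins = n_del = n_bases = 0
    n_unaligned = 0
    for obs in observations:
        window = obs.window if hasattr(obs, "window") else obs
        ref = None
        if index_fn is not None:
            idx = index_fn(obs)
            if idx is not None and idx in refs:
                ref = refs[idx]
                if edlib.align(window, ref)["editDistance"] \
                        > max_dist_fraction * len(ref):
                    ref = None
        if ref is None:
            best_d = None
            for cand in refs.values():
                d = edlib.align(window, cand,
                                k=int(max_dist_fraction * len(cand)))
                d = d["editDistance"]
                if d >= 0 and (best_d is None or d < best_d):
                    best_d, ref = d, cand
            if ref is None:
                n_unaligned += 1
                continue
        script = align_observation(window, ref)
        n_sub += script.substitutions
        n_ins += script.insertions
        n_del += script.deletions
        n_bases += len(ref)
        for b in BASES:
            base_counts[b] += ref.count(b)
            for op in event_counts[b]:
                event_counts[b][op] += script.per_base[b][op]
        for rb, ob in script.sub_pairs:
            sub_counts[BASES.index(rb), BASES.index(ob)] += 1
    per_base_rates = {
        b: {op: (event_counts[b][op] / base_counts[b]
                 if base_counts[b] else 0.0)
            for op in event_counts[b]}
        for b in BASES}
    total = (n_sub + n_ins + n_del) / n_bases if n_bases else 0.0
    return ErrorBreakdown(
        total_error_rate=total,
        sub_rate=n_sub / n_bases if n_bases else 0.0,
        ins_rate=n_ins / n_bases if n_bases else 0.0,
        del_rate=n_del / n_bases if n_bases else 0.0,
        per_base_rates=per_base_rates,
        sub_matrix_observed=sub_counts,
        n_aligned_bases=n_bases,
        n_observations=len(observations),
        n_unaligned=n_unaligned)


def phred_summary(reads: Sequence) -> dict:
    """Per-read mean quality (averaged on the probability scale, the
    ONT convention) and the implied overall error probability."""
    if not reads:
        raise ValueError("no reads")
    per_read_q = []
    all_p_sum = 0.0
    n_bases = 0
    for r in reads:
        quals = np.asarray(r.qualities, dtype=float)
        if quals.size == 0:
            continue
        p = np.mean([error_prob_from_phred(q) for q in quals])
        per_read_q.append(phred_from_error_prob(p))
        all_p_sum += p * quals.size
        n_bases += quals.size
    if n_bases == 0:
        raise ValueError("reads carry no qualities")
    overall_p = all_p_sum / n_bases
    return {
        "per_read_q": per_read_q,
        "mean_q": phred_from_error_prob(overall_p),
        "implied_error_prob": overall_p,
    }


def run_deletion_incidence(reads: Sequence, reference: str,
                           run_start: int, run_len: int,
                           flank: int = 8) -> dict:
    """Fraction of reads whose homopolymer run lost at least one base.

    The run locus is located in each read by exact match of its unique
    ``flank``-nt flanking contexts (run-length calling); reads whose
    flanks are themselves corrupted are not interpretable at this
    locus and are excluded from the denominator.  A read counts as
    deleted when the called run is shorter than the reference run;
    substitutions inside the run do not shorten it and insertions
    lengthen it, so neither is mistaken for a deletion.

    A deletion co-occurring with an insertion in the same segment
    restores the length and is invisible to the raw count.  With
    a = P(called short) and b = P(called long) this censoring obeys
    a = p_del (1 - p_ins) and b = p_ins (1 - p_del); solving the pair
    gives ``fraction_deleted_corrected``, the incidence corrected for
    insertion masking using observed quantities only.
    """
    left = reference[max(0, run_start - flank):run_start]
    right = reference[run_start + run_len:run_start + run_len + flank]
    if not left or not right:
        raise ValueError("run too close to the reference edge")
    n_called = n_short = n_long = 0
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        i = seq.find(left)
        if i == -1 or seq.find(left, i + 1) != -1:
            continue
        j = seq.find(right, i + len(left))
        if j == -1 or seq.find(right, j + 1) != -1:
            continue
        called = j - (i + len(left))
        if called > run_len + flank:  # implausible span; skip
            continue
        n_called += 1
        if called < run_len:
            n_short += 1
        elif called > run_len:
            n_long += 1
    if n_called == 0:
        return {"fraction_deleted": 0.0, "fraction_deleted_corrected": 0.0,
                "n_called": 0, "n_reads": len(reads)}
    a = n_short / n_called
    b = n_long / n_called
    # smaller root of m^2 + (a + b - 1) m + a b = 0, with m = p_del p_ins
    disc = (1.0 - a - b) ** 2 - 4.0 * a * b
    m = ((1.0 - a - b) - math.sqrt(max(disc, 0.0))) / 2.0 if b > 0 else 0.0
    return {"fraction_deleted": a,
            "fraction_deleted_corrected": min(1.0, a + m),
            "n_called": n_called, "n_reads": len(reads)}


@dataclass
class CoverageStats:
    per_payload_depth: Dict[int, int]
    mean_depth: float
    min_depth: int
    n_payloads: int
    n_reads: Optional[int] = None
    no_assembly_coverage: Optional[float] = None

    @staticmethod
    def reads_needed(target_depth: float, n_payloads: int,
                     payloads_per_read: float = 1.0) -> int:
        return math.ceil(target_depth * n_payloads / payloads_per_read)


def coverage_stats(assignments: Iterable[int], n_payloads: int,
                   n_reads: Optional[int] = None) -> CoverageStats:
    """Depth per reference payload from cluster/index assignments.

    Unobserved payloads count as zero depth; ``no_assembly_coverage``
    is the coverage the same read count would give at one payload per
    read.
    """
    if n_payloads < 1:
        raise ValueError("n_payloads must be >= 1")
    depth = {i: 0 for i in range(n_payloads)}
    total = 0
    for a in assignments:
        total += 1
        if a in depth:
            depth[a] += 1
    return CoverageStats(
        per_payload_depth=depth,
        mean_depth=total / n_payloads,
        min_depth=min(depth.values()),
        n_payloads=n_payloads,
        n_reads=n_reads,
        no_assembly_coverage=(n_reads / n_payloads
                              if n_reads is not None else None))


def sequence_until(batches: Iterable[Sequence], n_payloads: int,
                   index_fn: Callable, decode_fn: Callable,
                   min_depth: int = 3, fraction: float = 0.95) -> dict:
    """Consume observation batches until decoding succeeds.

    After each batch the per-payload depth estimate is updated from
    ``index_fn`` (observation -> payload index or None).  Once the
    fraction of payload indices at depth >= ``min_depth`` exceeds
    ``fraction``, ``decode_fn(observations)`` is attempted; it returns
    decoded bytes or None.  Stops at the first success; an exhausted
    stream is reported, not raised.
    """
    depth = np.zeros(n_payloads, dtype=int)
    observations: List = []
    n_batches = 0
    for batch in batches:
        n_batches += 1
        for obs in batch:
            observations.append(obs)
            idx = index_fn(obs)
            if idx is not None and 0 <= idx < n_payloads:
                depth[idx] += 1
        if (depth >= min_depth).mean() >= fraction:
            data = decode_fn(observations)
            if data is not None:
                return {"stop_batch": n_batches, "success": True,
                        "n_observations": len(observations),
                        "decoded": data}
    data = decode_fn(observations) if observations else None
    return {"stop_batch": n_batches, "success": data is not None,
            "n_observations": len(observations), "decoded": data}
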