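"""Nanopore-like read simulation for assembled storage amplicons.

The error channel applies independent per-base substitutions (with a
purine<->purine / pyrimidine<->pyrimidine transition bias), insertions
and deletions at configurable rates, plus a run-level homopolymer
model: every maximal run of identical bases of length >= ``hp_min_len``
independently loses one base with probability ``hp_del_prob``,
emulating the systematic run-length under-calling of nanopore
basecalls.  Inside such runs the i.i.d. deletion process is suppressed
so that the run-level probability *is* the per-run deletion incidence;
substitutions and insertions still apply there.

Per-base Phred qualities are drawn as the read's realized error rate
converted to a Q score plus uniform jitter, so the per-read mean
quality tracks -10*log10(error fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .dna import BASES, find_runs, indices_to_seq, revcomp, seq_to_indices

__all__ = [
    "ErrorProfile",
    "ReadRecord",
    "error_prob_from_phred",
    "phred_from_error_prob",
    "default_sub_matrix",
    "apply_channel",
    "simulate_run",
    "homopolymer_stats",
    "write_fastq",
    "read_fastq",
]


def error_prob_from_phred(q: float) -> float:
    """Phred score -> error probability, p = 10^(-q/10)."""
    if q < 0:
        raise ValueError("Phred scores are non-negative")
    return 10.0 ** (-q / 10.0)


def phred_from_error_prob(p: float, cap: float = 60.0) -> float:
    if p <= 0:
        return cap
    return min(cap, -10.0 * math.log10(p))


def default_sub_matrix(transition_bias: float = 3.0) -> np.ndarray:
    """Row-stochastic conditional substitution matrix (zero diagonal).

    Transitions (A<->G, C<->T) are weighted ``transition_bias`` relative
    to each transversion, reflecting the observed purine<->purine and
    pyrimidine<->pyrimidine substitution excess.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    m = np.zeros((4, 4))
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            if i == j:
                continue
            m[i, j] = transition_bias if (a, b) in transitions else 1.0
    return m / m.sum(axis=1, keepdims=True)


@dataclass
class ErrorProfile:
    """Per-base channel rates and the homopolymer run-deletion model."""

    sub_rate: float = 0.03
    ins_rate: float = 0.0087
    del_rate: float = 0.03
    transition_bias: float = 3.0
    sub_matrix: Optional[np.ndarray] = None
    hp_min_len: int = 5
    hp_del_prob: float = 0.44
    quality_jitter: float = 3.0
    truncate_geom_p: float = 0.0  # 0 disables end truncation

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.sub_matrix is None:
            self.sub_matrix = default_sub_matrix(self.transition_bias)
        m = np.asarray(self.sub_matrix, dtype=float)
        if m.shape != (4, 4) or np.any(np.diag(m) != 0):
            raise ValueError("sub_matrix must be 4x4 with zero diagonal")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("sub_matrix rows must sum to 1")
        self.sub_matrix = m

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, hp_del_prob=0.0)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred, int
    truth_ref: Optional[str] = None

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.qualities) != len(self.sequence):
            raise ValueError("quality length mismatch")
        if self.qualities.size and (
                self.qualities.min() < 0 or self.qualities.max() > 60):
            raise ValueError("Phred scores must lie in [0, 60]")


def apply_channel(ref: str, profile: ErrorProfile,
                  rng: np.random.Generator,
                  read_id: str = "read", truth_ref: Optional[str] = None
                  ) -> ReadRecord:
    """Corrupt one reference sequence into a simulated read."""
    if not ref:
        raise ValueError("empty reference")
    base_idx = seq_to_indices(ref).copy()
    n = base_idx.size

    run_mask = np.zeros(n, dtype=bool)
    runs = find_runs(ref, profile.hp_min_len)
    for start, length in runs:
        run_mask[start:start + length] = True

    delete = np.zeros(n, dtype=bool)
    # run-level deletions: at most one per run, per read
    for start, length in runs:
        if rng.random() < profile.hp_del_prob:
            delete[start + rng.integers(length)] = True
    # i.i.d. stage (deletions suppressed inside long runs)
    u = rng.random(n)
    delete |= (u < profile.del_rate) & ~run_mask
    sub_sel = (u >= profile.del_rate) \
        & (u < profile.del_rate + profile.sub_rate) & ~delete
    sub_idx = np.flatnonzero(sub_sel)
    if sub_idx.size:
        cum = np.cumsum(profile.sub_matrix, axis=1)
        draws = rng.random(sub_idx.size)
        rows = cum[base_idx[sub_idx]]
        base_idx[sub_idx] = (draws[:, None] < rows).argmax(axis=1)

    keep = ~delete
    kept = base_idx[keep]
    gaps = rng.random(n + 1) < profile.ins_rate
    gap_idx = np.flatnonzero(gaps)
    kept_before = np.concatenate([[0], np.cumsum(keep)])
    ins_pos = kept_before[gap_idx]
    ins_bases = rng.integers(0, 4, gap_idx.size, dtype=np.uint8)
    out = np.insert(kept, ins_pos, ins_bases)

    if profile.truncate_geom_p > 0:
        drop = rng.geometric(profile.truncate_geom_p) - 1
        if drop > 0:
            out = out[:-drop] if drop < out.size else out[:1]

    n_errors = int(delete.sum()) + int(sub_sel.sum()) + int(gap_idx.size)
    p = n_errors / n if n else 0.0
    q_mean = phred_from_error_prob(max(p, 1e-6))
    jitter = rng.uniform(-profile.quality_jitter, profile.quality_jitter,
                         out.size)
    quals = np.clip(np.round(q_mean + jitter), 0, 60).astype(int)
    return ReadRecord(read_id=read_id, sequence=indices_to_seq(out),
                      qualities=quals, truth_ref=truth_ref)


def simulate_run(references: Sequence[str], n_reads: int,
                 profile: ErrorProfile, seed: int,
                 rc_prob: float = 0.5,
                 ref_ids: Optional[Sequence[str]] = None
                 ) -> List[ReadRecord]:
    """Simulate a sequencing run over the reference products.

    References are sampled uniformly per read; with probability
    ``rc_prob`` the read reports the reverse-complement strand.
    Deterministic for a fixed seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not references:
        raise ValueError("no references")
    if ref_ids is None:
        ref_ids = [f"ref{i}" for i in range(len(references))]
    rng = np.random.Generator(np.random.PCG64(seed))
    reads = []
    for i in range(n_reads):
        ri = int(rng.integers(len(references)))
        rec = apply_channel(references[ri], profile, rng,
                            read_id=f"read{i}", truth_ref=ref_ids[ri])
        if rng.random() < rc_prob:
            rec = ReadRecord(read_id=rec.read_id,
                             sequence=revcomp(rec.sequence),
                             qualities=rec.qualities[::-1],
                             truth_ref=rec.truth_ref)
        reads.append(rec)
    return reads


def homopolymer_stats(seqs: Iterable[str], min_len: int):
    """Summarize maximal homopolymer runs of length >= ``min_len``.

    Returns (fraction of sequences containing at least one such run,
    total run count, {run length: count} histogram).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n_seq = 0
    n_with = 0
    histogram: dict = {}
    total_runs = 0
    for s in seqs:
        n_seq += 1
        runs = find_runs(s, min_len)
        if runs:
            n_with += 1
        for _, length in runs:
            total_runs += 1
            histogram[length] = histogram.get(length, 0) + 1
    fraction = n_with / n_seq if n_seq else 0.0
    return fraction, total_runs, histogram


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)

def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(33 + int(q)) for q in r.qualities)
            comment = f" truth={r.truth_ref}" if r.truth_ref else ""
            fh.write(f"@{r.read_id}{comment}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> List[ReadRecord]:
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        truth = None
        if "truth=" in rec.description:
            truth = rec.description.split("truth=")[1].split()[0]
        out.append(ReadRecord(
            read_id=rec.id, sequence=str(rec.seq),
            qualities=np.array(
                rec.letter_annotations["phred_quality"], dtype=int),
            truth_ref=truth))
    return out
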