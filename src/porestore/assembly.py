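"""Gibson / OE-PCR assembly design for concatenated oligo readout.

Storage oligos are only 150 nt, far below the fragment sizes at which a
nanopore flowcell is efficient.  Concatenating many oligos into one
long amplicon — either by sequential Gibson assembly with orthogonal
30-nt overhangs, or by overlap-extension PCR of group-ID-tagged
subpools — multiplies the payload observations obtained per read.

This module generates candidate 30-nt overhangs under the standard
constraints (GC between 40% and 60%, no GGGG/CCCC), scores
intramolecular structure and pairwise cross-talk by longest
Watson-Crick complementary stretch, greedily prunes the candidate set
to an orthogonal subset, and plans tiered assemblies with exact
expected product lengths:

    L_0 = unit_len (150)
    L_t = m_t * L_{t-1} + (m_t + 1) * overhang_len

so a 6-fragment first tier is 6*150 + 7*30 = 1110 bp and a [6, 4]
two-tier assembly is 4*1110 + 5*30 = 4590 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .dna import gc_fraction, random_seq, revcomp

__all__ = [
    "Overhang",
    "AssemblyPlan",
    "OepcrPlan",
    "generate_overhang_candidates",
    "self_structure_score",
    "crosstalk_score",
    "select_orthogonal_subset",
    "plan_gibson",
    "plan_oepcr",
    "build_reference_products",
    "expected_product_len",
]

OVERHANG_LEN = 30
UNIT_LEN = 150


class PoolExhaustedError(Exception):
    """Not enough orthogonal overhangs (or oligos) for the request."""


@dataclass(frozen=True)
class Overhang:
    sequence: str
    gc_fraction: float
    self_score: int

    def __post_init__(self):
        if len(self.sequence) != OVERHANG_LEN:
            raise ValueError("overhangs are 30 nt")


@dataclass
class AssemblyPlan:
    """Tiered Gibson concatenation blueprint."""

    tiers: List[int]
    overhangs_per_tier: List[List[Overhang]]
    unit_len: int = UNIT_LEN
    overhang_len: int = OVERHANG_LEN
    expected_product_len: int = 0

    @property
    def fragments_per_product(self) -> int:
        n = 1
        for m in self.tiers:
            n *= m
        return n


@dataclass
class OepcrPlan:
    """Overlap-extension PCR grouping of a file's oligos."""

    n_groups: int
    group_id_len: int = 20
    junction_overlap: int = 20
    group_assignment: Dict[int, int] = field(default_factory=dict)

    def group_sizes(self) -> List[int]:
        sizes = [0] * self.n_groups
        for g in self.group_assignment.values():
            sizes[g] += 1
        return sizes

    def fused_length(self, unit_len: int = UNIT_LEN) -> int:
        n = self.n_groups
        return n * unit_len - (n - 1) * self.junction_overlap


# ---------------------------------------------------------------------------
# overhang generation and scoring

def _passes_constraints(seq: str) -> bool:
    if not 0.40 <= gc_fraction(seq) <= 0.60:
        return False
    return "GGGG" not in seq and "CCCC" not in seq


def generate_overhang_candidates(n: int, seed: int) -> List[Overhang]:
    """Rejection-sample ``n`` constraint-satisfying 30-mers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    out = []
    seen = set()
    while len(out) < n:
        s = random_seq(rng, OVERHANG_LEN)
        if s in seen or not _passes_constraints(s):
            continue
        seen.add(s)
        out.append(Overhang(sequence=s, gc_fraction=gc_fraction(s),
                            self_score=self_structure_score(s)))
    return out


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (classic DP)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def self_structure_score(s: str) -> int:
    """Hairpin proxy: longest reverse-complementary match between two
    non-overlapping windows of ``s`` (higher = more self-structure)."""
    if len(s) < 4:
        raise ValueError("sequence too short to score")
    n = len(s)
    best = 0
    rc = revcomp(s)
    # match s[i:i+k] against rc; rc[p:p+k] corresponds to
    # s[n-p-k : n-p], so non-overlap requires i+k <= n-p-k or n-p <= i
    for i in range(n):
        for p in range(n):
            k = 0
            while (i + k < n and p + k < n and s[i + k] == rc[p + k]):
                k += 1
                j_start = n - p - k
                if (i + k <= j_start or n - p <= i) and k > best:
                    best = k
    return best


def crosstalk_score(a: str, b: str) -> int:
    """Longest stretch of ``a`` whose Watson-Crick reverse complement
    occurs in ``b`` (symmetric in its arguments)."""
    return _longest_common_substring(a, revcomp(b))


def select_orthogonal_subset(candidates: Sequence[Overhang], k: int,
                             threshold: int = 10) -> List[Overhang]:
    """Greedy conflict elimination, then pick ``k`` by self-structure.

    Pairs with crosstalk above ``threshold`` are conflicts; the member
    in the most conflicts is removed repeatedly (ties: higher
    self_score goes first, then lexicographically larger sequence)
    until no conflicts remain.  Raises :class:`PoolExhaustedError` if
    fewer than ``k`` survive.
    """
    if k > len(candidates):
        raise PoolExhaustedError(
            f"asked for {k} overhangs from {len(candidates)} candidates")
    cands = list(candidates)
    n = len(cands)
    conflict = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if crosstalk_score(cands[i].sequence, cands[j].sequence) \
                    > threshold:
                conflict[i][j] = conflict[j][i] = True
    alive = set(range(n))
    while True:
        degree = {i: sum(conflict[i][j] for j in alive if j != i)
                  for i in alive}
        worst = max(degree.values(), default=0)
        if worst == 0:
            break
        # eliminate: max degree, then higher self_score, then lexicographic
        victim = max(
            (i for i in alive if degree[i] == worst),
            key=lambda i: (cands[i].self_score, cands[i].sequence))
        alive.remove(victim)
    survivors = sorted((cands[i] for i in alive),
                       key=lambda o: (o.self_score, o.sequence))
    if len(survivors) < k:
        raise PoolExhaustedError(
            f"only {len(survivors)} orthogonal overhangs available, "
            f"{k} requested")
    return survivors[:k]


# ---------------------------------------------------------------------------
# assembly planning

def expected_product_len(tiers: Sequence[int],
                         unit_len: int = UNIT_LEN,
                         overhang_len: int = OVERHANG_LEN) -> int:
    """Tier recurrence L_t = m_t * L_{t-1} + (m_t + 1) * overhang_len."""
    length = unit_len
    for m in tiers:
        length = m * length + (m + 1) * overhang_len
    return length


def plan_gibson(tiers: Sequence[int],
                overhang_pool: Optional[Sequence[Overhang]] = None,
                unit_len: int = UNIT_LEN,
                overhang_len: int = OVERHANG_LEN,
                seed: int = 0) -> AssemblyPlan:
    """Plan a tiered Gibson assembly; tier t needs m_t + 1 overhangs."""
    tiers = list(tiers)
    if not tiers or any(m < 1 for m in tiers):
        raise ValueError("tiers must be positive fragment counts")
    needed = sum(m + 1 for m in tiers)
    if overhang_pool is None:
        cands = generate_overhang_candidates(max(3 * needed, 24), seed)
        overhang_pool = select_orthogonal_subset(cands, needed)
    if len(overhang_pool) < needed:
        raise PoolExhaustedError(
            f"plan needs {needed} overhangs, pool has {len(overhang_pool)}")
    per_tier = []
    cursor = 0
    for m in tiers:
        per_tier.append(list(overhang_pool[cursor:cursor + m + 1]))
        cursor += m + 1
    return AssemblyPlan(
        tiers=tiers, overhangs_per_tier=per_tier, unit_len=unit_len,
        overhang_len=overhang_len,
        expected_product_len=expected_product_len(
            tiers, unit_len, overhang_len))


def plan_oepcr(n_groups: int, oligos_per_group: Sequence[int] | int,
               junction_overlap: int = 20) -> OepcrPlan:
    """Split a file's oligos into contiguous balanced groups.

    ``oligos_per_group`` may be the total oligo count (balanced split,
    sizes differ by <= 1) or an explicit per-group size list.
    """
    if n_groups < 2:
        raise ValueError("OE-PCR needs at least 2 groups")
    if isinstance(oligos_per_group, int):
        total = oligos_per_group
        base, extra = divmod(total, n_groups)
        sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    else:
        sizes = list(oligos_per_group)
        if len(sizes) != n_groups:
            raise ValueError("size list does not match n_groups")
    assignment = {}
    idx = 0
    for g, size in enumerate(sizes):
        for _ in range(size):
            assignment[idx] = g
            idx += 1
    return OepcrPlan(n_groups=n_groups, junction_overlap=junction_overlap,
                     group_assignment=assignment)


def build_reference_products(plan: AssemblyPlan, pool: Sequence[str],
                             n_products: int, rng_seed: int) -> List[str]:
    """Sample concatenated reference products from an oligo pool.

    Each 150-nt slot draws an oligo uniformly at random, reproducing a
    Gibson product that can contain any combination of pool members.
    Product length equals ``plan.expected_product_len`` exactly.
    """
    if not pool:
        raise ValueError("empty oligo pool")
    rng = np.random.Generator(np.random.PCG64(rng_seed))

    def build_tier(t: int) -> str:
        ovh = [o.sequence for o in plan.overhangs_per_tier[t]]
        m = plan.tiers[t]
        if t == 0:
            frags = [pool[rng.integers(len(pool))] for _ in range(m)]
        else:
            frags = [build_tier(t - 1) for _ in range(m)]
        parts = []
        for i in range(m):
            parts.append(ovh[i])
            parts.append(frags[i])
        parts.append(ovh[m])
        return "".join(parts)

    out = []
    for _ in range(n_products):
        product = build_tier(len(plan.tiers) - 1)
        assert len(product) == plan.expected_product_len
        out.append(product)
    return out


def build_oepcr_products(plan: OepcrPlan, pools: Sequence[Sequence[str]],
                         n_products: int, rng_seed: int,
                         junction_ids: Optional[Sequence[str]] = None
                         ) -> List[str]:
    """Sample OE-PCR fused products: one oligo per group, adjacent
    groups merged on a ``junction_overlap``-nt shared junction.

    ``pools[g]`` holds full oligo sequences of group g whose last
    ``junction_overlap`` nt equal the next group's first
    ``junction_overlap`` nt (the shared junction ID); the overlap is
    counted once in the fused product.
    """
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    ov = plan.junction_overlap
    out = []
    for _ in range(n_products):
        picks = [pools[g][rng.integers(len(pools[g]))]
                 for g in range(plan.n_groups)]
        fused = picks[0]
        for nxt in picks[1:]:
            fused = fused + nxt[ov:] if ov else fused + nxt
        out.append(fused)
    return out
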