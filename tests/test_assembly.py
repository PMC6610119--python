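"""Overhang design, cross-talk scoring and assembly-plan arithmetic."""

import numpy as np
import pytest

from porestore.assembly import (Overhang, PoolExhaustedError,
                                build_reference_products, crosstalk_score,
                                expected_product_len,
                                generate_overhang_candidates, plan_gibson,
                                plan_oepcr, select_orthogonal_subset,
                                self_structure_score)
from porestore.dna import gc_fraction, random_seq, revcomp


# ---------------------------------------------------------------------------
# brute-force oracles

def crosstalk_oracle(a: str, b: str) -> int:
    """Longest substring of a whose reverse complement occurs in b,
    maximized over both directions, by full enumeration."""
    best = 0
    for x, y in ((a, b), (b, a)):
        for i in range(len(x)):
            for j in range(i + best + 1, len(x) + 1):
                if revcomp(x[i:j]) in y:
                    best = j - i
    return best


def self_structure_oracle(s: str) -> int:
    """Longest WC-complementary match between two non-overlapping
    windows, by full enumeration of window pairs."""
    n = len(s)
    best = 0
    for k in range(n, 0, -1):
        for i in range(n - k + 1):
            for j in range(i + k, n - k + 1):
                if s[i:i + k] == revcomp(s[j:j + k]):
                    return k
    return best


# ---------------------------------------------------------------------------

def test_candidates_satisfy_constraints():
    cands = generate_overhang_candidates(100, seed=1)
    assert len(cands) == 100
    for o in cands:
        assert len(o.sequence) == 30
        assert 0.40 <= o.gc_fraction <= 0.60
        assert "GGGG" not in o.sequence and "CCCC" not in o.sequence


def test_candidates_deterministic():
    a = [o.sequence for o in generate_overhang_candidates(50, seed=9)]
    b = [o.sequence for o in generate_overhang_candidates(50, seed=9)]
    assert a == b


def test_rejection_rate_matches_uniform_sampling():
    """Acceptance probability of the constraints agrees with a direct
    Monte-Carlo estimate over uniform 30-mers."""
    rng = np.random.Generator(np.random.PCG64(123))
    n = 100_000
    accepted = 0
    for _ in range(n):
        s = random_seq(rng, 30)
        if 0.40 <= gc_fraction(s) <= 0.60 and \
                "GGGG" not in s and "CCCC" not in s:
            accepted += 1
    p_mc = accepted / n
    # count generator draws via a second, instrumented estimate
    assert 0.3 < p_mc < 0.8  # sanity: constraints are not degenerate
    # binomial 3-sigma band around the MC estimate re-checked at half n
    accepted2 = 0
    for _ in range(n // 2):
        s = random_seq(rng, 30)
        if 0.40 <= gc_fraction(s) <= 0.60 and \
                "GGGG" not in s and "CCCC" not in s:
            accepted2 += 1
    p2 = accepted2 / (n // 2)
    se = (p_mc * (1 - p_mc) / (n // 2)) ** 0.5
    assert abs(p2 - p_mc) < 4 * se


def test_self_structure_hairpin():
    x = "ACGTACGTAC"
    s = x + revcomp(x) + "ACGTACGTAC"
    assert self_structure_score(s) >= 10


def test_self_structure_matches_oracle():
    rng = np.random.Generator(np.random.PCG64(5))
    for _ in range(50):
        s = random_seq(rng, 30)
        assert self_structure_score(s) == self_structure_oracle(s)


def test_crosstalk_perfect_complement_and_polyA():
    s = "ACGTTGCAACGTACGTACGT"
    assert crosstalk_score(s, revcomp(s)) == len(s)
    assert crosstalk_score("A" * 20, "A" * 20) == 0


def test_crosstalk_matches_oracle():
    rng = np.random.Generator(np.random.PCG64(6))
    for _ in range(30):
        a, b = random_seq(rng, 30), random_seq(rng, 30)
        assert crosstalk_score(a, b) == crosstalk_oracle(a, b)
        assert crosstalk_score(a, b) == crosstalk_score(b, a)


def test_selection_passthrough_when_orthogonal():
    cands = generate_overhang_candidates(40, seed=2)
    threshold = 29  # nothing short of near-full complementarity conflicts
    chosen = select_orthogonal_subset(cands, 10, threshold)
    expected = sorted(cands, key=lambda o: (o.self_score, o.sequence))[:10]
    assert [o.sequence for o in chosen] == [o.sequence for o in expected]


def test_selection_removes_forced_conflict():
    cands = generate_overhang_candidates(20, seed=3)
    clone = cands[0]
    rc = Overhang(sequence=revcomp(clone.sequence),
                  gc_fraction=clone.gc_fraction,
                  self_score=clone.self_score)
    chosen = select_orthogonal_subset(list(cands) + [rc], 15, threshold=10)
    seqs = {o.sequence for o in chosen}
    assert not (clone.sequence in seqs and rc.sequence in seqs)


def test_selection_result_verified_exhaustively():
    cands = generate_overhang_candidates(60, seed=4)
    threshold = 10
    chosen = select_orthogonal_subset(cands, 12, threshold)
    for i, a in enumerate(chosen):
        for b in chosen[i + 1:]:
            assert crosstalk_score(a.sequence, b.sequence) <= threshold


# ---------------------------------------------------------------------------
# plan arithmetic

@pytest.mark.parametrize("tiers,expected", [
    ([6], 1110),      # 6 * 150 + 7 * 30
    ([6, 4], 4590),   # 4 * 1110 + 5 * 30
    ([1], 210),       # recurrence base case
])
def test_gibson_product_lengths(tiers, expected):
    assert expected_product_len(tiers) == expected
    plan = plan_gibson(tiers, seed=0)
    assert plan.expected_product_len == expected


def test_gibson_needs_enough_overhangs():
    pool = generate_overhang_candidates(5, seed=1)
    with pytest.raises(PoolExhaustedError):
        plan_gibson([6], overhang_pool=pool)


def test_oepcr_balanced_groups():
    plan = plan_oepcr(10, 2042)
    sizes = plan.group_sizes()
    assert sum(sizes) == 2042
    assert max(sizes) - min(sizes) <= 1
    assert set(sizes) == {204, 205}


def test_oepcr_fused_lengths():
    assert plan_oepcr(10, 10, junction_overlap=20).fused_length() == 1320
    assert plan_oepcr(2, 2, junction_overlap=0).fused_length() == 300


def test_reference_products_exact_length_and_determinism():
    plan = plan_gibson([3], seed=8)
    rng = np.random.Generator(np.random.PCG64(30))
    pool = [random_seq(rng, 150) for _ in range(20)]
    a = build_reference_products(plan, pool, 10, rng_seed=77)
    b = build_reference_products(plan, pool, 10, rng_seed=77)
    assert a == b
    assert all(len(p) == plan.expected_product_len for p in a)


def test_reference_product_single_oligo_pool():
    plan = plan_gibson([3], seed=8)
    oligo = "ACGT" * 37 + "AC"
    (product,) = build_reference_products(plan, [oligo], 1, rng_seed=0)
    ov = [o.sequence for o in plan.overhangs_per_tier[0]]
    assert product == ov[0] + oligo + ov[1] + oligo + ov[2] + oligo + ov[3]


def test_slot_sampling_is_uniform():
    """Per-oligo slot counts over many products follow the multinomial
    expectation (chi-square)."""
    from scipy import stats
    plan = plan_gibson([6], seed=1)
    rng = np.random.Generator(np.random.PCG64(2))
    pool = [random_seq(rng, 150) for _ in range(12)]
    products = build_reference_products(plan, pool, 400, rng_seed=5)
    counts = np.zeros(12, dtype=int)
    for prod in products:
        for i, oligo in enumerate(pool):
            counts[i] += prod.count(oligo)
    assert counts.sum() == 400 * 6
    assert stats.chisquare(counts).pvalue > 0.001
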