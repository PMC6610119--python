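# Methods

This note records the models implemented in `porestore`, the
parameters that matter, and the choices made where the design was
genuinely open.

## Storage geometry and codec

Every oligo is 150 nt: a 20-nt front file ID, a 110-nt payload, a
20-nt back file ID. File IDs double as PCR primer sites for random
access and as the anchors used to cut payloads out of long reads; the
generator enforces GC between 40–60 %, no homopolymer ≥ 4, and > 10
edits between any two generated IDs so anchor search cannot confuse
them.

Encoding runs: length header (8 bytes) → XOR with a seeded PCG64
keystream (randomization) → split into fixed-size byte blocks → outer
Reed–Solomon code → per-block inner code with an index prefix → file-ID
flanks. All stages invert exactly; `decode(encode(x)) == x` holds for
every inner mode and redundancy level tested.

**Outer code.** GF(2⁸) Reed–Solomon, systematic, with codewords
running *across* blocks: byte *j* of every block in a stripe forms one
codeword, so losing an oligo is one erasure per codeword and a wrong
consensus payload is one error symbol. Stripes keep codewords ≤ 255
symbols; parity per stripe is ⌈*k*·*r*⌉ for redundancy fraction *r*
(20 data blocks at *r* = 0.25 encode to 25). The decoder corrects
*e* erasures plus *t* errors whenever *e* + 2*t* ≤ *n*<sub>parity</sub>
(Forney syndromes, Berlekamp–Massey, Chien search, Forney algorithm)
and verifies the corrected word, so the erasure threshold is sharp.

**Inner codes.** `direct` maps 2 bits/base (A=00, C=01, G=10, T=11).
`homopolymer_free` maps 4 bits → 3 trits → 3 bases through a rotating
code (`base_k = base_{k-1} + 1 + trit (mod 4)`), so consecutive bases
always differ; rate 1.33 bits/base. Block capacities follow: 24
data bytes per payload in direct mode, 15 in homopolymer-free mode,
after a 24-bit index prefix.

**Index whitening.** Indices are small integers; coded directly their
high bits would open every payload with a long homopolymer run (a
hotspot for correlated nanopore deletions) and make all prefixes
nearly identical. The index bits are therefore XORed with a fixed
seeded mask before inner coding — the same randomization principle the
scrambler applies to the data.

## Assembly design

Overhang candidates are uniform 30-mers rejection-sampled under the
sequence constraints (GC 40–60 % inclusive over the full 30-mer, no
GGGG/CCCC). Thermodynamic structure prediction is deliberately
replaced by combinatorial proxies: self-structure is the longest
Watson–Crick reverse-complementary match between two non-overlapping
windows of the sequence, and cross-talk between two overhangs is the
longest stretch of one whose reverse complement occurs in the other
(computed as a longest-common-substring against the reverse
complement, symmetric by construction). Both proxies equal brute-force
window enumeration on all tested instances. Pairs above a conflict
threshold (default 10 complementary bases) are eliminated greedily:
highest conflict degree first, ties broken toward keeping lower
self-structure, then lexicographically — the elimination order is
fixed for reproducibility.

Tiered Gibson plans follow the recurrence
L₀ = 150, L_t = m_t·L_{t−1} + (m_t+1)·30, giving 1110 bp for a
6-fragment tier and 4590 bp for a [6, 4] plan; tier *t* consumes
m_t + 1 overhangs. Reference products sample one pool oligo per slot
uniformly at random, modelling an assembly that can contain any
combination of the pool.

OE-PCR plans split a file's oligos into contiguous, balanced groups
(sizes differ by ≤ 1). Junctions are shared 20-nt IDs: the back ID of
group *g* *is* the front ID of group *g* + 1, so a fused 10-group
product is 10·150 − 9·20 = 1320 nt with every junction counted once.

## Error channel

Per base, independently: deletion (3.0 %), substitution (3.0 %) drawn
from a row-stochastic 4×4 matrix that weights transitions (A↔G, C↔T)
3× each transversion, and insertion of a uniform base per gap
(0.87 %); 6.87 % total, matching the overall rate the profiler should
measure. Rates, matrix and bias are all parameters.

**Homopolymer model.** Each maximal run of ≥ 5 identical bases loses
exactly one base with probability 0.44 per read, independent of run
length; i.i.d. deletions are suppressed *inside* such runs so the
run-level probability is the per-run deletion incidence (without
suppression the incidence would be 1−(1−0.44)·0.97⁵ ≈ 52 %,
inconsistent with the 44 % the model is built to reproduce). The
channel deliberately makes these deletions correlated across reads —
they defeat plurality consensus whenever a majority of a cluster lost
the same run base, which is the known failure mode of this readout for
homopolymer-bearing payloads; the package reproduces the limitation
rather than fixing it.

**Qualities.** Per-read mean Phred is set from the realized error
fraction (Q = −10·log₁₀ p, capped at 60) with ±3 uniform per-base
jitter; per-read means are the only quality statistic the workflow
consumes. Optional geometric end-truncation is off by default.

## Extraction

Anchor search is a semi-global Sellers dynamic program vectorized over
read positions: the last DP row yields, for every read offset, the
minimum edit distance of the anchor to a substring ending there.
Candidate ends within `max_edits` (default 4, ~20 % of a 20-nt anchor)
are grouped into occurrences; lowest edits then leftmost wins, starts
are resolved by a reverse DP, and overlapping hits are pruned.
Payload windows are cut between each front-ID hit and the nearest
downstream back-ID hit and kept when their length is within ±15 nt of
110; out-of-band windows are rejected rather than trimmed to avoid
chimeras spanning a missed anchor. Both read orientations are
extracted and the richer one kept (one molecule, one orientation);
minus-strand windows are reverse-complemented into payload
orientation. Coordinates are 0-based half-open throughout. For OE-PCR
products, windows are cut between consecutive junction-ID hits
instead.

## Clustering and consensus

Clustering is index-first. Windows whose inner-coded index prefix
decodes are bucketed by index; since an errored prefix still decodes
to *some* index in direct mode, only in-range buckets with ≥ 3 members
are trusted, and each is verified against a medoid seed within an edit
radius (default 15) to eject aliased impostors. A quick consensus of
each verified bucket then serves as the cluster representative:
remaining windows are attached to the representative sharing an exact
16-mer when within the radius, and whatever is left is greedily
star-clustered. Verified representatives sit about one channel-noise
radius from every true copy, which is why attachment uses them rather
than raw member windows.

Consensus is pointer-based trace reconstruction. Each member carries a
pointer; each step elects the next base by plurality over in-sync
members (ties fixed A<C<G<T; the margin is winner minus runner-up).
Disagreeing members are classified against the lookahead context voted
by the agreeing members (context length 5): substitution advances the
pointer 1, insertion 2, deletion 0; anything else marks the member
*out of sync*. Parked members are ignored for 8 steps, then the last
6 consensus bases are searched for within ±6 of the member's expected
offset; an exact match re-anchors the pointer (nearest match to the
expected offset, ties leftmost) and clears the label. The widths are
open design choices — 4⁶ ≫ 110 makes a 6-base suffix statistically
unique within a payload window — and all live in `ConsensusParams`.
A `drop_on_desync` flag reproduces the older algorithm that discards
unclassifiable members; the out-of-sync variant reconstructs at least
as well at every tested cluster size and strictly better at some,
which is what permits decoding from lower coverage. If all members
exhaust before 110 bases the remainder is pad-voted and the result is
flagged; the pipeline withholds flagged consensus (and consensus whose
embedded index contradicts its bucket) so the outer decoder sees a
1-symbol erasure instead of a 2-symbol error.

## Profiler

Observations are globally aligned (unit-cost edit distance) to their
reference payloads — located by decoded index when possible, else by
best edit distance, with observations beyond 30 % of the payload
length excluded as unaligned. Events are attributed per reference base
walking the CIGAR (insertions charged to the next reference base);
total error is events per aligned reference base. Per-read quality is
averaged on the probability scale. Coverage counts observations per
reference payload with zeros included, and reports the no-assembly
equivalent (reads ÷ payloads) plus the read count a target coverage
would need.

Per-run homopolymer deletion incidence is measured by run-length
calling: the run locus is located by exact match of its unique 8-nt
flanks (reads with corrupted flanks are not interpretable at the locus
and leave the denominator), and a shorter-than-reference called run
counts as deleted. A deletion masked by a compensating insertion in
the same segment is invisible to the raw count; with *a* = P(short)
and *b* = P(long) the censoring satisfies *a* = p_del(1−p_ins),
*b* = p_ins(1−p_del), and solving the pair gives the corrected
incidence from observed quantities alone.

The sequence-until rule consumes observation batches, tracks estimated
per-payload depth, attempts a decode once a configured fraction of
payloads reaches a minimum depth, and stops on the first success.

## Scaled experiment sizes

The decode experiments run at desk scale as the package's own choice
of problem size: the headline decode uses a 32 kB file (≈ 1.7 k
oligos) in 10-fragment OE-PCR products with redundancy 0.25, bisecting
coverage over full pipeline runs; channel calibration uses ≥ 10⁶
aligned bases; the consensus comparison uses 100 payloads at cluster
sizes 3/5/10/20. Calibration references use homopolymer-free payloads
so the measured total error isolates the base channel rates, mirroring
measurement on files that carry no runs.

## What the synthetic data does and does not capture

The generator reproduces the read structure (concatemers of 150-nt
units with 30-nt overhang spacers or 20-nt junctions), the error
magnitudes and substitution bias, the per-read quality summary, and
the correlated homopolymer deletions. It does not model raw-current
basecalling artifacts, read truncation and chimera formation beyond an
optional geometric tail, pore-dependent quality drift, assembly side
products, or synthesis errors in the oligo pool; conclusions from
passing tests transfer to real data only to the extent those effects
are secondary at these error rates.

## Known limitations

* Payloads containing homopolymer runs ≥ 5 fail consensus whenever a
  majority of cluster members lost the same run base; with the direct
  inner code ~25 % of payloads carry such runs and the outer code must
  absorb the resulting erasures. The homopolymer-free inner code
  avoids the problem at a 33 % capacity cost.
* Cross-talk scoring is combinatorial; sequences with pathological
  thermodynamics but short complementary stretches are not flagged.
* The simulator's insertion model is single-base per gap; long
  insertions are not generated.
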