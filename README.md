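# porestore

DNA data storage readout over assembled nanopore reads.

Nanopore flowcells are inefficient on the 150-nt oligos used for DNA
data storage: every pore spends most of its time capturing rather than
reading when fragments are short. `porestore` implements the
computational side of a workflow that fixes this by *concatenating*
storage oligos into kilobase-scale amplicons before sequencing —
sequential Gibson assembly with orthogonal 30-nt overhangs, or
overlap-extension PCR (OE-PCR) over group-ID-tagged subpools — so that
a single long read observes dozens of payloads.

The package covers the full round trip for people building or studying
such systems:

* **Codec** — bytes → 150-nt oligos (20-nt file-ID + 110-nt payload +
  20-nt file-ID): XOR-keystream randomization, a Reed–Solomon outer
  code over payload blocks (errors *and* erasures are corrected, up to
  *e* + 2*t* ≤ *n*<sub>parity</sub> per stripe), and two inner codes —
  `direct` (2 bits/base) and `homopolymer_free` (4 bits → 3 bases
  through a rotating code with no repeated base).
* **Assembly design** — orthogonal 30-nt overhang sets (GC 40–60 %, no
  GGGG/CCCC, minimal self-structure and pairwise cross-talk by longest
  Watson–Crick complementary stretch), tiered Gibson plans with the
  exact product-length recurrence
  *L*<sub>t</sub> = *m*<sub>t</sub>·*L*<sub>t−1</sub> + (*m*<sub>t</sub>+1)·30
  (so tiers [6] → 1110 bp and [6, 4] → 4590 bp), and OE-PCR group
  plans with shared 20-nt junction IDs.
* **Read simulator** — a nanopore-like error channel (substitutions
  with purine↔purine / pyrimidine↔pyrimidine transition bias,
  insertions, deletions; defaults 3.0 / 0.87 / 3.0 %, 6.87 % total)
  plus a run-level homopolymer model in which every run ≥ 5 nt loses a
  base with probability 0.44 per read; FASTQ output with qualities
  tracking the realized per-read error rate.
* **Extraction** — approximate (edit-distance ≤ 4) anchor search for
  the 20-nt file IDs over both strands of each concatemer read, and
  payload windows cut between anchor pairs.
* **Consensus** — index-first clustering and a pointer/plurality
  trace-reconstruction algorithm that classifies each disagreement as
  substitution / insertion / deletion from local context and, instead
  of dropping unclassifiable members, parks them *out of sync* and
  re-anchors them by matching the recent consensus suffix — the
  feature that lets files decode at lower coverage.
* **Profiler** — alignment-based error breakdown, observed
  substitution matrix, Phred summaries (Q = −10·log₁₀ p), payload
  coverage accounting and a *sequence-until* stopping rule.
* **Pipeline/CLI** — one-config end-to-end runs with per-stage seeds.

## Worked example

```python
import numpy as np
from porestore import (RunConfig, run_end_to_end)

cfg = RunConfig(file_size=4096, coverage=30.0, tiers=(6,))
report = run_end_to_end(cfg)
print(report.success, report.n_reads, round(report.alignments_per_read, 2),
      report.n_erased, report.n_corrected)
```

prints

```
True 1070 5.92 11 4
```

— a 4 kB file encoded into 214 oligos, read through 1070 simulated
noisy reads of 6-fragment assemblies (≈ 5.9 payload observations
recovered per read of the ideal 6), decoded byte-exactly with 11
payload blocks erased and 4 corrected by the outer code.

The same flow is available from the shell:

```
porestore plan-assembly --tiers 6,4     # -> 4590 bp expected product
porestore design-overhangs --n 100 --k 12 --seed 1
porestore run-all --config run.yaml --workdir out/
```

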