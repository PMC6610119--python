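"""End-to-end orchestration: encode -> assemble -> simulate -> extract
-> cluster -> consensus -> decode -> profile.

A :class:`RunConfig` captures every parameter and every stochastic
seed, so a run is reproducible from its config alone.  Two assembly
routes are supported:

* ``gibson``: tiered concatenation with orthogonal 30-nt overhangs;
  every payload sits between the file's front and back 20-nt IDs.
* ``oepcr``: the file's oligos are split into contiguous groups and
  each product takes one oligo per group, fused on shared 20-nt
  junction IDs (the back ID of group g is the front ID of group g+1),
  so each junction is counted once in the product.

Reads are simulated at a target mean payload coverage, payload windows
are cut out by anchor search, clustered index-first, reconstructed by
out-of-sync consensus (flagged, padded consensus sequences are
withheld so the outer decoder sees them as erasures rather than
errors), and the byte stream is recovered through the Reed-Solomon
outer code.
"""

from __future__ import annotations

import math
import time
from dataclasses import asdict, dataclass, field, replace
from typing import List, Optional

import numpy as np
import yaml

from . import assembly as asm
from .codec import (EncodedFile, FileParams, decode_file_full,
                    decode_index_prefix, encode_file, make_file_ids,
                    UnrecoverableFileError)
from .consensus import (Cluster, ConsensusParams, cluster_observations,
                        consensus_sequence)
from .extract import PayloadObservation, extract_payloads, find_anchors
from .profiler import coverage_stats, phred_summary, profile_errors
from .simulate import ErrorProfile, simulate_run, write_fastq

__all__ = [
    "RunConfig", "RunReport", "StageError", "encode_stage",
    "build_references", "run_end_to_end", "min_successful_coverage",
    "extract_payloads_multi", "make_fixture",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    # data
    file_size: int = 4096
    data_seed: int = 0
    # codec
    payload_len: int = 110
    index_bits: int = 24
    redundancy_fraction: float = 0.25
    inner_mode: str = "direct"
    scramble_seed: int = 1
    id_seed: int = 2
    # assembly
    assembly: str = "gibson"  # or "oepcr"
    tiers: tuple = (6,)
    n_groups: int = 10
    junction_overlap: int = 20
    overhang_seed: int = 3
    # simulation
    sub_rate: float = 0.03
    ins_rate: float = 0.0087
    del_rate: float = 0.03
    hp_del_prob: float = 0.44
    coverage: float = 30.0
    n_reads: Optional[int] = None
    rc_prob: float = 0.5
    build_seed: int = 5
    read_seed: int = 4
    # decoding
    max_edits: int = 4
    cluster_radius: int = 15
    max_cluster_members: int = 40
    drop_on_desync: bool = False

    def error_profile(self) -> ErrorProfile:
        return ErrorProfile(sub_rate=self.sub_rate, ins_rate=self.ins_rate,
                            del_rate=self.del_rate,
                            hp_del_prob=self.hp_del_prob)

    def fragments_per_product(self) -> int:
        if self.assembly == "gibson":
            n = 1
            for m in self.tiers:
                n *= m
            return n
        return self.n_groups

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tiers"] = list(d["tiers"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "tiers" in d:
            d["tiers"] = tuple(d["tiers"])
        return cls(**d)


@dataclass
class RunReport:
    success: bool
    n_reads: int
    n_observations: int
    n_clusters: int
    coverage_mean: float
    alignments_per_read: float
    n_payloads: int
    n_erased: int
    n_corrected: int
    mean_read_q: Optional[float] = None
    timings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages

def _random_bytes(size: int, seed: int) -> bytes:
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.integers(0, 256, size, dtype=np.uint8).tobytes()


@dataclass
class _Encoded:
    encoded: EncodedFile
    params: FileParams
    junctions: Optional[List[str]] = None  # oepcr: n_groups + 1 IDs
    group_of: Optional[dict] = None        # oepcr: index -> group


def encode_stage(config: RunConfig, data: bytes) -> _Encoded:
    if config.assembly == "gibson":
        front, back = make_file_ids(config.id_seed)[0]
        params = FileParams(
            file_id_front=front, file_id_back=back,
            payload_len=config.payload_len, index_bits=config.index_bits,
            redundancy_fraction=config.redundancy_fraction,
            inner_mode=config.inner_mode,
            scramble_seed=config.scramble_seed)
        return _Encoded(encoded=encode_file(data, params), params=params)
    if config.assembly != "oepcr":
        raise ValueError(f"unknown assembly route {config.assembly!r}")
    n_ids = config.n_groups + 1
    pairs = make_file_ids(config.id_seed, n_pairs=math.ceil(n_ids / 2))
    junctions = [s for p in pairs for s in p][:n_ids]
    params = FileParams(
        file_id_front=junctions[0], file_id_back=junctions[1],
        payload_len=config.payload_len, index_bits=config.index_bits,
        redundancy_fraction=config.redundancy_fraction,
        inner_mode=config.inner_mode, scramble_seed=config.scramble_seed)
    enc = encode_file(data, params)
    plan = asm.plan_oepcr(config.n_groups, enc.n_oligos,
                          config.junction_overlap)
    group_of = plan.group_assignment
    regrouped = []
    for o in enc.oligos:
        g = group_of[o.index]
        seq = junctions[g] + o.payload + junctions[g + 1]
        regrouped.append(replace(o, sequence=seq))
    enc.oligos = regrouped
    return _Encoded(encoded=enc, params=params, junctions=junctions,
                    group_of=group_of)


def build_references(config: RunConfig, enc: _Encoded,
                     n_products: int) -> List[str]:
    if config.assembly == "gibson":
        plan = asm.plan_gibson(list(config.tiers), seed=config.overhang_seed)
        pool = [o.sequence for o in enc.encoded.oligos]
        return asm.build_reference_products(
            plan, pool, n_products, rng_seed=config.build_seed)
    plan = asm.plan_oepcr(config.n_groups, enc.encoded.n_oligos,
                          config.junction_overlap)
    pools: List[List[str]] = [[] for _ in range(config.n_groups)]
    for o in enc.encoded.oligos:
        pools[enc.group_of[o.index]].append(o.sequence)
    return asm.build_oepcr_products(plan, pools, n_products,
                                    rng_seed=config.build_seed)


def extract_payloads_multi(read, anchors: List[str], payload_len: int = 110,
                           max_edits: int = 4, indel_slack: int = 15
                           ) -> List[PayloadObservation]:
    """Cut windows between consecutive anchor hits (OE-PCR junctions).

    ``anchors`` lists the junction IDs in product order; windows
    between any two consecutive hits with a payload-compatible length
    are emitted.  Orientation handling matches
    :func:`~porestore.extract.extract_payloads`.
    """
    from .dna import revcomp
    if hasattr(read, "sequence"):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "read", read

    def oriented(s: str, strand: str):
        hits = []
        for a in anchors:
            hits.extend(find_anchors(s, a, max_edits, search_rc=False))
        hits.sort(key=lambda h: h.start)
        out = []
        for h1, h2 in zip(hits, hits[1:]):
            window = s[h1.end:h2.start]
            if abs(len(window) - payload_len) <= indel_slack:
                out.append(PayloadObservation(
                    read_id=read_id, window=window,
                    position_in_read=len(out), source_strand=strand))
        return out

    fwd = oriented(seq, "+")
    rev = oriented(revcomp(seq), "-")
    return rev if len(rev) > len(fwd) else fwd


def _extract_all(config: RunConfig, enc: _Encoded, reads) \
        -> List[PayloadObservation]:
    obs: List[PayloadObservation] = []
    if config.assembly == "gibson":
        for r in reads:
            obs.extend(extract_payloads(
                r, enc.params.file_id_front, enc.params.file_id_back,
                payload_len=config.payload_len,
                max_edits=config.max_edits))
    else:
        for r in reads:
            obs.extend(extract_payloads_multi(
                r, enc.junctions, payload_len=config.payload_len,
                max_edits=config.max_edits))
    return obs


def decode_observations(observations, enc: _Encoded, config: RunConfig,
                        consensus_params: ConsensusParams = None):
    """Cluster, build consensus and run the outer decode.

    Returns (data or None, diagnostics dict).
    """
    cp = consensus_params or ConsensusParams(
        expected_len=config.payload_len)
    diag = {"n_clusters": 0, "n_padded": 0, "n_erased": 0, "n_corrected": 0}
    if not observations:
        return None, diag
    clusters = cluster_observations(
        observations, cluster_radius=config.cluster_radius,
        params=enc.params, n_payloads=enc.encoded.n_oligos)
    diag["n_clusters"] = len(clusters)
    clusters = sorted(clusters, key=lambda c: -len(c.members))
    pairs = []
    for c in clusters:
        members = c.members[:config.max_cluster_members]
        res = consensus_sequence(Cluster(members=members,
                                         provisional_index=c.provisional_index),
                                 cp, drop_on_desync=config.drop_on_desync)
        if res.padded:
            diag["n_padded"] += 1
            continue  # withheld: cheaper as an erasure than as an error
        if c.provisional_index is not None:
            # the index coded inside the consensus must agree with the
            # bucket's index (voted by independent prefixes); a clash
            # means the reconstruction is corrupt
            try:
                emb = decode_index_prefix(res.sequence, enc.params)
            except ValueError:
                emb = None
            if emb != c.provisional_index:
                diag["n_padded"] += 1
                continue
        pairs.append((c.provisional_index, res.sequence))
    try:
        data, report = decode_file_full(pairs, enc.params,
                                        n_oligos=enc.encoded.n_oligos)
    except UnrecoverableFileError:
        return None, diag
    diag["n_erased"] = len(report.erased_indices)
    diag["n_corrected"] = len(report.corrected_indices)
    return data, diag


# ---------------------------------------------------------------------------
# end to end

def run_end_to_end(config: RunConfig, workdir=None,
                   data: Optional[bytes] = None) -> RunReport:
    """Run the whole pipeline; deterministic for fixed config seeds."""
    timings = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        return out

    if data is None:
        data = _random_bytes(config.file_size, config.data_seed)
    enc = stage("encode", lambda: encode_stage(config, data))
    n_payloads = enc.encoded.n_oligos
    frags = config.fragments_per_product()
    n_reads = config.n_reads or math.ceil(
        config.coverage * n_payloads / frags)
    refs = stage("assemble",
                 lambda: build_references(config, enc, n_reads))
    profile = config.error_profile()
    reads = stage("simulate", lambda: simulate_run(
        refs, n_reads, profile, seed=config.read_seed,
        rc_prob=config.rc_prob))
    observations = stage("extract",
                         lambda: _extract_all(config, enc, reads))
    decoded, diag = stage("decode",
                          lambda: decode_observations(observations, enc,
                                                      config))
    success = decoded == data

    def obs_index(o):
        try:
            return decode_index_prefix(o.window, enc.params)
        except ValueError:
            return None

    cov = coverage_stats((i for i in map(obs_index, observations)
                          if i is not None),
                         n_payloads, n_reads=n_reads)
    q = phred_summary(reads)["mean_q"] if reads else None

    if workdir is not None:
        import pathlib
        wd = pathlib.Path(workdir)
        wd.mkdir(parents=True, exist_ok=True)
        config.to_yaml(wd / "config.yaml")
        _write_fasta(wd / "pool.fasta",
                     ((f"oligo_{o.index}", o.sequence)
                      for o in enc.encoded.oligos))
        _write_fasta(wd / "refs.fasta",
                     ((f"ref{i}", s) for i, s in enumerate(refs)))
        write_fastq(reads, wd / "reads.fastq")
        with open(wd / "observations.tsv", "w") as fh:
            fh.write("read_id\tordinal\tstrand\twindow\n")
            for o in observations:
                fh.write(f"{o.read_id}\t{o.position_in_read}\t"
                         f"{o.source_strand}\t{o.window}\n")
        if decoded is not None:
            (wd / "decoded.bin").write_bytes(decoded)

    return RunReport(
        success=success, n_reads=n_reads, n_observations=len(observations),
        n_clusters=diag["n_clusters"], coverage_mean=cov.mean_depth,
        alignments_per_read=len(observations) / n_reads if n_reads else 0.0,
        n_payloads=n_payloads, n_erased=diag["n_erased"],
        n_corrected=diag["n_corrected"], mean_read_q=q, timings=timings)


def min_successful_coverage(config: RunConfig, lo: int, hi: int,
                            data: Optional[bytes] = None,
                            verbose: bool = False) -> Optional[int]:
    """Bisect the minimum integer coverage at which the pipeline
    decodes byte-exactly (assumes success is monotone in coverage).

    Returns None when even ``hi`` fails.  Seeds are offset by the
    coverage under test so evaluations are independent but
    reproducible.
    """
    if data is None:
        data = _random_bytes(config.file_size, config.data_seed)

    def success(cov: int) -> bool:
        cfg = replace(config, coverage=float(cov),
                      read_seed=config.read_seed + 101 * cov,
                      build_seed=config.build_seed + 101 * cov)
        rep = run_end_to_end(cfg, data=data)
        if verbose:
            print(f"  coverage {cov}x -> success={rep.success} "
                  f"(obs={rep.n_observations}, erased={rep.n_erased}, "
                  f"corrected={rep.n_corrected})")
        return rep.success

    if not success(hi):
        return None
    while lo < hi:
        mid = (lo + hi) // 2
        if success(mid):
            hi = mid
        else:
            lo = mid + 1
    return hi


# ---------------------------------------------------------------------------
# fixtures

def _write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def make_fixture(kind: str, size: int, seed: int, outdir) -> dict:
    """Generate small deterministic on-disk fixtures with truth labels.

    Kinds: ``oligo_pool``, ``clean_reads``, ``noisy_reads``,
    ``cluster``.  Returns a manifest of the files written.
    """
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config = RunConfig(file_size=max(64, size), data_seed=seed,
                       id_seed=seed + 1, read_seed=seed + 2,
                       build_seed=seed + 3)
    data = _random_bytes(config.file_size, config.data_seed)
    enc = encode_stage(config, data)
    manifest = {"kind": kind, "seed": seed}
    if kind == "oligo_pool":
        _write_fasta(out / "pool.fasta",
                     ((f"oligo_{o.index}", o.sequence)
                      for o in enc.encoded.oligos))
        manifest["pool"] = str(out / "pool.fasta")
        return manifest
    refs = build_references(config, enc, n_products=8)
    if kind in ("clean_reads", "noisy_reads"):
        profile = ErrorProfile.error_free() if kind == "clean_reads" \
            else config.error_profile()
        reads = simulate_run(refs, 8, profile, seed=seed + 4)
        write_fastq(reads, out / "reads.fastq")
        _write_fasta(out / "refs.fasta",
                     ((f"ref{i}", s) for i, s in enumerate(refs)))
        manifest["reads"] = str(out / "reads.fastq")
        manifest["refs"] = str(out / "refs.fasta")
        return manifest
    if kind == "cluster":
        from .dna import find_runs
        # pick a run-free payload: correlated run deletions are the
        # channel's known unrecoverable case, and this fixture embeds a
        # reconstructible truth
        truth = next(o.payload for o in enc.encoded.oligos
                     if not find_runs(o.payload, 5))
        rng = np.random.Generator(np.random.PCG64(seed + 5))
        from .simulate import apply_channel
        copies = [apply_channel(truth, config.error_profile(), rng).sequence
                  for _ in range(10)]
        _write_fasta(out / "cluster.fasta",
                     [("truth", truth)] + [(f"copy{i}", c)
                                           for i, c in enumerate(copies)])
        manifest["cluster"] = str(out / "cluster.fasta")
        return manifest
    raise ValueError(f"unknown fixture kind {kind!r}")
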