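"""Candidate-read filtering cascade.

Host-unmapped reads are reduced to high-quality, high-complexity,
host-free candidate microbial reads in four stages applied in order:

1. depth normalisation by uniform sub-sampling (default 100,000 reads);
2. quality filter: keep a read iff at least ``min_frac`` of its bases
   have Phred quality >= ``min_quality``;
3. complexity filter: DUST-style repeated-triplet score with threshold;
4. host screen: remove reads sharing more than ``max_shared`` canonical
   k-mers with the host reference index.

Every stage is a per-read predicate, so the final candidate set does not
depend on the order of the quality and complexity stages; the per-stage
removal counts do, and the report records the order used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kmers import canonical_ints, kmer_ints, kmers_batch
from .synthetic import ReadRecord

DUST_WINDOW = 64  # normalisation constant of the triplet score


@dataclass
class FilterConfig:
    depth: int = 100_000
    subsample_seed: int = 0
    min_quality: int = 20
    min_quality_frac: float = 0.8
    complexity_threshold: float = 7.0
    host_k: int = 21
    max_shared_host_kmers: int = 2
    deduplicate: bool = False  # optional exact-sequence stage, off by default
    skip_quality: bool = False
    skip_complexity: bool = False
    skip_host: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.min_quality_frac <= 1.0:
            raise ValueError("min_quality_frac must lie in (0, 1]")
        if self.min_quality < 0 or self.complexity_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterReport:
    input: int = 0
    after_subsample: int = 0
    removed_low_quality: int = 0
    removed_low_complexity: int = 0
    removed_duplicate: int = 0
    removed_host_screen: int = 0
    candidate_output: int = 0
    subsample_shortfall: bool = False
    stage_order: list[str] = field(default_factory=list)

    def validate(self) -> None:
        removed = (self.removed_low_quality + self.removed_low_complexity
                   + self.removed_duplicate + self.removed_host_screen)
        if self.after_subsample - removed != self.candidate_output:
            raise AssertionError("filter report counts do not conserve reads")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for k in ("input", "after_subsample", "removed_low_quality",
                      "removed_low_complexity", "removed_duplicate",
                      "removed_host_screen", "candidate_output"):
                fh.write(f"{k}\t{getattr(self, k)}\n")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def subsample_reads(reads: list[ReadRecord], depth: int, seed: int):
    """Uniform sample without replacement of min(depth, n) reads.

    Returns ``(sample, shortfall_flag)``; an input smaller than the target
    depth is returned whole with the flag set.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(reads) <= depth:
        return list(reads), len(reads) < depth
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=depth, replace=False))
    return [reads[i] for i in idx], False


def quality_filter(reads: list[ReadRecord], min_quality: int = 20,
                   min_frac: float = 0.8):
    """Split reads into (kept, removed) by the fraction of high-quality bases."""
    kept, removed = [], []
    for r in reads:
        if len(r.sequence) != len(r.qualities):
            raise ValueError(f"read {r.read_id}: sequence/quality length mismatch")
        frac = np.count_nonzero(r.qualities >= min_quality) / len(r.qualities)
        (kept if frac >= min_frac else removed).append(r)
    return kept, removed


def complexity_score(sequence: str) -> float:
    """DUST-style repeated-triplet score.

    Over each window the score is sum_t c_t (c_t - 1) / 2 over triplet
    counts c_t, normalised by (w - 2) with w = 64; sequences up to 128
    bases form a single window, longer ones take the maximum over sliding
    128-base windows (step 64). A homopolymer maximises the score; a
    sequence whose triplets are all distinct scores 0.
    """
    if len(sequence) < 3:
        return 0.0
    seq = sequence.upper()
    denom = DUST_WINDOW - 2

    def window_score(s: str) -> float:
        counts: dict[str, int] = {}
        for i in range(len(s) - 2):
            t = s[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values()) / denom

    if len(seq) <= 2 * DUST_WINDOW:
        return window_score(seq)
    starts = list(range(0, len(seq) - 2 * DUST_WINDOW + 1, DUST_WINDOW))
    if starts[-1] != len(seq) - 2 * DUST_WINDOW:
        starts.append(len(seq) - 2 * DUST_WINDOW)
    return max(window_score(seq[s : s + 2 * DUST_WINDOW]) for s in starts)


def _complexity_scores_batch(reads: list[ReadRecord]) -> np.ndarray:
    """Vectorised triplet score for equal-length reads up to 128 bases."""
    seqs = [r.sequence for r in reads]
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(seqs), L)
    code = np.full(256, 0, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
        code[ord(b.lower())] = i
    c = code[arr]
    trip = (c[:, :-2] << 4) | (c[:, 1:-1] << 2) | c[:, 2:]
    counts = np.zeros((len(seqs), 64), dtype=np.int64)
    rows = np.repeat(np.arange(len(seqs)), trip.shape[1])
    np.add.at(counts, (rows, trip.ravel()), 1)
    return (counts * (counts - 1) // 2).sum(axis=1) / (DUST_WINDOW - 2)


def complexity_filter(reads: list[ReadRecord], threshold: float = 7.0):
    if not reads:
        return [], []
    L = len(reads[0].sequence)
    if L <= 2 * DUST_WINDOW and all(len(r.sequence) == L for r in reads):
        scores = _complexity_scores_batch(reads)
    else:
        scores = np.array([complexity_score(r.sequence) for r in reads])
    kept = [r for r, s in zip(reads, scores) if s <= threshold]
    removed = [r for r, s in zip(reads, scores) if s > threshold]
    return kept, removed


def build_host_index(host_ref: str | list[str], k: int = 21) -> np.ndarray:
    """Sorted array of canonical k-mers of the host reference sequence(s)."""
    refs = [host_ref] if isinstance(host_ref, str) else list(host_ref)
    parts = [canonical_ints(kmer_ints(r, k), k) for r in refs if len(r) >= k]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def host_screen(reads: list[ReadRecord], host_index: np.ndarray, k: int = 21,
                max_shared: int = 2):
    """Remove reads sharing more than ``max_shared`` canonical k-mers with
    the host index. An empty index keeps everything (with nothing to
    screen against there is no evidence of host origin)."""
    if len(host_index) == 0:
        return list(reads), []
    if not reads:
        return [], []
    L = len(reads[0].sequence)
    if all(len(r.sequence) == L for r in reads) and L >= k:
        km = kmers_batch([r.sequence for r in reads], k, canonical=True)
        pos = np.searchsorted(host_index, km)
        pos[pos == len(host_index)] = 0
        shared = (host_index[pos] == km).sum(axis=1)
    else:
        shared = np.array([
            int(np.isin(canonical_ints(kmer_ints(r.sequence, k), k), host_index).sum())
            for r in reads
        ])
    kept = [r for r, s in zip(reads, shared) if s <= max_shared]
    removed = [r for r, s in zip(reads, shared) if s > max_shared]
    return kept, removed


def deduplicate_reads(reads: list[ReadRecord]):
    seen: set[str] = set()
    kept, removed = [], []
    for r in reads:
        if r.sequence in seen:
            removed.append(r)
        else:
            seen.add(r.sequence)
            kept.append(r)
    return kept, removed


# --------------------------------------------------------------------------
# cascade
# --------------------------------------------------------------------------

def run_filter(reads: list[ReadRecord], host_ref: str | list[str] | np.ndarray,
               config: FilterConfig | None = None):
    """Full cascade; returns (candidate reads, FilterReport)."""
    cfg = config or FilterConfig()
    report = FilterReport(input=len(reads))
    current, shortfall = subsample_reads(reads, cfg.depth, cfg.subsample_seed)
    report.after_subsample = len(current)
    report.subsample_shortfall = shortfall
    report.stage_order.append("subsample")

    if not cfg.skip_quality:
        current, removed = quality_filter(current, cfg.min_quality, cfg.min_quality_frac)
        report.removed_low_quality = len(removed)
        report.stage_order.append("quality")
    if not cfg.skip_complexity:
        current, removed = complexity_filter(current, cfg.complexity_threshold)
        report.removed_low_complexity = len(removed)
        report.stage_order.append("complexity")
    if cfg.deduplicate:
        current, removed = deduplicate_reads(current)
        report.removed_duplicate = len(removed)
        report.stage_order.append("deduplicate")
    if not cfg.skip_host:
        index = (host_ref if isinstance(host_ref, np.ndarray)
                 else build_host_index(host_ref, cfg.host_k))
        current, removed = host_screen(current, index, cfg.host_k,
                                       cfg.max_shared_host_kmers)
        report.removed_host_screen = len(removed)
        report.stage_order.append("host_screen")

    report.candidate_output = len(current)
    report.validate()
    return current, report


# --------------------------------------------------------------------------
# io
# --------------------------------------------------------------------------

def read_fastq(path) -> list[ReadRecord]:
    """FASTQ reader (Sanger Phred+33; .gz transparently supported)."""
    import gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            reads.append(ReadRecord(title.split()[0], seq, q))
    return reads


def read_unmapped_sam(path) -> list[ReadRecord]:
    """Extract unmapped records from a SAM/BAM of host alignments."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if not rec.is_unmapped:
                continue
            if rec.is_paired and not rec.mate_is_unmapped:
                continue
            quals = rec.query_qualities
            reads.append(ReadRecord(
                rec.query_name, rec.query_sequence,
                np.asarray(quals if quals is not None else [30] * len(rec.query_sequence),
                           dtype=np.uint8),
                mate=2 if rec.is_read2 else (1 if rec.is_read1 else 0),
            ))
    return reads


def write_candidates_fasta(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
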