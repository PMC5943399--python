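"""Marker-gene taxonomic profiling.

Candidate reads are matched against a canonical-k-mer index of marker
genes. A read hitting markers of exactly one genus (with at least
``min_hits`` shared k-mers) is assigned to that genus; a read hitting
several genera is pushed up to the lowest common ancestor of the hit
taxa; a read hitting nothing stays unassigned. Genus-level counts are
aggregated to any higher rank, and externally produced relative-abundance
tables (rank-prefixed taxon paths) can be ingested so that real profiler
output enters the same statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import canonical_ints, kmer_ints
from .synthetic import MarkerGene, ReadRecord
from .taxonomy import RANKS, ROOT_ID, Taxonomy

RANK_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
               "f": "family", "g": "genus", "s": "species"}


@dataclass
class MarkerIndex:
    k: int
    kmer_to_markers: dict[int, frozenset[str]]
    marker_to_taxon: dict[str, str]
    taxonomy: Taxonomy

    @property
    def n_kmers(self) -> int:
        return len(self.kmer_to_markers)


def build_index(markers: list[MarkerGene], taxonomy: Taxonomy, k: int = 21) -> MarkerIndex:
    """Canonical k-mer index over a marker set."""
    if not markers:
        raise ValueError("empty marker set")
    if k < 11:
        raise ValueError("k must be >= 11 to keep random collisions negligible")
    shortest = min(len(m.sequence) for m in markers)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest marker length {shortest}")
    seen_ids: set[str] = set()
    tmp: dict[int, set[str]] = {}
    m2t: dict[str, str] = {}
    for m in markers:
        if m.marker_id in seen_ids:
            raise ValueError(f"duplicate marker id {m.marker_id!r}")
        seen_ids.add(m.marker_id)
        if m.taxon_id not in taxonomy.nodes:
            raise ValueError(f"marker {m.marker_id!r}: unknown taxon {m.taxon_id!r}")
        m2t[m.marker_id] = m.taxon_id
        for km in canonical_ints(kmer_ints(m.sequence, k), k):
            tmp.setdefault(int(km), set()).add(m.marker_id)
    return MarkerIndex(k, {km: frozenset(v) for km, v in tmp.items()}, m2t, taxonomy)


def assign_read(read: ReadRecord | str, index: MarkerIndex, min_hits: int = 2) -> str:
    """Taxon id at the deepest unambiguous rank, or ``"unassigned"``."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    seq = read if isinstance(read, str) else read.sequence
    hits: dict[str, int] = {}
    for km in canonical_ints(kmer_ints(seq, index.k), index.k):
        for mid in index.kmer_to_markers.get(int(km), ()):
            hits[mid] = hits.get(mid, 0) + 1
    taxa = {index.marker_to_taxon[mid] for mid, c in hits.items() if c >= min_hits}
    if not taxa:
        return "unassigned"
    if len(taxa) == 1:
        return taxa.pop()
    node = index.taxonomy.lca(sorted(taxa))
    return "unassigned" if node.taxon_id == ROOT_ID else node.taxon_id


def profile_sample(reads: list[ReadRecord] | list[str], index: MarkerIndex,
                   min_hits: int = 2) -> tuple[dict[str, int], int]:
    """Per-taxon read counts plus the unassigned count; order-invariant."""
    counts: dict[str, int] = {}
    unassigned = 0
    for r in reads:
        t = assign_read(r, index, min_hits)
        if t == "unassigned":
            unassigned += 1
        else:
            counts[t] = counts.get(t, 0) + 1
    return counts, unassigned


# --------------------------------------------------------------------------
# abundance tables
# --------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Samples x taxa abundances at one taxonomic rank.

    ``counts`` is None for externally ingested tables that only carry
    relative abundances; diversity statistics work from ``relative``
    either way. ``unassigned`` tracks per-sample reads not assigned at
    this table's rank, so counts.sum(axis=1) + unassigned equals the
    candidate read count of each sample.
    """

    rank: str
    relative: pd.DataFrame  # rows sum to 1 over assigned taxa
    counts: pd.DataFrame | None = None
    unassigned: pd.Series | None = None
    taxonomy: Taxonomy | None = None
    low_confidence_min_reads: int = 10

    def __post_init__(self):
        sums = self.relative.sum(axis=1)
        nonzero = sums > 0
        if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
            raise ValueError("relative abundances must sum to 1 per sample")
        if self.counts is not None and (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.relative.index)

    def low_confidence_samples(self) -> list[str]:
        """Samples with fewer assigned reads than the confidence floor."""
        if self.counts is None:
            return []
        tot = self.counts.sum(axis=1)
        return list(tot.index[tot < self.low_confidence_min_reads])

    def to_tsv(self, path, relative: bool = True) -> None:
        df = self.relative if relative or self.counts is None else self.counts
        df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, rank: str, taxonomy: Taxonomy | None = None,
                 relative: bool = True) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        if relative:
            return cls(rank, df, taxonomy=taxonomy)
        rel = df.div(df.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
        return cls(rank, rel, counts=df, taxonomy=taxonomy)


def table_from_profiles(profiles: dict[str, tuple[dict[str, int], int]],
                        taxonomy: Taxonomy, rank: str = "genus") -> AbundanceTable:
    """Assemble an AbundanceTable from per-sample ``profile_sample`` output.

    Assignments above ``rank`` (LCA fallbacks) count as unassigned at this
    rank; assignments below are lifted to their ancestor.
    """
    taxa = taxonomy.at_rank(rank)
    rows, unasn = {}, {}
    for sid, (counts, unassigned) in profiles.items():
        row = dict.fromkeys(taxa, 0)
        extra = unassigned
        for tid, c in counts.items():
            anc = tid if taxonomy.nodes[tid].rank == rank else taxonomy.ancestor_at(tid, rank)
            if anc is None:
                extra += c
            else:
                row[anc] += c
        rows[sid] = row
        unasn[sid] = extra
    counts_df = pd.DataFrame.from_dict(rows, orient="index")[taxa].sort_index()
    rel = counts_df.div(counts_df.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    return AbundanceTable(rank, rel, counts=counts_df,
                          unassigned=pd.Series(unasn).sort_index(),
                          taxonomy=taxonomy)


def aggregate_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum descendant taxa into their ancestors at ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if RANKS.index(rank) > RANKS.index(table.rank):
        raise ValueError(f"{rank!r} is not an ancestor rank of {table.rank!r}")
    if rank == table.rank:
        return table
    if table.taxonomy is None:
        raise ValueError("aggregation requires an attached taxonomy")
    mapping = {t: table.taxonomy.ancestor_at(t, rank) for t in table.relative.columns}
    targets = table.taxonomy.at_rank(rank)

    def agg(df: pd.DataFrame) -> pd.DataFrame:
        out = df.T.groupby(mapping).sum().T
        return out.reindex(columns=targets, fill_value=0 if df is not None else 0)

    rel = agg(table.relative)
    counts = agg(table.counts) if table.counts is not None else None
    return AbundanceTable(rank, rel, counts=counts, unassigned=table.unassigned,
                          taxonomy=table.taxonomy)


# --------------------------------------------------------------------------
# external profiler tables (rank-prefixed taxon paths)
# --------------------------------------------------------------------------

def read_external_profile(path, dialect: str = "rank_prefixed",
                          rank: str = "phylum") -> AbundanceTable:
    """Ingest an external profiler table.

    ``rank_prefixed``: first column holds pipe-separated taxon paths with
    single-letter rank prefixes (``k__Bacteria|p__Proteobacteria``);
    remaining columns are per-sample relative abundances. Rows whose
    deepest rank equals ``rank`` are extracted and renormalised per
    sample. ``plain``: first column is a bare taxon name at ``rank``.
    """
    if dialect not in ("rank_prefixed", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a taxon column and >= 1 sample column")
    taxa_col = df.columns[0]
    rows = {}
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        taxon_path = str(row[taxa_col])
        if dialect == "plain":
            name = taxon_path
        else:
            parts = taxon_path.split("|")
            try:
                parsed = [(RANK_PREFIX[p[0]], p[3:]) for p in parts
                          if len(p) > 3 and p[1:3] == "__"]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: unknown rank prefix {exc}") from None
            if len(parsed) != len(parts) or not parsed:
                raise ValueError(f"{path}:{lineno}: malformed taxon path {taxon_path!r}")
            if parsed[-1][0] != rank:
                continue
            name = parsed[-1][1]
        rows[name] = row.iloc[1:].astype(float)
    if not rows:
        raise ValueError(f"{path}: no rows at rank {rank!r}")
    mat = pd.DataFrame(rows)  # samples x taxa
    sums = mat.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"{path}: abundances for sample {bad!r} sum to 0")
    rel = mat.div(sums, axis=0)
    rel.index.name = "sample_id"
    return AbundanceTable(rank, rel)


def write_external_profile(table: AbundanceTable, path,
                           kingdom: str = "Bacteria") -> None:
    """Rank-prefixed writer (round-trips with :func:`read_external_profile`)."""
    prefix = {v: k for k, v in RANK_PREFIX.items()}[table.rank]
    with open(path, "w") as fh:
        fh.write("clade_name\t" + "\t".join(table.relative.index) + "\n")
        for taxon in table.relative.columns:
            path_str = f"k__{kingdom}|{prefix}__{taxon}"
            vals = "\t".join(f"{v:.6g}" for v in table.relative[taxon])
            fh.write(f"{path_str}\t{vals}\n")
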