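"""Five-rank microbial taxonomy (phylum > class > order > family > genus).

The tree is the backbone over which read assignments are aggregated and
over which the lowest-common-ancestor fallback of the profiler resolves
ambiguous hits. It is deliberately self-contained: nodes live in a flat
id -> record map with parent pointers, plus a synthetic root sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

RANKS = ("phylum", "class", "order", "family", "genus")
ROOT_ID = "root"


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str  # one of RANKS, or "root"
    parent_id: str | None  # None only for the root


class Taxonomy:
    """A rooted tree of :class:`TaxonNode` with strictly ordered ranks."""

    def __init__(self, nodes: list[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for n in nodes:
            if n.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {n.taxon_id!r}")
            self.nodes[n.taxon_id] = n
        if ROOT_ID not in self.nodes:
            self.nodes[ROOT_ID] = TaxonNode(ROOT_ID, "root", "root", None)
        self._validate()

    def _validate(self) -> None:
        order = {r: i for i, r in enumerate(RANKS)}
        order["root"] = -1
        for n in self.nodes.values():
            if n.taxon_id == ROOT_ID:
                continue
            if n.parent_id not in self.nodes:
                raise ValueError(f"taxon {n.taxon_id!r} has unknown parent {n.parent_id!r}")
            parent = self.nodes[n.parent_id]
            if order[n.rank] <= order[parent.rank]:
                raise ValueError(
                    f"rank {n.rank!r} of {n.taxon_id!r} not below parent rank {parent.rank!r}"
                )
        # reaching the root from every node also rules out cycles
        for n in self.nodes.values():
            self.lineage(n.taxon_id)

    def lineage(self, taxon_id: str) -> list[TaxonNode]:
        """Path from the node up to (excluding) the root."""
        out = []
        cur = self.nodes[taxon_id]
        seen = set()
        while cur.taxon_id != ROOT_ID:
            if cur.taxon_id in seen:
                raise ValueError("cycle in taxonomy")
            seen.add(cur.taxon_id)
            out.append(cur)
            cur = self.nodes[cur.parent_id]
        return out

    def ancestor_at(self, taxon_id: str, rank: str) -> str | None:
        for node in self.lineage(taxon_id):
            if node.rank == rank:
                return node.taxon_id
        return None

    def lca(self, taxon_ids: list[str]) -> TaxonNode:
        """Lowest common ancestor; returns the root sentinel if disjoint."""
        if not taxon_ids:
            raise ValueError("empty taxon list")
        paths = [list(reversed([n.taxon_id for n in self.lineage(t)])) for t in taxon_ids]
        anc = ROOT_ID
        for level in range(min(len(p) for p in paths)):
            ids = {p[level] for p in paths}
            if len(ids) == 1:
                anc = ids.pop()
            else:
                break
        return self.nodes[anc]

    def at_rank(self, rank: str) -> list[str]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return sorted(t for t, n in self.nodes.items() if n.rank == rank)

    @property
    def genera(self) -> list[str]:
        return self.at_rank("genus")

    def __len__(self) -> int:
        return len(self.nodes) - 1  # root sentinel excluded

    # ------------------------------------------------------------------ io
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\trank\tname\tparent_id\n")
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                if tid == ROOT_ID:
                    continue
                fh.write(f"{n.taxon_id}\t{n.rank}\t{n.name}\t{n.parent_id}\n")

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        nodes = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("taxon_id"):
                raise ValueError(f"{path}: missing taxonomy header")
            for line in fh:
                tid, rank, name, parent = line.rstrip("\n").split("\t")
                nodes.append(TaxonNode(tid, name, rank, parent))
        return cls(nodes)
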