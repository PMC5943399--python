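"""Reference-free sample dissimilarity on de Bruijn graphs.

Each sample is summarised by its normalised k-mer mass distribution. The
distance between two samples is the earth mover's distance between their
distributions, with ground metric the shortest-path hop count on the
order-k de Bruijn graph over {A,C,G,T} (undirected: w is adjacent to
every single-shift successor or predecessor). Because the ground metric
is a graph metric, the transportation problem is solved exactly as a
min-cost flow on the graph itself: node demands are the (integerised)
mass differences, every arc costs one hop, and the optimal flow cost
equals the optimal transport cost.

Two graph modes are provided. ``complete`` (default) uses the full
4^k-node graph, which guarantees finite distances and the triangle
inequality. ``observed`` restricts the graph to the union support of the
two samples and charges a fixed penalty of (k+1) hops for mass moved
between disconnected components; it is offered for sensitivity analysis
only. Both are interpretations of an under-specified construction, not
claims of equivalence with any particular implementation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.stats import spearmanr

from ._kmers import canonical_int, int_to_kmer, kmer_ints, kmer_to_int
from .diversity import DistanceMatrix

_FLOW_SCALE = 10**9  # integerisation scale for network-simplex demands


@dataclass
class KmerDistribution:
    k: int
    mass: dict[str, float]  # k-mer -> probability
    canonical: bool = False

    def __post_init__(self):
        for km in self.mass:
            if len(km) != self.k:
                raise ValueError(f"key {km!r} has length != k={self.k}")
        total = sum(self.mass.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"masses sum to {total}, expected 1")
        if any(v < 0 for v in self.mass.values()):
            raise ValueError("negative mass")

    @property
    def support_size(self) -> int:
        return sum(1 for v in self.mass.values() if v > 0)


def kmer_counts(reads, k: int, canonical: bool = False) -> KmerDistribution:
    """Normalised k-mer mass of a read set (strings or objects with
    ``.sequence``); windows containing non-ACGT characters are skipped."""
    if k < 2:
        raise ValueError("k must be >= 2")
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    if not seqs:
        raise ValueError("empty read set")
    counts: dict[int, int] = {}
    for seq in seqs:
        for km in kmer_ints(seq, k):
            km = int(km)
            if canonical:
                km = canonical_int(km, k)
            counts[km] = counts.get(km, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no valid k-mer window in any read")
    return KmerDistribution(
        k, {int_to_kmer(km, k): c / total for km, c in counts.items()}, canonical)


# --------------------------------------------------------------------------
# ground metric
# --------------------------------------------------------------------------

def _neighbors(v: int, k: int) -> list[int]:
    """Single-shift neighbours of a packed k-mer in the de Bruijn graph."""
    mask = (1 << (2 * k)) - 1
    out = []
    left = (v << 2) & mask
    right = v >> 2
    hi = 2 * (k - 1)
    for b in range(4):
        out.append(left | b)          # shift left, append base
        out.append(right | (b << hi))  # shift right, prepend base
    return out


def ground_distance(u: str, v: str, k: int | None = None) -> int:
    """Shortest-path hop count between two k-mers (BFS on the full graph)."""
    if len(u) != len(v):
        raise ValueError("k-mers must have equal length")
    k = k or len(u)
    if len(u) != k:
        raise ValueError("k-mer length does not match k")
    return _bfs_distance(kmer_to_int(u), kmer_to_int(v), k)


def _bfs_distance(src: int, dst: int, k: int) -> int:
    if src == dst:
        return 0
    dist = {src: 0}
    q = deque([src])
    while q:
        cur = q.popleft()
        d = dist[cur] + 1
        for nb in _neighbors(cur, k):
            if nb not in dist:
                if nb == dst:
                    return d
                dist[nb] = d
                q.append(nb)
    raise RuntimeError("de Bruijn graph is connected; unreachable")  # pragma: no cover


def _bfs_from(src: int, k: int, allowed: set[int] | None = None) -> dict[int, int]:
    """Distances from src, optionally restricted to an observed node set."""
    dist = {src: 0}
    q = deque([src])
    while q:
        cur = q.popleft()
        for nb in _neighbors(cur, k):
            if allowed is not None and nb not in allowed:
                continue
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    return dist


@lru_cache(maxsize=8)
def _debruijn_graph(k: int) -> nx.DiGraph:
    """Full order-k de Bruijn graph with unit-cost arcs both ways."""
    g = nx.DiGraph()
    n = 4**k
    for v in range(n):
        for nb in _neighbors(v, k):
            if nb != v:
                g.add_edge(v, nb, weight=1)
                g.add_edge(nb, v, weight=1)
    return g


# --------------------------------------------------------------------------
# earth mover's distance
# --------------------------------------------------------------------------

def _integer_demands(a: KmerDistribution, b: KmerDistribution) -> dict[int, int]:
    """Scaled (b - a) demands rounded to integers summing exactly to 0."""
    diff: dict[int, float] = {}
    for km, m in a.mass.items():
        diff[kmer_to_int(km)] = diff.get(kmer_to_int(km), 0.0) - m
    for km, m in b.mass.items():
        diff[kmer_to_int(km)] = diff.get(kmer_to_int(km), 0.0) + m
    ints = {v: int(round(d * _FLOW_SCALE)) for v, d in diff.items()}
    drift = sum(ints.values())
    if drift != 0:  # push the rounding residue onto the largest atom
        key = max(ints, key=lambda v: abs(ints[v]))
        ints[key] -= drift
    return {v: d for v, d in ints.items() if d != 0}


def emd(a: KmerDistribution, b: KmerDistribution, mode: str = "complete") -> float:
    """Exact optimal-transport distance between two k-mer distributions."""
    if a.k != b.k:
        raise ValueError("distributions have different k")
    if mode == "complete":
        demands = _integer_demands(a, b)
        if not demands:
            return 0.0
        g = _debruijn_graph(a.k).copy()
        for v, d in demands.items():
            g.nodes[v]["demand"] = d
        cost, _ = nx.network_simplex(g)
        return cost / _FLOW_SCALE
    if mode == "observed":
        return _emd_observed(a, b)
    raise ValueError(f"unknown mode {mode!r}")


def _emd_observed(a: KmerDistribution, b: KmerDistribution) -> float:
    """Transportation LP on the union support with subgraph BFS distances;
    unreachable pairs cost a flat (k+1) hops."""
    from scipy.optimize import linprog

    sup_a = sorted(a.mass)
    sup_b = sorted(b.mass)
    allowed = {kmer_to_int(km) for km in set(sup_a) | set(sup_b)}
    penalty = a.k + 1
    C = np.empty((len(sup_a), len(sup_b)))
    for i, ka in enumerate(sup_a):
        d = _bfs_from(kmer_to_int(ka), a.k, allowed)
        for j, kb in enumerate(sup_b):
            C[i, j] = d.get(kmer_to_int(kb), penalty)
    na, nb = len(sup_a), len(sup_b)
    A_eq = np.zeros((na + nb, na * nb))
    for i in range(na):
        A_eq[i, i * nb : (i + 1) * nb] = 1
    for j in range(nb):
        A_eq[na + j, j::nb] = 1
    b_eq = np.concatenate([[a.mass[km] for km in sup_a],
                           [b.mass[km] for km in sup_b]])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def pairwise_emd(samples: dict[str, KmerDistribution] | list[KmerDistribution],
                 mode: str = "complete") -> DistanceMatrix:
    if isinstance(samples, list):
        samples = {f"S{i}": s for i, s in enumerate(samples)}
    ids = list(samples)
    ks = {samples[s].k for s in ids}
    if len(ks) > 1:
        raise ValueError("all samples must share k")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = emd(samples[ids[i]], samples[ids[j]], mode=mode)
    return DistanceMatrix(ids, d, "emdebruijn")


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------

def ordinate(d: DistanceMatrix, n_axes: int = 3):
    """Classical multidimensional scaling (principal coordinates).

    Eigendecomposition of the double-centred squared-distance matrix;
    axes are ordered by eigenvalue and sign-fixed so the first non-zero
    loading of each axis is positive. Requesting more axes than there
    are positive eigenvalues truncates with a warning flag.
    """
    import pandas as pd

    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D2 = d.values**2
    n = len(d.ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10 if vals.max() > 0 else vals > np.inf
    n_avail = int(pos.sum())
    used = min(n_axes, n_avail)
    coords = vecs[:, :used] * np.sqrt(vals[:used])
    for j in range(used):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    if used < n_axes:
        coords = np.hstack([coords, np.zeros((n, n_axes - used))])
    df = pd.DataFrame(coords, index=d.ids,
                      columns=[f"PC{j+1}" for j in range(n_axes)])
    df.attrs["eigenvalues"] = vals[:n_axes]
    df.attrs["truncated"] = used < n_axes
    return df


def correlate_ordinations(a, b) -> dict:
    """Spearman rank correlation between two ordinations or two distance
    matrices (vectorised upper triangles)."""
    if isinstance(a, DistanceMatrix) and isinstance(b, DistanceMatrix):
        if a.ids != b.ids:
            raise ValueError("distance matrices cover different samples")
        rho, p = spearmanr(a.condensed(), b.condensed())
        return {"rho": float(rho), "p": float(p), "n_pairs": len(a.condensed())}
    if list(a.index) != list(b.index):
        raise ValueError("ordinations cover different samples")
    out = {}
    for ca in a.columns:
        for cb in b.columns:
            rho, p = spearmanr(a[ca], b[cb])
            out[(ca, cb)] = {"rho": float(rho), "p": float(p)}
    return out
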