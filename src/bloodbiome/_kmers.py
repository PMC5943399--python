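"""Low-level 2-bit k-mer encoding shared by the host screen, the marker
index and the reference-free distance.

k-mers are packed into Python ints (2 bits per base, A=0 C=1 G=2 T=3,
most-significant base first). Canonicalisation takes the lexicographic
minimum of a k-mer and its reverse complement, which is the usual
convention for unstranded sequence comparison.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit codes for a sequence; non-ACGT bases map to 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_ints(seq: str, k: int) -> np.ndarray:
    """Packed integers for every window of ``seq`` containing only ACGT.

    Windows touching any other character (e.g. N) are dropped.
    """
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = (codes > 3).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    vals = np.zeros(n, dtype=np.int64)
    safe = np.where(codes > 3, 0, codes).astype(np.int64)
    for j in range(k):
        vals = (vals << 2) | safe[j : j + n]
    return vals[valid]


def revcomp_int(kmer: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (kmer & 3))
        kmer >>= 2
    return out


def canonical_int(kmer: int, k: int) -> int:
    rc = revcomp_int(kmer, k)
    return kmer if kmer <= rc else rc


def canonical_ints(vals: np.ndarray, k: int) -> np.ndarray:
    """Vectorised canonicalisation of packed k-mers."""
    rc = np.zeros_like(vals)
    tmp = np.ascontiguousarray(vals).copy()
    for _ in range(k):  # in-place ops keep temporaries small
        rc <<= 2
        rc |= 3 - (tmp & 3)
        tmp >>= 2
    return np.minimum(vals, rc)


def int_to_kmer(val: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[val & 3])
        val >>= 2
    return "".join(reversed(out))


def kmer_to_int(kmer: str) -> int:
    val = 0
    for c in kmer:
        code = _CODE[ord(c)]
        if code > 3:
            raise ValueError(f"non-ACGT base {c!r} in k-mer {kmer!r}")
        val = (val << 2) | int(code)
    return val


def kmers_batch(seqs: list[str], k: int, canonical: bool = True) -> np.ndarray:
    """Packed k-mers for equal-length sequences, shape (n_reads, L-k+1).

    Reads must be pure ACGT (the synthetic generator guarantees this);
    use :func:`kmer_ints` read-by-read otherwise.
    """
    if not seqs:
        return np.empty((0, 0), dtype=np.int64)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    L = len(seqs[0])
    codes = _CODE[arr].reshape(len(seqs), L).astype(np.int64)
    if (codes > 3).any():
        raise ValueError("kmers_batch requires pure-ACGT sequences")
    W = L - k + 1

    def pack(c: np.ndarray) -> np.ndarray:
        out = c[:, 0:W].copy()
        for j in range(1, k):
            out <<= 2
            out |= c[:, j : j + W]
        return out

    vals = pack(codes)
    if canonical:
        rvals = pack(3 - codes[:, ::-1])[:, ::-1]
        vals = np.minimum(vals, rvals)
    return vals
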