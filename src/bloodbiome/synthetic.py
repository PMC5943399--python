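"""Synthetic study generator.

Produces every input the analysis consumes — taxonomy, marker genes, host
reference, per-sample read sets with a true-origin table, sample design
tables and cell-type proportions — with the statistical structure of a
whole-blood meta-transcriptome cohort: four subject groups (~48 samples
each), ~100,000 candidate non-host reads per sample of which roughly 1%
hit marker genes, 20+ phyla with a strongly dominant one, group-specific
evenness (elevated in one group), and a cell-type proportion negatively
correlated with alpha diversity.

Group alpha-diversity laws
--------------------------
Per-sample phylum compositions are built in three steps:

1. a target inverse-Simpson value is drawn from the group's shifted-gamma
   law ``1 + Gamma(k, theta)``, moment-matched to the group's (mean, SD);
2. a sparse phylum support is drawn (the dominant phylum is always
   present; on average ``mean_phyla`` per sample), plus any "spike"
   phyla forced in at a group-specific presence rate;
3. an evenness tilt ``e`` is solved by bisection so that the composition
   ``p ∝ w_support^(1-e)`` has exactly the target inverse Simpson, and a
   mild Dirichlet jitter is applied on that support.

The shifted-gamma family is used because an index floored at 1 with the
default group moments is necessarily right-skewed; a gamma matches both
moments for every group without leaving the feasible region.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._kmers import BASES, canonical_ints, kmer_ints
from .taxonomy import RANKS, ROOT_ID, Taxonomy, TaxonNode

# Default study conditions: four groups, sizes, alpha-law moments
# (phylum-level inverse Simpson), Table-style age/sex structure,
# phylum-pool sizes (group gamma richness), and presence-spike rates for
# the two designated phyla.
GROUP_DEFAULTS: dict[str, dict] = {
    "Control": dict(n=49, alpha_mean=1.77, alpha_sd=0.74, age=(41.1, 10.7),
                    male_frac=38 / 49, pool_size=20, spike_rate=0.10),
    "SCZ":     dict(n=48, alpha_mean=2.50, alpha_sd=0.79, age=(29.9, 5.8),
                    male_frac=39 / 48, pool_size=23, spike_rate=0.42),
    "BPD":     dict(n=48, alpha_mean=1.55, alpha_sd=0.66, age=(46.5, 9.9),
                    male_frac=20 / 48, pool_size=18, spike_rate=0.05),
    "ALS":     dict(n=47, alpha_mean=1.65, alpha_sd=0.86, age=(56.4, 10.3),
                    male_frac=29 / 47, pool_size=16, spike_rate=0.07),
}
GROUP_ORDER = ("Control", "SCZ", "BPD", "ALS")

DEFAULT_N_PHYLA = 23
DEFAULT_GENERA_PER_PHYLUM = 4
READ_LENGTH = 100
GOOD_PHRED = 35


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerGene:
    marker_id: str
    taxon_id: str  # genus-level leaf
    sequence: str


@dataclass
class AlphaLaw:
    """Shifted-gamma law for per-sample target inverse Simpson."""

    mean: float
    sd: float

    def draw(self, n: int, rng: np.random.Generator, upper: float) -> np.ndarray:
        k = ((self.mean - 1.0) / self.sd) ** 2
        theta = self.sd**2 / (self.mean - 1.0)
        a = 1.0 + rng.standard_gamma(k, n) * theta
        return np.clip(a, 1.02, upper)


@dataclass
class GroupProfile:
    """Generator parameters for one subject group.

    ``concentration`` is a Dirichlet concentration vector over genus-level
    taxa; when ``alpha_law`` is None, :func:`draw_sample_abundances` is a
    plain Dirichlet draw from it. When an alpha law is set, the structured
    three-step draw documented in the module docstring is used instead and
    ``concentration`` supplies the base taxon weights.
    """

    label: str
    concentration: np.ndarray  # over genera, positive
    microbial_fraction: float = 0.012
    expected_marker_hits: float = 1235.0
    alpha_law: AlphaLaw | None = None
    pool_phyla: list[int] | None = None  # phylum indices available to the group
    mean_phyla: float = 4.1
    spike_phyla: list[int] = field(default_factory=list)
    spike_rate: float = 0.0
    support_tilt: float = 0.3  # flattening exponent for presence draws
    jitter: float = 400.0  # Dirichlet concentration of the final jitter

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        if (self.concentration <= 0).any():
            raise ValueError("all Dirichlet concentrations must be > 0")
        if not 0.0 < self.microbial_fraction < 1.0:
            raise ValueError("microbial_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    group: str
    age: float
    sex: str  # "M" / "F"
    rin: float
    batch: str
    lane: str
    rna_concentration: float


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: np.ndarray  # Phred scores, uint8, same length as sequence
    mate: int = 0

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


# --------------------------------------------------------------------------
# taxonomy and markers
# --------------------------------------------------------------------------

def build_taxonomy(n_phyla: int, genera_per_phylum: int, seed: int = 0) -> Taxonomy:
    """A complete 5-rank tree with ``n_phyla * genera_per_phylum`` genera.

    Intermediate class/order/family layers mirror the phylum structure so
    that every genus has a full-depth lineage. Deterministic per seed
    (the seed currently only fixes name suffixes, kept for contract
    stability).
    """
    if n_phyla < 1 or genera_per_phylum < 1:
        raise ValueError("n_phyla and genera_per_phylum must be >= 1")
    nodes: list[TaxonNode] = []
    for p in range(n_phyla):
        phy = f"p{p:02d}"
        nodes.append(TaxonNode(phy, f"phylum_{p:02d}", "phylum", ROOT_ID))
        for g in range(genera_per_phylum):
            # each genus carries its own class/order/family chain so the
            # lowest common ancestor of two genera of a phylum is the phylum
            prev = phy
            for rank in RANKS[1:-1]:
                tid = f"{rank[0]}{p:02d}_{g:02d}"
                nodes.append(TaxonNode(tid, f"{rank}_{p:02d}_{g:02d}", rank, prev))
                prev = tid
            tid = f"g{p:02d}_{g:02d}"
            nodes.append(TaxonNode(tid, f"genus_{p:02d}_{g:02d}", "genus", prev))
    return Taxonomy(nodes)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_markers(
    taxonomy: Taxonomy,
    markers_per_genus: int = 2,
    length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
    k: int = 21,
    max_retries: int = 50,
) -> list[MarkerGene]:
    """Random marker genes, one set per genus, k-mer-unique across genera.

    Any candidate marker sharing a canonical ``k``-mer with a marker of a
    different genus is rejection-resampled, so that the profiler's k-mer
    index maps every marker k-mer to a single genus.
    """
    if not taxonomy.genera:
        raise ValueError("taxonomy has no genus-level leaves")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    markers: list[MarkerGene] = []
    kmer_owner: dict[int, str] = {}
    for genus in taxonomy.genera:
        for m in range(markers_per_genus):
            for attempt in range(max_retries + 1):
                length = int(rng.integers(lo, hi + 1))
                seq = _random_seq(rng, length)
                kms = set(canonical_ints(kmer_ints(seq, k), k).tolist())
                clash = any(kmer_owner.get(km, genus) != genus for km in kms)
                if not clash:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a cross-genus-unique marker for {genus} "
                    f"after {max_retries} retries"
                )
            for km in kms:
                kmer_owner.setdefault(km, genus)
            markers.append(MarkerGene(f"{genus}_m{m}", genus, seq))
    return markers


def simulate_host_reference(length: int = 20000, seed: int = 0) -> str:
    """A random host reference chromosome used by the exclusion screen."""
    return _random_seq(np.random.default_rng(seed), length)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# --------------------------------------------------------------------------
# group profiles and abundance draws
# --------------------------------------------------------------------------

def base_phylum_weights(n_phyla: int = DEFAULT_N_PHYLA, dominant: float = 0.70,
                        decay: float = 0.7) -> np.ndarray:
    """Dominant-phylum composition: w_0 = ``dominant``, geometric tail."""
    tail = decay ** np.arange(n_phyla - 1)
    tail = (1.0 - dominant) * tail / tail.sum()
    return np.concatenate([[dominant], tail])


def default_group_profiles(
    taxonomy: Taxonomy,
    n_phyla: int = DEFAULT_N_PHYLA,
    spike_phyla: tuple[int, int] = (20, 21),
) -> dict[str, GroupProfile]:
    """Profiles for the default four-group study.

    The phylum pool of each group is the ``pool_size`` highest-weight
    phyla plus, for every group, the two spike phyla (whose presence is
    governed by ``spike_rate`` rather than the pool draw).
    """
    w_phy = base_phylum_weights(n_phyla)
    genera = taxonomy.genera
    n_gen = len(genera) // n_phyla
    # genus-level base concentration: phylum weight split unevenly
    w_gen = np.empty(len(genera))
    split = np.array([0.55, 0.25, 0.13, 0.07][:n_gen])
    split = split / split.sum()
    for p in range(n_phyla):
        w_gen[p * n_gen : (p + 1) * n_gen] = w_phy[p] * split
    profiles = {}
    spikes = [s for s in spike_phyla if s < n_phyla]
    regular = [p for p in range(n_phyla) if p not in spikes]
    for g in GROUP_ORDER:
        d = GROUP_DEFAULTS[g]
        # the group's expected richness counts the spike phyla, so the
        # regular pool is pool_size minus the spikes
        n_reg = max(1, min(d["pool_size"] - len(spikes), len(regular)))
        pool = regular[:n_reg] + spikes
        profiles[g] = GroupProfile(
            label=g,
            concentration=w_gen * 3.0,
            alpha_law=AlphaLaw(d["alpha_mean"], d["alpha_sd"]),
            pool_phyla=pool,
            spike_phyla=[s for s in spike_phyla if s < n_phyla],
            spike_rate=d["spike_rate"],
        )
    return profiles


def _solve_evenness_compositions(W: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Row-wise bisection: p_i ∝ W_i^(1-e_i) with inverse Simpson = target.

    ``W`` holds the (masked) support weights per sample; zero entries are
    absent taxa. Inverse Simpson of ``p ∝ w^(1-e)`` is monotone increasing
    in ``e`` (e=1 is uniform over the support), so plain bisection applies.
    """
    mask = W > 0
    logw = np.where(mask, np.log(np.where(mask, W, 1.0)), 0.0)
    lo = np.full(len(W), -16.0)
    hi = np.full(len(W), 1.0)
    for _ in range(48):
        e = 0.5 * (lo + hi)
        p = np.where(mask, np.exp((1.0 - e)[:, None] * logw), 0.0)
        p /= p.sum(axis=1, keepdims=True)
        below = 1.0 / (p**2).sum(axis=1) < targets
        lo = np.where(below, e, lo)
        hi = np.where(below, hi, e)
    e = 0.5 * (lo + hi)
    p = np.where(mask, np.exp((1.0 - e)[:, None] * logw), 0.0)
    return p / p.sum(axis=1, keepdims=True)


def draw_group_phylum_abundances(
    profile: GroupProfile, n_samples: int, n_phyla: int, seed: int
) -> np.ndarray:
    """Phylum-level compositions for ``n_samples`` draws of one group."""
    rng = np.random.default_rng(seed)
    w = base_phylum_weights(n_phyla)
    pool = np.array(profile.pool_phyla if profile.pool_phyla is not None
                    else range(n_phyla))
    targets = profile.alpha_law.draw(n_samples, rng, upper=len(pool) - 0.5)
    K = 1 + rng.poisson(profile.mean_phyla - 1.0, size=n_samples)
    K = np.minimum(np.maximum(K, np.ceil(targets).astype(int) + 1), len(pool))
    W = np.zeros((n_samples, n_phyla))
    W[:, 0] = w[0]
    others = pool[pool != 0]
    pw = w[others] ** profile.support_tilt
    pw = pw / pw.sum()
    for i in range(n_samples):
        idx = rng.choice(others, size=K[i] - 1, replace=False, p=pw)
        W[i, idx] = w[idx]
        for s in profile.spike_phyla:
            if rng.random() < profile.spike_rate:
                W[i, s] = w[s]
    P = _solve_evenness_compositions(W, targets)
    # mild jitter on the realised support
    gam = rng.standard_gamma(profile.jitter * P)
    gam = np.where(W > 0, gam, 0.0)
    return gam / gam.sum(axis=1, keepdims=True)


def draw_sample_abundances(profile: GroupProfile, seed: int,
                           n_phyla: int = DEFAULT_N_PHYLA) -> np.ndarray:
    """One relative-abundance vector over genus-level taxa.

    Plain-Dirichlet mode (``alpha_law is None``) draws directly from
    ``Dirichlet(concentration)``. Structured mode draws a phylum
    composition from the group's alpha law and splits each phylum's mass
    over its genera proportionally to the genus base concentrations.
    """
    rng = np.random.default_rng(seed)
    if profile.alpha_law is None:
        return rng.dirichlet(profile.concentration)
    phy = draw_group_phylum_abundances(profile, 1, n_phyla, seed)[0]
    n_gen = len(profile.concentration) // n_phyla
    out = np.zeros(len(profile.concentration))
    for p in range(n_phyla):
        if phy[p] <= 0:
            continue
        conc = profile.concentration[p * n_gen : (p + 1) * n_gen]
        out[p * n_gen : (p + 1) * n_gen] = phy[p] * rng.dirichlet(conc * 20)
    return out


# --------------------------------------------------------------------------
# design tables
# --------------------------------------------------------------------------

def simulate_design(seed: int = 0, sizes: dict[str, int] | None = None,
                    n_batches: int = 4, n_lanes: int = 8) -> list[SampleDesign]:
    """Sample design table with group-specific age/sex structure."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for g in GROUP_ORDER:
        d = GROUP_DEFAULTS[g]
        n = (sizes or {}).get(g, d["n"])
        for _ in range(n):
            rows.append(SampleDesign(
                sample_id=f"S{i:03d}",
                group=g,
                age=float(np.clip(rng.normal(*d["age"]), 18, 90)),
                sex="M" if rng.random() < d["male_frac"] else "F",
                rin=float(np.clip(rng.normal(8.0, 0.8), 5.0, 10.0)),
                batch=f"b{int(rng.integers(n_batches))}",
                lane=f"L{int(rng.integers(n_lanes))}",
                rna_concentration=float(np.clip(rng.normal(80.0, 25.0), 10.0, None)),
            ))
            i += 1
    return rows


def design_to_frame(designs: list[SampleDesign]):
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(d) for d in designs]).set_index("sample_id")


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------

DEFAULT_READ_KNOBS = dict(
    n_reads=100_000,
    microbial_fraction=0.012,
    host_leak_fraction=0.55,
    low_quality_fraction=0.05,
    low_complexity_fraction=0.05,
    error_rate=0.0,
)

_CATEGORIES = ("microbial", "host", "low_quality", "low_complexity", "unknown")


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = BASES[(BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def simulate_sample_reads(
    design: SampleDesign,
    abundances: np.ndarray,
    markers: list[MarkerGene],
    host_ref: str,
    knobs: dict | None = None,
    seed: int = 0,
):
    """Read set for one sample plus its true-origin table.

    Returns ``(reads, origin)`` where ``origin`` maps read id ->
    ``(category, taxon_id-or-empty)``. Categories: substrings of marker
    genes for taxa drawn proportionally to ``abundances`` (with per-base
    substitution errors), substrings of the host reference, low-quality
    reads (40% of positions at Phred 2–15), low-complexity repeats, and
    uniform-random "unknown" background.
    """
    k = dict(DEFAULT_READ_KNOBS)
    k.update(knobs or {})
    fracs = np.array([k["microbial_fraction"], k["host_leak_fraction"],
                      k["low_quality_fraction"], k["low_complexity_fraction"]])
    if fracs.sum() > 1.0 + 1e-12:
        raise ValueError("category fractions sum to more than 1")
    if k["n_reads"] < 1:
        raise ValueError("n_reads must be >= 1")
    if k["microbial_fraction"] > 0 and not markers:
        raise ValueError("microbial_fraction > 0 requires a non-empty marker set")

    rng = np.random.default_rng(seed)
    n = int(k["n_reads"])
    probs = np.concatenate([fracs, [1.0 - fracs.sum()]])
    counts = rng.multinomial(n, probs)

    abundances = np.asarray(abundances, dtype=float)
    by_taxon: dict[str, list[MarkerGene]] = {}
    for m in markers:
        by_taxon.setdefault(m.taxon_id, []).append(m)
    taxa = sorted(by_taxon)
    if markers:
        if len(abundances) != len(taxa):
            raise ValueError("abundance vector length does not match marker taxa")
        p_taxa = abundances / abundances.sum() if abundances.sum() > 0 else None

    L = READ_LENGTH
    reads: list[ReadRecord] = []
    origin: dict[str, tuple[str, str]] = {}
    good_q = np.full(L, GOOD_PHRED, dtype=np.uint8)

    def add(category: str, seq: str, qual: np.ndarray, taxon: str = "") -> None:
        rid = f"{design.sample_id}_r{len(reads):06d}"
        reads.append(ReadRecord(rid, seq, qual))
        origin[rid] = (category, taxon)

    for _ in range(counts[0]):  # microbial
        t = taxa[int(rng.choice(len(taxa), p=p_taxa))]
        m = by_taxon[t][int(rng.integers(len(by_taxon[t])))]
        start = int(rng.integers(0, max(1, len(m.sequence) - L + 1)))
        seq = _mutate(m.sequence[start : start + L].ljust(L, "A"), rng, k["error_rate"])
        add("microbial", seq, good_q, t)
    for _ in range(counts[1]):  # host leak
        start = int(rng.integers(0, len(host_ref) - L + 1))
        add("host", host_ref[start : start + L], good_q)
    for _ in range(counts[2]):  # low quality
        qual = good_q.copy()
        pos = rng.choice(L, size=int(0.4 * L), replace=False)
        qual[pos] = rng.integers(2, 16, size=len(pos))
        add("low_quality", _random_seq(rng, L), qual)
    for _ in range(counts[3]):  # low complexity
        if rng.random() < 0.5:
            seq = BASES[int(rng.integers(4))] * L
        else:
            a, b = rng.choice(4, size=2, replace=False)
            seq = (BASES[a] + BASES[b]) * (L // 2)
        add("low_complexity", seq, good_q)
    for _ in range(counts[4]):  # unknown background
        add("unknown", _random_seq(rng, L), good_q)

    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm], origin


def write_fastq(reads: list[ReadRecord], path) -> None:
    """Sanger (Phred+33) FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_origin_table(origin: dict[str, tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\ttaxon_id\n")
        for rid in sorted(origin):
            cat, tax = origin[rid]
            fh.write(f"{rid}\t{cat}\t{tax}\n")


def write_design_table(designs: list[SampleDesign], path) -> None:
    cols = ["sample_id", "group", "age", "sex", "rin", "batch", "lane",
            "rna_concentration"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in designs:
            fh.write("\t".join(str(getattr(d, c)) for c in cols) + "\n")


# --------------------------------------------------------------------------
# cell proportions
# --------------------------------------------------------------------------

CELL_TYPES = ("CD8_memory", "CD8_naive", "CD4T", "NK", "Bcell", "Granulocyte")


def simulate_cell_proportions(
    alpha_values: np.ndarray,
    target_correlation: float = -0.41,
    n_celltypes: int = 6,
    seed: int = 0,
    tolerance: float = 0.1,
    max_retries: int = 40,
):
    """Cell-type proportion table whose first column tracks alpha.

    The designated cell type's proportion is built from a noisy linear
    transform of standardised alpha so that its empirical correlation with
    ``alpha_values`` lands within ``tolerance`` of ``target_correlation``;
    remaining mass is split over the other cell types by a Dirichlet draw.
    Rows are non-negative and sum to one.
    """
    alpha_values = np.asarray(alpha_values, dtype=float)
    if not np.isfinite(alpha_values).all():
        raise ValueError("alpha values must be finite")
    if n_celltypes < 2:
        raise ValueError("need at least two cell types")
    if not -1.0 < target_correlation < 1.0:
        raise ValueError("target correlation must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    n = len(alpha_values)
    z = (alpha_values - alpha_values.mean()) / max(alpha_values.std(), 1e-12)
    rho = target_correlation
    for _ in range(max_retries):
        x = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        p_des = np.clip(0.15 + 0.05 * x, 0.01, 0.60)
        with np.errstate(invalid="ignore"):
            got = np.corrcoef(p_des, alpha_values)[0, 1]
        if np.isfinite(got) and abs(got - rho) <= tolerance:
            break
    else:
        raise RuntimeError("could not attain the requested correlation")
    # moderately dispersed rest-shares: the remaining mass must not act as
    # a near-deterministic proxy of the designated proportion, or partial
    # correlations adjusted for the other cell types would be attenuated
    rest = rng.dirichlet(np.full(n_celltypes - 1, 2.0), size=n)
    table = np.column_stack([p_des, rest * (1.0 - p_des)[:, None]])
    return table


def write_cell_table(table: np.ndarray, sample_ids: list[str], path,
                     names: tuple[str, ...] = CELL_TYPES) -> None:
    names = names[: table.shape[1]]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(names) + "\n")
        for sid, row in zip(sample_ids, table):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
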