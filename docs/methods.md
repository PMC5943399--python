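# Methods

This note documents the models and procedures implemented in
`bloodbiome`, the assumptions behind them, the parameters that matter,
and what the synthetic-data generator does and does not emulate.

## Candidate-read filtering

Host-unmapped reads are processed in a fixed stage order: sub-sampling,
quality filter, complexity filter, (optional) exact-sequence
deduplication, host k-mer screen.

- **Sub-sampling before filtering.** Depth normalisation (default
  100,000 reads) precedes the quality stages. Filtering first and then
  sub-sampling would equalise *final* depth instead; we keep
  normalisation first so that downstream per-sample totals reflect the
  same amount of raw evidence. Samples smaller than the target depth are
  kept whole and flagged rather than dropped.
- **Quality.** A read is kept iff at least `min_frac` (default 0.8) of
  its bases have Phred ≥ `q` (default 20). This is a per-read predicate,
  so its position relative to the complexity stage affects per-stage
  counts but never the final candidate set (a property the tests
  assert).
- **Complexity.** A DUST-style statistic: over each window the score is
  `Σ_t c_t(c_t−1)/2 / 62` for overlapping-triplet counts `c_t`.
  Sequences up to 128 bases are scored as a single window (a 100-base
  homopolymer scores (98·97/2)/62 ≈ 76.7); longer sequences take the
  maximum over sliding 128-base windows with 64-base step. The default
  threshold of 7 sits far above the score of random or genic sequence
  (≈ 1.2 expected for a random 100-mer) and far below any simple repeat
  (a dinucleotide repeat scores ≈ 38), so the classification is
  effectively deterministic for reads of the simulated kinds.
- **Host screen.** Instead of a seeded aligner we use an exact screen:
  a read is removed iff it shares more than `max_shared` (default 2)
  canonical 21-mers with the host reference index. For desk-scale host
  references this is deterministic, dependency-free and stricter than an
  aligner; the threshold of 2 tolerates isolated chance collisions.
  An empty host index keeps all reads and warns, since there is nothing
  to screen against.
- **Deduplication** (exact sequence, first occurrence kept) is exposed
  but off by default: the upstream definition of "unique" reads is not
  settled, and the synthetic data contains no duplication process.

## Marker-gene profiling

Markers are indexed by canonical k-mers (k = 21 by default; k ≥ 11
enforced so random 100-mer collisions stay negligible). A read is
assigned to a genus when markers of exactly one genus share at least
`min_hits` (default 2, suppressing single-k-mer collisions) k-mers with
it; hits in several genera fall back to the lowest common ancestor of
the hit taxa, and reads with no qualifying marker stay unassigned. This
is deliberately a containment-plus-LCA scheme, not phylogenetic
placement: the statistics layer only requires a per-taxon read-count
contract, and abundances are read-count proportions without any
copy-number or genome-size correction.

Abundance tables carry counts, relative abundances over *assigned* reads
(each row sums to 1), and per-sample unassigned totals. Alpha diversity
is computed over assigned mass only; samples with fewer than 10 assigned
reads are flagged low-confidence but not excluded. Externally produced
profiler tables (pipe-separated, rank-prefixed taxon paths with a
relative-abundance column per sample) can be ingested directly; their
abundances are renormalised per sample at the extracted rank, so tables
printed on a percentage scale or with overlapping ranks enter the
statistics layer on the same footing.

## Diversity

- alpha: inverse Simpson `1/Σ pᵢ²`, scale-free (counts and proportions
  give identical values), bounded by `[1, richness]`.
- beta: Bray-Curtis on **relative** abundances, so residual depth
  differences between samples do not masquerade as community turnover
  after the fixed-depth design.
- gamma: count of taxa with positive abundance in at least one sample of
  a group. No detection threshold beyond abundance > 0 is applied.

## Reference-free distance (k-mer EMD)

Each sample is summarised by its normalised k-mer mass distribution
(default k = 6; 4,096 possible k-mers; configurable 4–12). The distance
between samples is the earth mover's distance under a ground metric on
k-mers: shortest-path hop count in the order-k de Bruijn graph over
{A,C,G,T}, undirected, connecting each k-mer to its single-shift
successors and predecessors.

Because the ground metric is a graph metric, the optimal transport cost
equals the minimum-cost flow on the graph itself with node demands equal
to the mass differences. We solve that flow with a network simplex on
integerised demands (scale 10⁹; the rounding residue, at most half a
unit per atom, is folded into the largest atom), which makes the result
exact to ~10⁻⁹ and avoids the quadratic-size transportation LP. The unit
tests verify agreement with an independent dense LP to 10⁻⁶ and the
metric axioms on random instances.

Two graph modes exist. `complete` (default) uses the full 4^k-node
graph: distances are always finite and the triangle inequality holds by
construction. `observed` restricts to the union support and charges a
flat k+1 hops between disconnected components; it is provided for
sensitivity analysis. Both are interpretations of an under-specified
construction rather than re-implementations of any particular tool.
Canonical (reverse-complement-merged) k-mers are off by default, which
matches stranded RNA-seq; a flag enables merging.

Ordination is classical multidimensional scaling (principal coordinates)
of the double-centred squared-distance matrix, axes ordered by
eigenvalue, each axis sign-fixed so its first non-zero loading is
positive. Requesting more axes than there are positive eigenvalues
truncates with a flag.

## Statistics

- **Normalised alpha** is, by default, the rank-based inverse-normal
  transform `Φ⁻¹((rank−0.5)/n)` with average ranks for ties — robust to
  the strong right skew of the inverse Simpson index; a plain z-score is
  available by flag (and is measurably less powerful on skewed alpha).
- **Group contrasts** come from a linear model of normalised alpha on
  group plus covariates (sex, age, RIN, batch, lane, RNA concentration;
  batch/lane categorical). The target group is the treatment reference,
  so each coefficient is a target-vs-other contrast; Bonferroni is over
  the number of contrasts. A rank-deficient design is an error naming
  the aliased columns; the pipeline orchestrator opts into automatic
  dropping (flagged) because tiny smoke-scale runs are deliberately
  over-parameterised.
- **Nagelkerke ΔR²**: `R² = (1 − exp(2(ll₀−ll₁)/n)) / (1 − exp(2ll₀/n))`
  with `ll₀` the intercept-only log-likelihood; ΔR² is full minus
  alpha-free reduced model. Separation triggers a BFGS and then an
  L2-penalised fallback, both flagged in the result.
- **PERMANOVA**: pseudo-F from squared-distance sums
  (`SS_total = Σ_{i<j} d²ᵢⱼ/N`, within-group sums divided by group
  size), p from label permutations with the add-one estimator, so p is
  never 0 and its minimum is 1/(1+n_perm). 1,000 permutations by
  default, deterministic per seed. The implementation is verified
  against an explicit two-loop oracle and against scikit-bio.
- **Presence tests**: per-taxon 2×K exact tests. Conditional on margins
  the cell counts are multivariate hypergeometric; the two-sided p sums
  the probabilities of all tables no more probable than the observed one
  (the probability-ordering convention of the classical exact test),
  enumerated over the K−1 free cells. For K = 2 this reproduces the
  standard two-sided Fisher test; the 2×4 implementation agrees with R's
  `fisher.test` to seven digits on the tables it is used for. The
  Bonferroni multiplier is the number of taxa observed in the data.
- **Beta pair-groups**: off-diagonal distances are partitioned into
  within-A, within-B and between; category means are compared by label
  permutation with pairs recomputed per permutation, which respects the
  dependence between pairs sharing a sample. A literal pair-level linear
  model is intentionally not the default, because pairs are not
  independent observations.
- **Cell-proportion association**: for each cell type, alpha and the
  proportion are residualised on the covariates plus all other cell
  types; since proportions sum to one, the last other type is dropped
  from the adjustment set. Pearson correlation of residuals with
  Bonferroni over cell types.

## Synthetic-study generator

The generator is the package's test bed and defines its default study
conditions: four groups (Control 49, SCZ 48, BPD 48, ALS 47), 100,000
reads per sample with 1.2% marker-derived, 55% residual host, 5%
low-quality, 5% low-complexity and the rest uniform-random background;
2×100 bp read geometry with flat Phred 35 for clean reads and 40% of
positions at Phred 2–15 for planted low-quality reads (chosen so the
quality filter's decision is exact, which the tests exploit); age and
sex distributions differing by group as in the cohort being emulated;
RIN, batch, lane and concentration as null technical covariates.

Phylum compositions are built per sample in three steps:

1. a target inverse Simpson is drawn from the group's shifted-gamma law
   `1 + Gamma(k, θ)`, moment-matched to the group's (mean, SD) defaults
   of (1.77, 0.74), (2.50, 0.79), (1.55, 0.66), (1.65, 0.86). A gamma is
   the natural two-moment family here: an index floored at 1 with these
   moments is necessarily right-skewed, and for the most dispersed group
   no truncated-normal law can reach the target SD at all.
2. a sparse support is drawn: the dominant phylum (base weight 0.70,
   geometric tail, emulating one phylum at ~73% relative abundance) is
   always present; on average ~4 phyla per sample; each group draws from
   its own phylum pool sized so that group richness lands at 20/23/18/16;
   two designated "spike" phyla join the support at group-specific rates
   (0.10/0.42/0.05/0.07), creating the presence/absence signal the exact
   tests detect.
3. an evenness tilt `e` is solved by per-sample bisection so the
   composition `p ∝ w^(1−e)` over the support has exactly the target
   inverse Simpson, followed by a mild Dirichlet(400·p) jitter. Realised
   group moments match the law to better than 1%.

Phylum mass is split over genera by a within-phylum Dirichlet. Marker
genes are random sequences (300–1,500 bases) rejection-resampled until no
canonical 21-mer is shared across genera, so profiler assignment is
unambiguous by construction. Cell proportions place a designated cell
type at `clip(0.15 + 0.05·x, 0.01, 0.6)` where `x` is a noisy linear
transform of standardised alpha targeting the requested correlation
(retrying until the empirical correlation is within ±0.1); the remaining
mass is split Dirichlet(2.0) — deliberately dispersed, because
near-deterministic rest shares would proxy the designated proportion and
attenuate covariate-adjusted partial correlations.

What the generator does **not** emulate: sequencing-error models trained
on real data, rRNA and library-preparation chemistry, duplicated reads,
insert-size structure (mates are independent substrings), phylogenetic
signal in marker sequences, or any true covariate effect on diversity.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated structure, not robustness to
real-data artefacts.

## Numerical and design choices

- All generators and permutation tests are bit-reproducible given their
  seed; the pipeline derives per-stage seeds from one global seed by
  CRC32 of "seed:stage", so stages are reproducible independently of
  execution order.
- The EMD integerisation scale (10⁹) bounds the flow-vs-exact error by
  ~10⁻⁹ × graph diameter; the LP cross-check tolerance is 10⁻⁶.
- Two-cluster PERMANOVA fixtures use 12 + 12 samples: with smaller
  clusters a sampled permutation reproduces the exact two-cluster
  partition often enough (probability 2/C(n, n/2) per draw) that the
  minimal p-value is visibly not attained.
- The ΔR²-recovery experiment uses a logistic slope of 0.4041 on a
  standard-normal predictor, calibrated once by bisection at n = 4·10⁵
  so the population Nagelkerke ΔR² is 0.0500.
- Test and acceptance problem sizes (e.g. 20,000-read planted samples in
  unit tests, 100,000 reads in the full-depth checks, 50 replicate
  studies for power, 200 null datasets × 199 permutations for PERMANOVA
  calibration) were chosen as the smallest sizes at which the measured
  quantities are stable to well within their tolerance bands.

## Known limitations

- Marker assignment has no notion of sequence similarity beyond exact
  k-mer sharing; highly diverged homologs of a marker would go
  unassigned. This is by design (the profiling contract, not the
  classifier, is the subject of the package).
- The joint event "all three group contrasts significant at 0.005" has
  probability ≈ 0.88–0.89 under the default alpha laws at these sample
  sizes; single-cohort findings of that form should be expected to
  fluctuate under replication at the same n, and the acceptance
  experiments report the measured rate rather than forcing it.
- Exact 2×K enumeration is feasible for the group counts used here
  (≤ ~50 per group, K ≤ ~6); much larger tables would need the network
  algorithm or simulation.
- The `observed` EMD mode's disconnection penalty (k+1) is a convention;
  distances between samples with fragmented shared support depend on it.
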