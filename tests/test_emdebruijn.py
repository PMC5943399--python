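"""k-mer distributions, the de Bruijn ground metric, exact EMD against a
linear-program oracle, and principal-coordinate ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from bloodbiome import emdebruijn as em
from bloodbiome._kmers import int_to_kmer
from bloodbiome.diversity import DistanceMatrix


def lp_oracle(a, b):
    """Dense transportation LP on the joint support (independent route)."""
    sa, sb = sorted(a.mass), sorted(b.mass)
    C = np.array([[em.ground_distance(u, v) for v in sb] for u in sa])
    na, nb = len(sa), len(sb)
    A = np.zeros((na + nb, na * nb))
    for i in range(na):
        A[i, i * nb:(i + 1) * nb] = 1
    for j in range(nb):
        A[na + j, j::nb] = 1
    beq = np.array([a.mass[u] for u in sa] + [b.mass[v] for v in sb])
    res = linprog(C.ravel(), A_eq=A, b_eq=beq, bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def rand_dist(rng, k=4, support=6):
    kms = rng.choice(4**k, size=support, replace=False)
    mass = rng.dirichlet(np.ones(support))
    return em.KmerDistribution(k, {int_to_kmer(int(v), k): float(p)
                                   for v, p in zip(kms, mass)})


class TestKmerCounts:
    def test_two_window_read(self):
        d = em.kmer_counts(["ACGTA"], 4)
        assert d.mass == {"ACGT": 0.5, "CGTA": 0.5}

    def test_n_windows_skipped(self):
        with pytest.raises(ValueError):
            em.kmer_counts(["ACGNA"], 4)

    def test_total_mass_one(self):
        rng = np.random.default_rng(0)
        reads = ["".join("ACGT"[i] for i in rng.integers(0, 4, 50)) for _ in range(20)]
        d = em.kmer_counts(reads, 5)
        assert sum(d.mass.values()) == pytest.approx(1.0, abs=1e-12)

    def test_canonical_merges_reverse_complements(self):
        d = em.kmer_counts(["AAAA", "TTTT"], 4, canonical=True)
        assert d.mass == {"AAAA": 1.0}

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            em.kmer_counts(["ACGT"], 1)


class TestGroundDistance:
    def test_identity(self):
        assert em.ground_distance("ACGT", "ACGT") == 0

    def test_single_shift(self):
        assert em.ground_distance("ACGT", "CGTA") == 1

    def test_matches_full_graph_bfs_oracle(self):
        import networkx as nx
        g = nx.Graph()
        for v in range(256):
            for nb in em._neighbors(v, 4):
                if nb != v:
                    g.add_edge(v, nb)
        lengths = dict(nx.single_source_shortest_path_length(g, 0))  # "AAAA"
        rng = np.random.default_rng(1)
        for v in rng.choice(256, size=40, replace=False):
            expect = 0 if v == 0 else lengths[int(v)]
            assert em.ground_distance("AAAA", int_to_kmer(int(v), 4)) == expect

    def test_opposite_homopolymers(self):
        d = em.ground_distance("AAAA", "TTTT")
        assert d <= 4

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            u, v, w = (int_to_kmer(int(x), 4) for x in rng.integers(0, 256, 3))
            duv = em.ground_distance(u, v)
            assert duv == em.ground_distance(v, u)
            assert duv <= em.ground_distance(u, w) + em.ground_distance(w, v)
            assert (duv == 0) == (u == v)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            em.ground_distance("ACGT", "ACGTA")


class TestEMD:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(3)
        a = rand_dist(rng)
        assert em.emd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_point_masses_one_shift(self):
        a = em.KmerDistribution(4, {"ACGT": 1.0})
        b = em.KmerDistribution(4, {"CGTA": 1.0})
        assert em.emd(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_matches_lp_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rand_dist(rng, support=int(rng.integers(2, 9)))
            b = rand_dist(rng, support=int(rng.integers(2, 9)))
            assert em.emd(a, b) == pytest.approx(lp_oracle(a, b), abs=1e-6)

    def test_disjoint_supports_at_constant_distance(self):
        # all mass moves over exactly one hop: EMD = 1
        a = em.KmerDistribution(4, {"AAAA": 0.5, "CCCC": 0.5})
        b = em.KmerDistribution(4, {"AAAC": 0.5, "CCCA": 0.5})
        for u in a.mass:
            for v in b.mass:
                assert em.ground_distance(u, v) >= 1
        assert em.emd(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_scale_consistency(self):
        reads = ["ACGTACG", "TTGCATG"]
        d1 = em.kmer_counts(reads, 4)
        d2 = em.kmer_counts(reads * 7, 4)
        assert d1.mass == d2.mass

    def test_k_mismatch_rejected(self):
        a = em.KmerDistribution(4, {"ACGT": 1.0})
        b = em.KmerDistribution(5, {"ACGTA": 1.0})
        with pytest.raises(ValueError):
            em.emd(a, b)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            a, b, c = (rand_dist(rng, support=4) for _ in range(3))
            assert em.emd(a, b) <= em.emd(a, c) + em.emd(c, b) + 1e-7

    def test_observed_mode_close_to_complete_on_dense_support(self):
        rng = np.random.default_rng(6)
        a = rand_dist(rng, support=12)
        b = rand_dist(rng, support=12)
        # observed-subgraph distances are >= complete-graph distances
        assert em.emd(a, b, mode="observed") >= em.emd(a, b) - 1e-9


class TestPairwiseEMD:
    def test_symmetric_and_matches_per_pair(self):
        rng = np.random.default_rng(7)
        samples = {f"S{i}": rand_dist(rng, support=5) for i in range(4)}
        dm = em.pairwise_emd(samples)
        assert np.allclose(dm.values, dm.values.T, atol=1e-9)
        for i, si in enumerate(dm.ids):
            for j, sj in enumerate(dm.ids):
                if i < j:
                    assert dm.values[i, j] == pytest.approx(
                        em.emd(samples[si], samples[sj]), abs=1e-9)

    def test_duplicate_sample_zero(self):
        rng = np.random.default_rng(8)
        a = rand_dist(rng)
        dm = em.pairwise_emd({"x": a, "y": a})
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestOrdination:
    def test_three_collinear_points(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                            "test")
        coords = em.ordinate(dm, 1)
        assert np.allclose(sorted(coords["PC1"]), [-1, 0, 1], atol=1e-9)

    def test_zero_matrix(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)), "test")
        coords = em.ordinate(dm, 2)
        assert np.allclose(coords.values, 0.0)
        assert coords.attrs["truncated"]

    def test_euclidean_embedding_recovered(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import cdist
        dm = DistanceMatrix([f"s{i}" for i in range(8)], cdist(pts, pts), "test")
        coords = em.ordinate(dm, 3)
        rec = cdist(coords.values, coords.values)
        assert np.allclose(rec, dm.values, atol=1e-6)

    def test_sign_convention(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                            "test")
        col = em.ordinate(dm, 1)["PC1"].values
        nz = col[np.abs(col) > 1e-12]
        assert nz[0] > 0


class TestCorrelations:
    def test_identical_matrices_rho_one(self):
        rng = np.random.default_rng(10)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], m, "x")
        out = em.correlate_ordinations(dm, dm)
        assert out["rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(6)]
        a = DistanceMatrix(ids, m, "x")
        b = DistanceMatrix(ids, m**3, "y")
        assert em.correlate_ordinations(a, b)["rho"] == pytest.approx(1.0)

    def test_independent_matrices_low_rho(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            mats = []
            for _ in range(2):
                m = rng.random((50, 50))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                mats.append(m)
            ids = [f"s{i}" for i in range(50)]
            rho = em.correlate_ordinations(
                DistanceMatrix(ids, mats[0], "x"),
                DistanceMatrix(ids, mats[1], "y"))["rho"]
            hits += abs(rho) < 0.2
        assert hits >= 0.95 * n_rep

    def test_sample_mismatch_rejected(self):
        a = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "x")
        b = DistanceMatrix(["a", "c"], np.array([[0, 1], [1, 0]], float), "y")
        with pytest.raises(ValueError):
            em.correlate_ordinations(a, b)


class TestGroupSeparation:
    def test_two_marker_pools_separate_on_axis_one(self, small_taxonomy):
        """Samples drawn from disjoint marker pools split along PC1."""
        from bloodbiome import synthetic as syn
        pools = [syn.simulate_markers(small_taxonomy, 1, (300, 400), seed=s)
                 for s in (100, 200)]
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            dists, labels = {}, {}
            for gi, pool in enumerate(pools):
                seqs = [m.sequence for m in pool]
                for s in range(5):
                    reads = []
                    for _ in range(60):
                        src = seqs[rng.integers(len(seqs))]
                        start = rng.integers(0, len(src) - 100 + 1)
                        reads.append(src[start:start + 100])
                    sid = f"g{gi}_s{s}"
                    dists[sid] = em.kmer_counts(reads, 4)
                    labels[sid] = gi
            dm = em.pairwise_emd(dists)
            coords = em.ordinate(dm, 1)
            lab = np.array([labels[s] for s in coords.index])
            x = coords["PC1"].values
            from sklearn.metrics import silhouette_score
            wins += silhouette_score(x.reshape(-1, 1), lab) > 0
        assert wins >= 0.9 * n_rep
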