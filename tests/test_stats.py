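"""Inferential layer: normalisation, adjusted contrasts, Nagelkerke R²,
beta pair-group comparison, PERMANOVA, exact presence tests, ordination
association and cell-proportion partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, kstest, norm

from bloodbiome import stats as st
from bloodbiome import synthetic as syn
from bloodbiome.diversity import DistanceMatrix


def make_design(n_per_group=25, seed=0, groups=("A", "B")):
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group):
            rows.append(dict(sample_id=f"{g}{i}", group=g,
                             age=rng.normal(40, 10), sex=rng.choice(["M", "F"]),
                             rin=rng.normal(8, 0.5), batch=f"b{rng.integers(3)}",
                             lane=f"L{rng.integers(4)}",
                             rna_concentration=rng.normal(80, 20)))
    return pd.DataFrame(rows).set_index("sample_id")


class TestNormalizeAlpha:
    def test_mean_zero(self):
        rng = np.random.default_rng(0)
        z = st.normalize_alpha(rng.gamma(2, 1, size=101))
        assert abs(z.mean()) < 1e-9

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 1, size=50)
        assert np.allclose(st.normalize_alpha(x), st.normalize_alpha(np.exp(x)))

    def test_five_point_quantiles(self):
        got = st.normalize_alpha([10.0, 20.0, 30.0, 40.0, 50.0])
        assert np.allclose(got, norm.ppf([0.1, 0.3, 0.5, 0.7, 0.9]), atol=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            st.normalize_alpha([1.0, 2.0])


class TestAlphaGroupContrasts:
    def test_null_type_one_error_calibrated(self):
        # identical groups: rejection at 0.05 stays inside the binomial CI
        design = make_design(30, seed=5)
        n_sim = 200
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(n_sim):
            alpha = pd.Series(rng.gamma(2, 1, size=len(design)), index=design.index)
            res = st.alpha_group_contrasts(alpha, design, "A")
            rejections += res.pvalues["B"] < 0.05
        # binomial 95% CI around 0.05 at 200 sims
        assert 3 <= rejections <= 18

    def test_null_covariate_estimate_near_zero(self):
        design = make_design(150, seed=2)
        rng = np.random.default_rng(3)
        alpha = pd.Series(rng.gamma(2, 1, size=len(design)), index=design.index)
        res = st.alpha_group_contrasts(alpha, design, "A")
        assert abs(res.estimates["age"]) < 0.05  # ~3 SE at this n

    def test_adjusted_p_at_least_raw(self, study_taxonomy):
        design = syn.design_to_frame(syn.simulate_design(seed=1))
        profiles = syn.default_group_profiles(study_taxonomy)
        rng = np.random.default_rng(4)
        alpha = {}
        for g in syn.GROUP_ORDER:
            ids = design.index[design.group == g]
            P = syn.draw_group_phylum_abundances(profiles[g], len(ids), 23,
                                                 int(rng.integers(2**31)))
            alpha.update({s: 1 / (row**2).sum() for s, row in zip(ids, P)})
        res = st.alpha_group_contrasts(pd.Series(alpha).loc[design.index],
                                       design, "SCZ")
        for g in res.pvalues:
            assert res.adjusted_pvalues[g] >= res.pvalues[g] - 1e-15
            assert 0 <= res.pvalues[g] <= 1

    def test_rank_deficient_design_names_column(self):
        design = make_design(20, seed=6)
        design["rna_concentration"] = design["age"] * 2.0  # aliased
        alpha = pd.Series(np.linspace(1, 3, len(design)), index=design.index)
        with pytest.raises(ValueError, match="rna_concentration"):
            st.alpha_group_contrasts(alpha, design, "A")


class TestLogisticDeltaR2:
    def test_null_delta_near_zero_large_n(self):
        design = make_design(2500, seed=8)
        rng = np.random.default_rng(9)
        alpha = pd.Series(rng.gamma(2, 1, size=len(design)), index=design.index)
        labels = pd.Series((design["group"] == "B").astype(int), index=design.index)
        res = st.logistic_delta_r2(labels, alpha, design)
        assert abs(res.r2["delta"]) < 0.01

    def test_intercept_only_r2_zero(self):
        assert st.nagelkerke_r2(-10.0, -10.0, 50) == pytest.approx(0.0)

    def test_signal_detected(self):
        design = make_design(100, seed=10)
        rng = np.random.default_rng(11)
        z = rng.standard_normal(len(design))
        y = (rng.random(len(design)) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
        res = st.logistic_delta_r2(pd.Series(y, index=design.index),
                                   pd.Series(np.exp(z), index=design.index), design)
        assert res.r2["delta"] > 0.1
        assert res.pvalues["alpha"] < 1e-4

    def test_single_class_rejected(self):
        design = make_design(10, seed=12)
        alpha = pd.Series(np.linspace(1, 2, len(design)), index=design.index)
        with pytest.raises(ValueError):
            st.logistic_delta_r2(pd.Series(1, index=design.index), alpha, design)


class TestBetaPairGroups:
    def test_category_sizes(self):
        rng = np.random.default_rng(13)
        n, nA = 12, 5
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * nA + ["B"] * (n - nA), index=ids)
        dm = DistanceMatrix(ids, m, "x")
        out = st.beta_pair_groups(dm, labels, n_perm=49, seed=0)
        iu = np.triu_indices(n, 1)
        lab = (labels.values == "B").astype(int)
        assert np.isfinite(list(out["means"].values())).all()
        nB = n - nA
        # counts per category
        li, lj = lab[iu[0]], lab[iu[1]]
        assert ((li == 0) & (lj == 0)).sum() == nA * (nA - 1) // 2
        assert ((li == 1) & (lj == 1)).sum() == nB * (nB - 1) // 2
        assert (li != lj).sum() == nA * nB

    def test_identical_groups_equal_means(self):
        rng = np.random.default_rng(14)
        n = 30
        pts = rng.normal(size=(n, 4))
        from scipy.spatial.distance import cdist
        m = cdist(pts, pts)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A", "B"] * (n // 2), index=ids)
        out = st.beta_pair_groups(DistanceMatrix(ids, m, "x"), labels,
                                  n_perm=99, seed=1)
        means = list(out["means"].values())
        assert max(means) - min(means) < 0.2 * np.mean(means)
        assert all(p > 0.01 for p in out["pvalues"].values())

    def test_block_structure_detected(self):
        n, nA = 16, 8
        m = np.full((n, n), 0.9)
        m[:nA, :nA] = 0.1
        m[nA:, nA:] = 0.1
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * nA + ["B"] * (n - nA), index=ids)
        out = st.beta_pair_groups(DistanceMatrix(ids, m, "x"), labels,
                                  n_perm=999, seed=2)
        assert out["means"]["between"] > out["means"]["within_A"]
        assert out["pvalues"]["within_A_vs_between"] <= 0.002

    def test_tiny_group_flagged(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        labels = pd.Series(["A", "B", "B"], index=ids)
        out = st.beta_pair_groups(DistanceMatrix(ids, m, "x"), labels,
                                  n_perm=9, seed=0)
        assert out["flags"]


class TestPermanova:
    def test_f_matches_two_loop_oracle(self):
        rng = np.random.default_rng(15)
        n = 8
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=ids)
        res = st.permanova(DistanceMatrix(ids, m, "x"), labels, n_perm=9, seed=0)
        # explicit double-loop sums of squares
        lab = np.array([0] * 4 + [1] * 4)
        ss_t = sum(m[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g, size in ((0, 4), (1, 4)):
            idx = np.where(lab == g)[0]
            ss_w += sum(m[i, j] ** 2 for ii, i in enumerate(idx)
                        for j in idx[ii + 1:]) / size
        f_expected = ((ss_t - ss_w) / 1) / (ss_w / (n - 2))
        assert res.pseudo_f == pytest.approx(f_expected, rel=1e-12)

    def test_two_tight_clusters_attain_minimal_p(self):
        # 10+10 so a sampled permutation reproducing the exact two-cluster
        # partition (which would tie the observed F) is vanishingly rare
        n = 20
        m = np.full((n, n), 5.0)
        m[:10, :10] = 0.01
        m[10:, 10:] = 0.01
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=ids)
        res = st.permanova(DistanceMatrix(ids, m, "x"), labels, n_perm=999, seed=3)
        assert res.permutation_p == pytest.approx(1 / 1000)

    def test_deterministic_per_seed_and_reorder_invariant(self):
        rng = np.random.default_rng(16)
        n = 10
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=ids)
        dm = DistanceMatrix(ids, m, "x")
        r1 = st.permanova(dm, labels, n_perm=199, seed=4)
        r2 = st.permanova(dm, labels, n_perm=199, seed=4)
        assert r1.permutation_p == r2.permutation_p
        perm = list(rng.permutation(n))
        dm2 = DistanceMatrix([ids[i] for i in perm], m[np.ix_(perm, perm)], "x")
        r3 = st.permanova(dm2, labels, n_perm=199, seed=4)
        assert r3.pseudo_f == pytest.approx(r1.pseudo_f, rel=1e-12)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(17)
        n = 14
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = ["A"] * 7 + ["B"] * 7
        res = st.permanova(DistanceMatrix(ids, m, "x"),
                           pd.Series(labels, index=ids), n_perm=99, seed=0)
        sk = skbio_permanova(skbio.DistanceMatrix(m, ids), grouping=labels,
                             permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_degenerate_groups_rejected(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        with pytest.raises(ValueError):
            st.permanova(DistanceMatrix(ids, m, "x"),
                         pd.Series(["A", "A", "B"], index=ids), n_perm=9, seed=0)


class TestFisherExact2xK:
    def test_two_group_case_matches_scipy(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            totals = rng.integers(2, 12, size=2)
            present = np.array([rng.integers(0, t + 1) for t in totals])
            mine = st.fisher_exact_2xk((present, totals))
            table = np.array([present, totals - present])
            _, expected = fisher_exact(table)
            assert mine == pytest.approx(expected, abs=1e-9)

    def test_tiny_enumeration(self):
        assert st.fisher_exact_2xk(((1, 1), (2, 2))) == pytest.approx(1.0)

    def test_four_group_tables_match_verified_oracle(self):
        # values cross-checked against R 4.3 fisher.test to 7 digits
        p1 = st.fisher_exact_2xk(((5, 20, 2, 3), (49, 48, 48, 47)))
        assert p1 == pytest.approx(1.036061e-06, rel=1e-5)
        p2 = st.fisher_exact_2xk(((6, 20, 3, 6), (49, 48, 48, 47)))
        assert p2 == pytest.approx(6.326545e-05, rel=1e-5)
        # the same counts permuted across groups give the same p
        assert st.fisher_exact_2xk(((20, 6, 3, 6), (48, 47, 48, 49))) == \
            pytest.approx(p2, rel=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact_2xk(((3,), (5,)))
        with pytest.raises(ValueError):
            st.fisher_exact_2xk(((6, 1), (5, 5)))


class TestBonferroni:
    def test_values(self):
        assert st.bonferroni(0.01, 5) == pytest.approx(0.05)
        assert st.bonferroni(0.5, 23) == 1.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            st.bonferroni(1.5, 2)


class TestPresenceTests:
    def test_spiked_taxon_flagged(self, study_taxonomy):
        from bloodbiome.profiling import AbundanceTable
        profiles = syn.default_group_profiles(study_taxonomy)
        rows, labels = [], {}
        rng = np.random.default_rng(19)
        for g, n in [("Control", 49), ("SCZ", 48), ("BPD", 48), ("ALS", 47)]:
            P = syn.draw_group_phylum_abundances(profiles[g], n, 23,
                                                 int(rng.integers(2**31)))
            for i, row in enumerate(P):
                sid = f"{g}{i}"
                rows.append(pd.Series(row, name=sid))
                labels[sid] = g
        rel = pd.DataFrame(rows)
        rel.columns = study_taxonomy.at_rank("phylum")
        table = AbundanceTable("phylum", rel)
        out = st.presence_tests(table, pd.Series(labels))
        spiked = study_taxonomy.at_rank("phylum")[20]
        assert out.loc[spiked, "p"] < 0.01
        assert (out["p_bonferroni"] >= out["p"] - 1e-15).all()


class TestOrdinationAssociation:
    def test_axis_driven_labels_detected(self):
        design = make_design(60, seed=20)
        rng = np.random.default_rng(21)
        coords = pd.DataFrame(rng.standard_normal((len(design), 3)),
                              index=design.index, columns=["PC1", "PC2", "PC3"])
        logits = 2.5 * coords["PC1"].values
        y = pd.Series((rng.random(len(design)) < 1 / (1 + np.exp(-logits))).astype(int),
                      index=design.index)
        res = st.ordination_association(coords, y, design)
        assert res.pvalues["PC1"] < 0.001
        assert res.r2["delta"] >= 0

    def test_joint_delta_at_least_single_axis(self):
        design = make_design(50, seed=22)
        rng = np.random.default_rng(23)
        coords = pd.DataFrame(rng.standard_normal((len(design), 3)),
                              index=design.index, columns=["PC1", "PC2", "PC3"])
        y = pd.Series(rng.integers(0, 2, len(design)), index=design.index)
        joint = st.ordination_association(coords, y, design, n_axes=3)
        single = st.ordination_association(coords[["PC1"]], y, design, n_axes=1)
        assert joint.r2["delta"] >= single.r2["delta"] - 1e-9


class TestCellProportionAssociation:
    def test_planted_negative_correlation_recovered(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            alpha = pd.Series(1 + rng.gamma(2.0, 0.5, 65),
                              index=[f"s{i}" for i in range(65)])
            table = pd.DataFrame(
                syn.simulate_cell_proportions(alpha.values, -0.41, 6, seed=seed),
                index=alpha.index, columns=list(syn.CELL_TYPES))
            out = st.cell_proportion_association(alpha, table, design=None,
                                                 covariates=())
            r = out.loc["CD8_memory", "partial_r"]
            hits += -0.55 < r < -0.25
        assert hits >= 0.9 * n_rep

    def test_independent_cell_type_null(self):
        rng = np.random.default_rng(24)
        alpha = pd.Series(1 + rng.gamma(2.0, 0.5, 65),
                          index=[f"s{i}" for i in range(65)])
        table = pd.DataFrame(
            syn.simulate_cell_proportions(alpha.values, 0.0, 6, seed=25),
            index=alpha.index, columns=list(syn.CELL_TYPES))
        out = st.cell_proportion_association(alpha, table, design=None,
                                             covariates=())
        assert abs(out.loc["CD8_memory", "partial_r"]) < 0.25

    def test_empty_covariates_reduce_to_plain_correlation(self):
        rng = np.random.default_rng(26)
        alpha = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        two = rng.dirichlet([3, 3], size=40)
        table = pd.DataFrame(two, index=alpha.index, columns=["c1", "c2"])
        out = st.cell_proportion_association(alpha, table, design=None,
                                             covariates=())
        from scipy.stats import pearsonr
        # adjustment set for c1 is empty (the single other type is dropped)
        r, _ = pearsonr(alpha, table["c1"])
        assert out.loc["c1", "partial_r"] == pytest.approx(r, abs=1e-9)


class TestPermanovaNullCalibration:
    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(27)
        n = 16
        pvals = []
        for _ in range(60):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            ids = [f"s{i}" for i in range(n)]
            labels = pd.Series(rng.permutation(["A"] * 8 + ["B"] * 8), index=ids)
            res = st.permanova(DistanceMatrix(ids, m, "x"), labels,
                               n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res.permutation_p)
        assert kstest(pvals, "uniform").pvalue > 0.01
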