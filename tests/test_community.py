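"""Distance statistics: oracle equivalences, null behavior, planted signals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from scentsel import (
    ScentMatrix,
    bray_curtis,
    cap_ordination,
    euclidean_1d,
    group_tests,
    mantel_spearman,
    permanova_nested,
    rf_distinctness,
)


def _matrix(arr, ids=None, cols=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"s{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    return ScentMatrix(pd.DataFrame(arr, index=ids, columns=cols))


class TestDistances:
    def test_bray_curtis_hand_values(self):
        m = _matrix([[2, 1], [1, 1], [1, 0], [0, 1]])
        d = bray_curtis(m)
        assert d["s0", "s1"] == pytest.approx(0.2)   # (1+0)/(3+2)
        assert d["s2", "s3"] == pytest.approx(1.0)   # disjoint
        assert d["s0", "s0"] == 0.0

    def test_bray_curtis_bounded_unit_interval(self, rng):
        m = _matrix(rng.uniform(0, 3, size=(10, 6)))
        d = np.asarray(bray_curtis(m).data)
        assert (d >= 0).all() and (d <= 1).all()

    def test_bray_curtis_two_all_zero_rows_rejected(self):
        m = _matrix([[0, 0], [0, 0], [1, 2]])
        with pytest.raises(ValueError):
            bray_curtis(m)

    def test_euclidean_1d_matches_pairwise_loop(self):
        v = pd.Series([3.0, 7.0, 5.0, 5.0], index=list("abcd"))
        d = euclidean_1d(v)
        assert d["a", "b"] == 4.0
        assert d["c", "d"] == 0.0
        for i, j in itertools.combinations(v.index, 2):
            assert d[i, j] == pytest.approx(abs(v[i] - v[j]))


def oracle_permanova_f(d: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from within/between squared distances (independent
    of the projection-trace implementation)."""
    n = len(groups)
    labels = np.unique(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(labels)
    if ss_within <= 1e-12:
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_exact_enumeration_matches_oracle_tail_fraction(self, rng):
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        for trial in range(20):
            x = rng.normal(size=(6, 3))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
            res = permanova_nested(dm, groups, method="exact")
            # oracle: enumerate the 20 distinct assignments by brute force
            f_obs = oracle_permanova_f(d, groups)
            fs = []
            for pos in itertools.combinations(range(6), 3):
                g = np.array(["g2"] * 6, dtype=object)
                for i in pos:
                    g[i] = "g1"
                fs.append(oracle_permanova_f(d, g))
            p_oracle = np.mean(np.asarray(fs) >= f_obs - 1e-12)
            assert res.table.loc["region", "p"] == pytest.approx(p_oracle)
            assert res.table.loc["region", "pseudo_F"] == pytest.approx(
                f_obs, abs=1e-8
            )

    def test_one_factor_euclidean_equals_classical_anova(self, rng):
        y = pd.Series(rng.normal(size=15), index=[f"s{i}" for i in range(15)])
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = permanova_nested(euclidean_1d(y), groups, n_perm=9, seed=0)
        f_classic = f_oneway(y[:5], y[5:10], y[10:]).statistic
        assert res.table.loc["region", "pseudo_F"] == pytest.approx(
            f_classic, abs=1e-8
        )

    def test_pseudo_f_matches_skbio_one_way(self, rng):
        x = rng.normal(size=(14, 4))
        x[:7] += 0.8
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(14)])
        groups = ["a"] * 7 + ["b"] * 7
        mine = permanova_nested(dm, groups, n_perm=9, seed=0)
        ref = skbio_permanova(
            dm, pd.DataFrame({"g": groups}, index=dm.ids), column="g",
            permutations=9,
        )
        assert mine.table.loc["region", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-10
        )

    def test_perfect_separation_captures_all_signal(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        res = permanova_nested(dm, ["g1"] * 3 + ["g2"] * 3, method="exact")
        assert res.table.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc["region", "p"] == pytest.approx(2 / 20)

    def test_nested_partition_dfs_and_determinism(self, small_study):
        d = bray_curtis(small_study.scent)
        pops = small_study.samples["population"]
        # two populations in two regions -> region absorbs population: use a
        # richer design
        pops4 = pd.Series(
            np.where(np.arange(50) % 2 == 0, pops + "_x", pops + "_y"),
            index=pops.index,
        )
        r1 = permanova_nested(d, small_study.samples["region"], pops4,
                              n_perm=99, seed=5)
        r2 = permanova_nested(d, small_study.samples["region"], pops4,
                              n_perm=99, seed=5)
        tab = r1.table
        assert tab.loc["region", "df"] == 1
        assert tab.loc["population(region)", "df"] == 2
        assert tab["df"].sum() == small_study.scent.n_samples - 1
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_singleton_population_rejected(self):
        d = DistanceMatrix(np.abs(np.subtract.outer(range(5), range(5))).astype(float),
                           ids=list("abcde"))
        with pytest.raises(ValueError, match="singleton"):
            permanova_nested(d, ["n"] * 5, ["p1", "p1", "p2", "p2", "p3"])


class TestMantel:
    def test_identity_and_monotone_transform_give_rho_one(self, rng):
        x = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d1 = DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(8)])
        rho, _ = mantel_spearman(d1, d1, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        d2 = DistanceMatrix(np.asarray(d1.data) ** 2, ids=d1.ids)
        rho2, _ = mantel_spearman(d1, d2, n_perm=99, seed=0)
        assert rho2 == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        from scipy.spatial.distance import pdist, squareform

        a = squareform(pdist(rng.normal(size=(9, 3))))
        b = squareform(pdist(rng.normal(size=(9, 3))))
        ids = [f"s{i}" for i in range(9)]
        rho, _ = mantel_spearman(
            DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids),
            n_perm=99, seed=0,
        )
        ref, _, _ = skbio_mantel(
            DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids),
            method="spearman", permutations=0,
        )
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from scipy.stats import kstest

        ids = [f"s{i}" for i in range(10)]
        ps = []
        for k in range(60):
            a = squareform(pdist(rng.normal(size=(10, 2))))
            b = squareform(pdist(rng.normal(size=(10, 2))))
            _, p = mantel_spearman(
                DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids),
                n_perm=199, seed=k,
            )
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_size_mismatch_rejected(self):
        d1 = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        d2 = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            mantel_spearman(d1, d2)


class TestCAP:
    def test_planted_compound_attains_max_vector_correlation(self, rng):
        x = rng.lognormal(0, 0.3, size=(24, 6))
        x[:12, 3] *= 8
        m = _matrix(x)
        res = cap_ordination(bray_curtis(m), ["a"] * 12 + ["b"] * 12, compounds=m)
        assert res.vectors["max_abs_r"].idxmax() == "c3"
        assert bool(res.vectors.loc["c3", "selected"])

    def test_identical_centroids_leading_eigenvalue_near_zero(self, rng):
        x = rng.lognormal(0, 0.4, size=(20, 5))
        m = _matrix(x)
        d = bray_curtis(m)
        strong = cap_ordination(d, ["a"] * 10 + ["b"] * 10)
        null = cap_ordination(d, ["a", "b"] * 10)
        # alternating labels give near-identical centroids
        assert null.constrained_eigenvalues[0] < 0.25 * np.trace(
            np.cov(np.asarray(d.data))
        ) + strong.constrained_eigenvalues[0]
        assert null.constrained_eigenvalues[0] < 0.2

    def test_eigenvalues_non_negative(self, rng):
        m = _matrix(rng.lognormal(0, 0.5, size=(15, 8)))
        res = cap_ordination(bray_curtis(m), ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert (res.constrained_eigenvalues >= 0).all()
        assert (res.unconstrained_eigenvalues >= 0).all()

    def test_single_group_rejected(self, rng):
        m = _matrix(rng.lognormal(0, 0.5, size=(6, 3)))
        with pytest.raises(ValueError):
            cap_ordination(bray_curtis(m), ["a"] * 6)


class TestRandomForest:
    def test_separable_classes_low_oob(self, rng):
        x = rng.lognormal(0, 0.2, size=(30, 5))
        x[:15, 2] += 10  # disjoint ranges on one compound
        res = rf_distinctness(_matrix(x), ["a"] * 15 + ["b"] * 15,
                              ntree=300, mtry=3, seed=0)
        assert res.oob_error < 5.0

    def test_permuted_labels_chance_level(self, rng):
        x = rng.lognormal(0, 0.5, size=(40, 10))
        labels = np.array(["a", "b"] * 20)
        rng.shuffle(labels)
        res = rf_distinctness(_matrix(x), labels, ntree=300, mtry=3, seed=0)
        assert 25.0 <= res.oob_error <= 75.0

    def test_planted_compound_ranks_first(self, rng):
        wins = 0
        for k in range(10):
            x = rng.lognormal(0, 0.4, size=(30, 8))
            x[:15, 4] *= 6
            res = rf_distinctness(_matrix(x), ["a"] * 15 + ["b"] * 15,
                                  ntree=200, mtry=3, seed=k)
            wins += res.importance.idxmax() == "c4"
        assert wins >= 9

    def test_mtry_clamped_with_warning(self, rng):
        x = rng.lognormal(0, 0.4, size=(12, 3))
        with pytest.warns(UserWarning, match="clamped"):
            rf_distinctness(_matrix(x), ["a"] * 6 + ["b"] * 6,
                            ntree=50, mtry=17, seed=0)


class TestGroupTests:
    def test_identical_groups_u_at_null_mean(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                      index=[f"s{i}" for i in range(6)])
        reg = pd.Series(["north"] * 3 + ["south"] * 3, index=v.index)
        out = group_tests(v, reg)
        assert out["mannwhitney"]["U"] == pytest.approx(4.5)  # n1*n2/2
        assert out["mannwhitney"]["p"] == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_extreme_u(self):
        v = pd.Series([1, 2, 3, 4, 5, 10, 11, 12, 13, 14], dtype=float,
                      index=[f"s{i}" for i in range(10)])
        reg = pd.Series(["north"] * 5 + ["south"] * 5, index=v.index)
        u = group_tests(v, reg)["mannwhitney"]["U"]
        assert u in (0.0, 25.0)

    def test_nested_anova_matches_sequential_projection(self, rng):
        v = pd.Series(rng.normal(size=24), index=[f"s{i}" for i in range(24)])
        reg = pd.Series(["n"] * 12 + ["s"] * 12, index=v.index)
        pop = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6,
                        index=v.index)
        v[reg == "n"] += 1.2
        tab = group_tests(v, reg, pop)["anova"]
        assert tab.loc["region", "df"] == 1
        assert tab.loc["population(region)", "df"] == 2
        assert tab.loc["residual", "df"] == 20
        # region SS equals the classical between-groups SS
        gm = v.mean()
        ss_region = sum(
            len(v[reg == g]) * (v[reg == g].mean() - gm) ** 2 for g in ("n", "s")
        )
        assert tab.loc["region", "sum_sq"] == pytest.approx(ss_region)

    def test_one_population_per_region_rejected(self):
        v = pd.Series(np.arange(8, dtype=float), index=[f"s{i}" for i in range(8)])
        reg = pd.Series(["n"] * 4 + ["s"] * 4, index=v.index)
        pop = pd.Series(["A"] * 4 + ["B"] * 4, index=v.index)
        with pytest.raises(ValueError, match="zero degrees"):
            group_tests(v, reg, pop)
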