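"""WISH network construction: adjacency, TOM, tree cut, eigenSNPs, GMAT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from wishnet.genotypes import GenotypeMatrix
from wishnet.gwas import scan
from wishnet.wish import (Gmat, ModuleSet, _scale_free_r2, adjacency,
                          detect_modules, eigensnp, gmat, nan_corr,
                          preselect_snps, scale_free_fit, select_modules, tom)


def tom_bruteforce(a):
    """Triple-loop oracle for the topological overlap measure."""
    a = np.asarray(a, dtype=float)
    m = len(a)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    t = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(m) if u not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            t[i, j] = (l + a[i, j]) / denom if denom > 1e-12 else 0.0
    return t


def planted_block_genotypes(rng, n_animals=75, block_sizes=(60, 60),
                            within_r=0.9, n_noise=0):
    """Continuous 'dosage-like' columns in correlated blocks (the network
    stages only see correlations, so Gaussian columns are a fair stand-in)."""
    cols, labels = [], []
    for b, size in enumerate(block_sizes):
        latent = rng.normal(size=n_animals)
        lam = np.sqrt(within_r)
        for _ in range(size):
            cols.append(lam * latent
                        + np.sqrt(1 - lam ** 2) * rng.normal(size=n_animals))
            labels.append(b + 1)
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_animals))
        labels.append(0)
    return np.column_stack(cols), np.array(labels)


class TestAdjacency:
    def test_duplicated_snp_has_unit_adjacency_for_any_power(self):
        x = np.random.default_rng(0).normal(size=20)
        X = np.column_stack([x, x])
        for g in (1, 2, 5, 7):
            assert adjacency(X, g)[0, 1] == pytest.approx(1.0)

    def test_half_correlation_fifth_power(self):
        a = 0.5 ** 5
        assert a == 0.03125  # the arithmetic the adjacency applies
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 2))
        X[:, 1] = 0.5 * X[:, 0] + np.sqrt(0.75) * X[:, 1]
        got = adjacency(X, 5)[0, 1]
        assert got == pytest.approx(np.abs(np.corrcoef(X.T)[0, 1]) ** 5)

    def test_bounds_symmetry_and_power_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            X = rng.normal(size=(rng.integers(10, 30), rng.integers(3, 9)))
            a1 = adjacency(X, 2)
            a2 = adjacency(X, 4)
            assert np.allclose(a1, a1.T)
            assert a1.min() >= 0 and a1.max() <= 1
            assert (a2 <= a1 + 1e-12).all()  # raising gamma never increases
            assert np.diag(a1).max() == 0.0

    def test_zero_variance_column_zeroed(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        a = adjacency(X, 2)
        assert a[0, 1] == 0.0

    def test_nan_corr_pairwise_complete_matches_pandas(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        X[rng.random(X.shape) < 0.15] = np.nan
        got = nan_corr(X)
        want = pd.DataFrame(X).corr(min_periods=1).to_numpy()
        assert got == pytest.approx(want, abs=1e-10)


class TestTom:
    def test_fully_connected_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        # l = 1, k = 2 -> t = (1+1)/(2+1-1) = 1 everywhere
        assert tom(a) == pytest.approx(np.ones((3, 3)))

    def test_empty_graph(self):
        t = tom(np.zeros((4, 4)))
        assert t == pytest.approx(np.eye(4))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            m = rng.integers(3, 9)
            a = rng.random((m, m))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert tom(a) == pytest.approx(tom_bruteforce(a), abs=1e-12)

    def test_rejects_asymmetric_or_out_of_range(self):
        with pytest.raises(ValueError):
            tom(np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            tom(np.array([[0.0, 1.5], [1.5, 0.0]]))


class TestScaleFree:
    def test_exact_power_law_bins_fit_perfectly(self):
        # counts inversely proportional to the bin-center k: log p is an
        # exact affine function of log k over equal-width bins
        centers = np.array([0.5, 1.5, 2.5, 3.5, 4.5])
        counts = (630 / (2 * np.arange(5) + 1)).astype(int)  # 630/(2b+1)
        k = np.repeat(centers, counts)
        r2, slope = _scale_free_r2(k, n_bins=5)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert slope < 0

    def test_degenerate_connectivity_is_na(self):
        r2, slope = _scale_free_r2(np.full(100, 3.0), n_bins=10)
        assert np.isnan(r2)

    def test_fit_reproducible_and_block_data_reaches_high_r2(self):
        rng = np.random.default_rng(5)
        X, _ = planted_block_genotypes(rng, n_animals=75,
                                       block_sizes=(40, 30), n_noise=60)
        t1, g1 = scale_free_fit(X)
        t2, g2 = scale_free_fit(X)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["fit_index"].max() > 0.5

    def test_needs_enough_snps(self):
        with pytest.raises(ValueError, match="50"):
            scale_free_fit(np.random.default_rng(0).normal(size=(20, 10)))


class TestPreselect:
    @staticmethod
    def _scan_result(X, y):
        g = GenotypeMatrix([f"a{i}" for i in range(len(X))], X)
        return scan(pd.Series(y, index=g.animal_ids), g), g

    def test_p_max_one_keeps_all_markers(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.5, size=(30, 8)).astype(float)
        res, g = self._scan_result(X, rng.normal(size=30))
        sub, meta = preselect_snps(res, g, g.animal_ids, p_max=1.01, top_n=100)
        assert sub.n_markers == 8 and "warning" in meta

    def test_hand_computed_connectivity_ranking(self):
        # |r| row sums (1.8, 1.0, 1.4) over m-1=2 -> k = (0.9, 0.5, 0.7)
        absr = np.array([[0.0, 0.7, 1.1], [0.7, 0.0, 0.3], [1.1, 0.3, 0.0]])
        k = absr.sum(axis=0) / 2
        assert k == pytest.approx([0.9, 0.5, 0.7])
        order = np.lexsort((np.arange(3), -k))
        assert list(order[:2]) == [0, 2]  # SNPs 1 and 3 kept

    def test_duplicated_snp_tie_breaks_by_index(self):
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.5, size=(40, 4)).astype(float)
        X = np.column_stack([base[:, 0], base[:, 0], base[:, 1:]])
        y = X[:, 0] * 0.8 + rng.normal(size=40)
        res, g = self._scan_result(X, y)
        sub1, _ = preselect_snps(res, g, g.animal_ids, p_max=1.01, top_n=3)
        sub2, _ = preselect_snps(res, g, g.animal_ids, p_max=1.01, top_n=3)
        assert list(sub1.marker_ids) == list(sub2.marker_ids)
        # the duplicated pair has identical k; the lower index is kept first
        assert "m0" in sub1.marker_ids

    def test_empty_animal_subset_raises(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.5, size=(30, 5)).astype(float)
        res, g = self._scan_result(X, rng.normal(size=30))
        with pytest.raises(ValueError):
            preselect_snps(res, g, [])


class TestModules:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(9)
        X, truth = planted_block_genotypes(rng)
        t = tom(adjacency(X, 5))
        mods = detect_modules(1.0 - t, min_size=50)
        ari = adjusted_rand_score(truth, mods.labels)
        assert ari >= 0.95
        assert len(mods.module_labels) == 2

    def test_degenerate_dissimilarity_single_module(self):
        d = np.full((60, 60), 0.5)
        np.fill_diagonal(d, 0.0)
        mods = detect_modules(d, min_size=50)
        assert set(mods.labels) <= {0, 1}
        assert "note" in mods.metadata

    def test_min_size_larger_than_blocks_unassigned(self):
        rng = np.random.default_rng(10)
        X, _ = planted_block_genotypes(rng, block_sizes=(20, 20))
        t = tom(adjacency(X, 5))
        mods = detect_modules(1.0 - t, min_size=50)
        assert (mods.labels == 0).all()

    def test_fewer_snps_than_min_size(self):
        mods = detect_modules(np.zeros((5, 5)), min_size=50)
        assert (mods.labels == 0).all()


class TestEigensnp:
    @staticmethod
    def _modules_for(X, labels):
        ids = np.array([f"s{j}" for j in range(X.shape[1])], dtype=object)
        g = GenotypeMatrix([f"a{i}" for i in range(len(X))], X,
                           marker_names=ids)
        mods = ModuleSet(ids, np.asarray(labels), min_size=2)
        return g, mods

    def test_identical_columns_explain_everything(self):
        col = np.tile([0.0, 1.0, 2.0, 1.0, 0.0, 2.0], 3)[:18]
        X = np.column_stack([col, col, col])
        g, mods = self._modules_for(X, [1, 1, 1])
        mods = eigensnp(g, mods)
        assert mods.var_explained["M1"] == pytest.approx(1.0)
        z = (col - col.mean()) / col.std()
        score = mods.eigensnps["M1"].to_numpy()
        assert np.corrcoef(score, z)[0, 1] == pytest.approx(1.0)

    def test_two_snp_module_variance_is_half_one_plus_r(self):
        rng = np.random.default_rng(11)
        X = rng.binomial(2, 0.5, size=(200, 2)).astype(float)
        g, mods = self._modules_for(X, [1, 1])
        mods = eigensnp(g, mods)
        r = abs(np.corrcoef(X.T)[0, 1])
        assert mods.var_explained["M1"] == pytest.approx((1 + r) / 2, abs=1e-10)

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.binomial(2, 0.4, size=(50, 7)).astype(float)
        g, mods = self._modules_for(X, [1] * 7)
        mods = eigensnp(g, mods)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        w, v = np.linalg.eigh(np.cov(Z, rowvar=False, ddof=0))
        assert mods.var_explained["M1"] == pytest.approx(
            w[-1] / w.sum(), abs=1e-8)
        score = Z @ v[:, -1]
        got = mods.eigensnps["M1"].to_numpy()
        assert abs(np.corrcoef(score, got)[0, 1]) == pytest.approx(1, abs=1e-8)

    def test_zero_variance_module_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        g, mods = self._modules_for(X, [1, 1])
        with pytest.raises(ValueError, match="module 1"):
            eigensnp(g, mods)


class TestGmat:
    @staticmethod
    def _frame(cols, ids):
        return pd.DataFrame(cols, index=ids)

    def test_eigensnp_duplicated_as_trait_gives_unit_mtr(self):
        rng = np.random.default_rng(13)
        ids = [f"a{i}" for i in range(30)]
        e = rng.normal(size=30)
        gm = gmat(self._frame({"M1": e}, ids),
                  self._frame({"OI": e, "other": rng.normal(size=30)}, ids))
        assert gm.mtr.loc["M1", "OI"] == pytest.approx(1.0)
        assert gm.p.loc["M1", "OI"] < 1e-12

    def test_student_p_matches_pearsonr(self):
        rng = np.random.default_rng(14)
        ids = [f"a{i}" for i in range(75)]
        e = rng.normal(size=75)
        y = 0.5 * e + rng.normal(size=75)
        gm = gmat(self._frame({"M1": e}, ids), self._frame({"OI": y}, ids))
        r_ref, p_ref = stats.pearsonr(e, y)
        assert gm.mtr.loc["M1", "OI"] == pytest.approx(r_ref, rel=1e-12)
        assert gm.p.loc["M1", "OI"] == pytest.approx(p_ref, rel=1e-9)

    def test_moderate_correlation_at_n75_is_significant(self):
        # r ~ 0.51 at n = 75 -> t ~ 5.07, far below the 0.001 rule
        n = 75
        t_stat = 0.51 * np.sqrt(n - 2) / np.sqrt(1 - 0.51 ** 2)
        assert t_stat == pytest.approx(5.07, abs=0.01)
        p = 2 * stats.t.sf(t_stat, n - 2)
        assert p < 1e-3

    def test_independent_noise_trait_stays_below_mtr_threshold(self):
        rng = np.random.default_rng(15)
        ids = [f"a{i}" for i in range(75)]
        e = rng.normal(size=75)
        below = sum(
            abs(np.corrcoef(e, rng.normal(size=75))[0, 1]) < 0.4
            for _ in range(200))
        assert below >= 198  # ~99%+ of independent traits stay below 0.4

    def test_selection_rule_uses_absolute_secondary_mtr(self):
        ids = [f"a{i}" for i in range(40)]
        rng = np.random.default_rng(16)
        e = rng.normal(size=40)
        other = -0.9 * e + 0.1 * rng.normal(size=40)  # strongly negative
        gm = gmat(pd.DataFrame({"M1": e}, index=ids),
                  pd.DataFrame({"OI": e + 0.01 * rng.normal(size=40),
                                "trait": other}, index=ids))
        assert select_modules(gm, p_oi_max=0.001, mtr_other_min=0.4) == ["M1"]

    def test_too_few_animals_raises(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError, match="at least 4"):
            gmat(pd.DataFrame({"M1": [1.0, 2.0, 3.0]}, index=ids),
                 pd.DataFrame({"OI": [1.0, 2.0, 3.0]}, index=ids))
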