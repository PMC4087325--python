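"""Genetic correctness of the synthetic F2 intercross generator."""

import numpy as np
import pandas as pd
import pytest

from wishnet.genotypes import GeneticMap
from wishnet.simdata import (ConfigError, QtlCluster, SimConfig, TraitSpec,
                             build_map, haldane_c, meiosis, simulate_cross,
                             simulate_founders)
from conftest import toy_config


def bootstrap_corr_se(x, y, rng, n_boot=300):
    """Bootstrap (over animals) standard error of a sample correlation."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    num = (xb * yb).sum(axis=1)
    den = np.sqrt((xb ** 2).sum(axis=1) * (yb ** 2).sum(axis=1))
    return float(np.std(num / den, ddof=1))


def two_marker_map(d_cm, same_chrom=True):
    chrom = ["1", "1"] if same_chrom else ["1", "2"]
    cm = [1.0, 1.0 + d_cm] if same_chrom else [1.0, 1.0]
    bp = [1_000_000, max(int((1.0 + d_cm) * 1e6), 1_000_001)]
    return GeneticMap(np.array(chrom, dtype=object),
                      np.array(["a", "b"], dtype=object),
                      np.array(bp), np.array(cm))


class TestFounders:
    def test_fixed_divergent_cluster_forces_alternative_alleles(self):
        cfg = toy_config()
        out = simulate_founders(cfg)
        gmap = out["map"]
        idx = gmap.chrom_indices("1")
        # oi_qtl is fixed: every line-A chromosome all 1, line B all 0
        cl = [c for c in cfg.clusters if c.name == "oi_qtl"][0]
        start = np.searchsorted(gmap.cm[idx], cl.start_cm)
        sel = idx[start:start + cl.n_markers]
        assert (out["haplotypes"]["A"][:, sel] == 1).all()
        assert (out["haplotypes"]["B"][:, sel] == 0).all()

    def test_zero_divergence_lines_share_frequency_profile(self):
        # no clusters, divergence 0: realized line frequency difference is
        # pure binomial noise ~ sqrt(2 p (1-p) / n_hap)
        cfg = SimConfig(n_founders_per_line=400, n_f1=2, n_f2=2,
                        n_chromosomes=2, markers_per_chrom=100,
                        divergence=0.0, clusters=(), seed=3)
        out = simulate_founders(cfg)
        fa = out["haplotypes"]["A"].mean(axis=0)
        fb = out["haplotypes"]["B"].mean(axis=0)
        diff = np.abs(fa - fb)
        p = (fa + fb) / 2
        se = np.sqrt(2 * p * (1 - p) / 800)
        # E|diff| = sqrt(2/pi) * se; allow a generous factor on the mean
        assert diff.mean() < 2.0 * np.sqrt(2 / np.pi) * se.mean()
        assert diff.mean() < 0.05

    def test_invalid_counts_raise(self):
        with pytest.raises(ConfigError):
            SimConfig(n_f2=0)
        with pytest.raises(ConfigError):
            SimConfig(missing_rate=1.0)


class TestMeiosis:
    def test_map_mismatch_raises(self):
        gmap = two_marker_map(10)
        with pytest.raises(ValueError, match="cover"):
            meiosis(np.zeros((2, 3), dtype=np.int8), gmap,
                    np.random.default_rng(0))

    def test_zero_distance_never_recombines(self):
        gmap = two_marker_map(1e-9)
        hap = np.array([[1, 1], [0, 0]], dtype=np.int8)
        rng = np.random.default_rng(0)
        for _ in range(300):
            g = meiosis(hap, gmap, rng)
            assert g[0] == g[1]

    @pytest.mark.parametrize("d_cm,same_chrom,expected_c", [
        (50.0, True, haldane_c(50.0)),   # (1 - e^-1)/2 ~ 0.3161
        (20.0, True, haldane_c(20.0)),
        (0.0, False, 0.5),               # independent assortment
    ])
    def test_recombination_fraction_matches_haldane(self, d_cm, same_chrom,
                                                    expected_c):
        gmap = two_marker_map(d_cm, same_chrom)
        hap = np.array([[1, 1], [0, 0]], dtype=np.int8)
        rng = np.random.default_rng(42)
        n = 10_000
        rec = sum(int(g[0] != g[1]) for g in
                  (meiosis(hap, gmap, rng) for _ in range(n)))
        se = np.sqrt(expected_c * (1 - expected_c) / n)
        assert abs(rec / n - expected_c) < 3 * se


class TestCross:
    def test_f1_heterozygous_at_fixed_loci(self, small_sim):
        sim = small_sim
        idx = sim.cluster_marker_indices("oi_qtl")
        f1_rows = np.flatnonzero(
            (sim.pedigree["generation"] == "F1").to_numpy())
        assert (sim.true_dosages[np.ix_(f1_rows, idx)] == 1).all()

    def test_f2_mendelian_segregation_at_fixed_locus(self, small_sim):
        sim = small_sim
        j = sim.cluster_marker_indices("oi_qtl")[0]
        f2 = np.flatnonzero((sim.pedigree["generation"] == "F2").to_numpy())
        d = sim.true_dosages[f2, j]
        counts = np.array([(d == k).sum() for k in (0, 1, 2)])
        from scipy.stats import chisquare
        stat, p = chisquare(counts, counts.sum() * np.array([0.25, 0.5, 0.25]))
        assert p > 0.01
        assert abs(d.mean() / 2 - 0.5) < 3 * np.sqrt(0.5 * 0.5 / (2 * len(d)))

    def test_dosage_values_and_mask_rate(self, small_sim):
        g = small_sim.genotypes
        obs = g.dosages[~np.isnan(g.dosages)]
        assert set(np.unique(obs)) <= {0.0, 1.0, 2.0}
        rate = g.missing_mask.mean()
        target = small_sim.config.missing_rate
        se = np.sqrt(target * (1 - target) / g.missing_mask.size)
        assert abs(rate - target) < 3 * se

    def test_pedigree_structure(self, small_sim):
        ped = small_sim.pedigree.set_index("animal_id")
        gen = ped["generation"]
        for aid, row in ped[gen == "F2"].iterrows():
            assert gen[row["sire"]] == "F1" and gen[row["dam"]] == "F1"
        for aid, row in ped[gen == "F1"].iterrows():
            assert gen[row["sire"]] == "F0" and gen[row["dam"]] == "F0"

    def test_ld_decay_follows_haldane(self, small_sim):
        """F2 dosage correlation between fixed-divergent loci ~ 1 - 2c.

        The SE is bootstrapped over animals: dosages are discrete, so the
        Gaussian (Fisher) approximation understates the sampling variance.
        """
        sim = small_sim
        idx = sim.cluster_marker_indices("oi_qtl")
        f2 = np.flatnonzero((sim.pedigree["generation"] == "F2").to_numpy())
        gmap = sim.genotypes.gmap
        pairs = [(idx[0], idx[k]) for k in range(1, len(idx), 4)]
        rng = np.random.default_rng(0)
        for a, b in pairs:
            d_cm = gmap.cm[b] - gmap.cm[a]
            rho = 1 - 2 * haldane_c(d_cm)
            x, y = sim.true_dosages[f2, a], sim.true_dosages[f2, b]
            r = np.corrcoef(x, y)[0, 1]
            se = bootstrap_corr_se(x, y, rng)
            assert abs(r - rho) < 5 * se

    def test_seed_determinism(self):
        cfg = toy_config(seed=5)
        a = simulate_cross(cfg)
        b = simulate_cross(cfg)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages,
                              equal_nan=True)
        assert np.array_equal(a.true_dosages, b.true_dosages)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)


class TestTraits:
    def test_uncorrelated_world_gives_uncorrelated_traits(self):
        names = ("t1", "t2", "t3")
        spec = TraitSpec(names=names, index_traits=names,
                         P=np.eye(3), G=0.5 * np.eye(3))
        cfg = SimConfig(n_founders_per_line=4, n_f1=8, n_f2=800,
                        n_chromosomes=2, markers_per_chrom=20,
                        clusters=(), traits=spec, seed=9)
        sim = simulate_cross(cfg)
        x = sim.traits[list(names)].to_numpy()
        r = np.corrcoef(x, rowvar=False)
        n = len(x)
        off = r[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_phenotype_regressed_on_true_bv_has_unit_slope(self):
        spec = TraitSpec(names=("t",), index_traits=("t",),
                         P=np.array([[1.0]]), G=np.array([[0.5]]))
        cfg = SimConfig(n_founders_per_line=4, n_f1=10, n_f2=2000,
                        n_chromosomes=1, markers_per_chrom=10,
                        clusters=(), traits=spec, seed=2)
        sim = simulate_cross(cfg)
        bv = sim.traits["t_ebv"].to_numpy()
        y = sim.traits["t"].to_numpy()
        slope = np.cov(y, bv)[0, 1] / np.var(bv)
        resid_var = np.var(y - slope * bv)
        se = np.sqrt(resid_var / (len(bv) * np.var(bv)))
        assert abs(slope - 1.0) < 3 * se

    def test_bv_covariance_matches_target_G(self):
        """Cluster-free world: simulated BV covariance reproduces G."""
        rng = np.random.default_rng(0)
        G = np.array([[0.5, 0.2, 0.1], [0.2, 0.4, 0.15], [0.1, 0.15, 0.6]])
        spec = TraitSpec(names=("a", "b", "c"), index_traits=("a",),
                         P=np.eye(3), G=G)
        cfg = SimConfig(n_founders_per_line=4, n_f1=10, n_f2=2000,
                        n_chromosomes=1, markers_per_chrom=10,
                        clusters=(), traits=spec, seed=4)
        sim = simulate_cross(cfg)
        bv = sim.traits[[c for c in ("a_ebv", "b_ebv", "c_ebv")]].to_numpy()
        n = len(bv)
        emp = np.cov(bv, rowvar=False)
        for i in range(3):
            for j in range(3):
                se = np.sqrt((G[i, i] * G[j, j] + G[i, j] ** 2) / n)
                assert abs(emp[i, j] - G[i, j]) < 3 * se

    def test_non_psd_environment_raises_with_eigenvalue(self):
        with pytest.raises(ConfigError, match="eigenvalue"):
            TraitSpec(names=("a", "b"), index_traits=("a",),
                      P=np.array([[1.0, 0.9], [0.9, 1.0]]),
                      G=np.array([[0.9, 0.0], [0.0, 0.9]]))

    def test_planted_cluster_ld_amplified_in_extremes(self, small_sim,
                                                      small_oi):
        """Ascertainment on the index induces LD among trait-associated
        markers: selecting index extremes raises the dosage correlation
        between the two unlinked planted clusters (near zero genome-wide)."""
        sim = small_sim
        idx_a = sim.cluster_marker_indices("oi_qtl")
        idx_b = sim.cluster_marker_indices("dw_qtl")
        aidx = {a: i for i, a in enumerate(sim.genotypes.animal_ids)}
        f2 = sim.pedigree[sim.pedigree["generation"] == "F2"]["animal_id"]
        oi = small_oi.loc[f2]
        extreme = oi.sort_values().index[-40:].tolist()

        def cross_abs_r(ids):
            rows = [aidx[a] for a in ids]
            da = sim.true_dosages[np.ix_(rows, idx_a)]
            db = sim.true_dosages[np.ix_(rows, idx_b)]
            keep_a = da.std(axis=0) > 0
            keep_b = db.std(axis=0) > 0
            r = np.corrcoef(np.hstack([da[:, keep_a], db[:, keep_b]]),
                            rowvar=False)
            return np.abs(r[:keep_a.sum(), keep_a.sum():]).mean()

        assert cross_abs_r(extreme) > cross_abs_r(list(f2))


def test_build_map_is_valid_and_cluster_lookup_errors():
    cfg = toy_config()
    gmap = build_map(cfg)
    assert len(gmap) == cfg.n_chromosomes * cfg.markers_per_chrom
    with pytest.raises(ConfigError, match="chromosome"):
        from wishnet.simdata import cluster_marker_indices
        cluster_marker_indices(gmap, QtlCluster(name="x", chrom="99",
                                                start_cm=0, n_markers=5))
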