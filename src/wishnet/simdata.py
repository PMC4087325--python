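"""Synthetic three-generation F2 intercross with correlated obesity traits.

The generator emulates the design of a divergent-line pig intercross: two
founder lines (an obese-prone and a lean line), F1 animals from line-A x
line-B matings, and a large F2 generation from F1 x F1 matings.  Meiosis
follows a Haldane (no-interference) model on the centimorgan scale, so the
recombination fraction between loci d cM apart is c = (1 - exp(-2d/100))/2,
which gives a closed-form oracle for the LD structure of the F2: the dosage
correlation between fixed-divergent loci is 1 - 2c.

Trait-associated SNP "clusters" are planted as founder haplotypes: every
line-A founder chromosome carries the full 1...1 haplotype across the
cluster's markers with a configured frequency (1.0 = line fixed).  Linked
causal markers therefore segregate as a coherent haplotype, creating the
within-cluster LD that the network stages are expected to recover.

Multi-trait breeding values are QTL contributions plus a polygenic deviate
with covariance G residualized for the QTL part; phenotypes add an
environmental deviate with covariance E = P - G.  The simulator emits the
true breeding values as the "estimated" breeding values consumed downstream
(optionally blurred to a configured accuracy); REML estimation is out of
scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GeneticMap, GenotypeMatrix

__all__ = [
    "ConfigError",
    "QtlCluster",
    "TraitSpec",
    "SimConfig",
    "SimOutput",
    "default_trait_spec",
    "default_clusters",
    "default_config",
    "build_map",
    "simulate_founders",
    "meiosis",
    "haldane_c",
    "simulate_cross",
    "simulate_traits",
    "synthetic_annotation",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def haldane_c(d_cm) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# Trait roster of the emulated resource population: the nine index traits
# first (weights below), then further obesity-related traits carried along
# for the module-trait association matrix.  Heritabilities follow the
# published descriptive statistics of the population; traits are simulated
# on a standardized scale (phenotypic variance 1).
INDEX_TRAITS = (
    "WT7m", "ABD7m", "ADG", "DXAfat", "DXApctfat",
    "SLfat", "BF1", "BF2", "SLfat_om",
)
EXTRA_TRAITS = (
    "WT2m", "BMI7m", "DXAlean", "DXAtotal", "FGL",
    "SLcw", "SLpctmeat", "SLfat_int",
)
HERITABILITY = {
    "WT7m": 0.39, "ABD7m": 0.28, "ADG": 0.54, "DXAfat": 0.43,
    "DXApctfat": 0.57, "SLfat": 0.23, "BF1": 0.22, "BF2": 0.23,
    "SLfat_om": 0.52, "WT2m": 0.78, "BMI7m": 0.23, "DXAlean": 0.71,
    "DXAtotal": 0.67, "FGL": 0.49, "SLcw": 0.54, "SLpctmeat": 0.18,
    "SLfat_int": 0.08,
}
# Biological weights of the nine index traits (fat depots weighted highest).
DEFAULT_WEIGHTS = {
    "WT7m": 0.1, "ABD7m": 0.1, "ADG": 0.1, "DXAfat": 0.5, "DXApctfat": 0.5,
    "SLfat": 0.8, "BF1": 1.0, "BF2": 1.0, "SLfat_om": 0.8,
}
# Single-factor loadings generating the trait correlation structure: one
# latent "adiposity/size" axis; meat percentage loads negatively.
_FACTOR_LOADING = {t: 0.5 for t in INDEX_TRAITS + EXTRA_TRAITS}
_FACTOR_LOADING.update({"DXAfat": 0.65, "DXApctfat": 0.65, "SLfat": 0.6,
                        "BF1": 0.6, "BF2": 0.6, "SLfat_om": 0.6,
                        "SLpctmeat": -0.45, "DXAlean": 0.35})


@dataclass(frozen=True)
class TraitSpec:
    """Trait names with target phenotypic (P) and genetic (G) covariances."""

    names: tuple
    index_traits: tuple
    P: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        G = np.asarray(self.G, dtype=float)
        m = len(self.names)
        if P.shape != (m, m) or G.shape != (m, m):
            raise ConfigError("P and G must be square and conformable with the trait list")
        if not np.allclose(P, P.T) or not np.allclose(G, G.T):
            raise ConfigError("P and G must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ConfigError("P must be positive definite")
        if np.linalg.eigvalsh(G).min() <= 0:
            raise ConfigError("G must be positive definite")
        h2 = np.diag(G) / np.diag(P)
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise ConfigError("heritabilities must lie in (0, 1]")
        emin = np.linalg.eigvalsh(P - G).min()
        if emin < -1e-10:
            raise ConfigError(
                f"environmental covariance P - G not positive semi-definite "
                f"(smallest eigenvalue {emin:.3e})"
            )
        if len(set(self.names)) != m:
            raise ConfigError("trait names must be unique")
        if not set(self.index_traits) <= set(self.names):
            raise ConfigError("index traits must be a subset of the trait list")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "G", G)

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.G) / np.diag(self.P)


def default_trait_spec() -> TraitSpec:
    names = INDEX_TRAITS + EXTRA_TRAITS
    lam = np.array([_FACTOR_LOADING[t] for t in names])
    h = np.sqrt([HERITABILITY[t] for t in names])
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    P = corr
    # genetic correlations somewhat stronger than phenotypic ones
    lam_g = np.sign(lam) * np.minimum(np.abs(lam) * 1.15, 0.9)
    corr_g = np.outer(lam_g, lam_g)
    np.fill_diagonal(corr_g, 1.0)
    G = corr_g * np.outer(h, h)
    return TraitSpec(names=names, index_traits=INDEX_TRAITS, P=P, G=G)


@dataclass(frozen=True)
class QtlCluster:
    """A planted block of linked markers carried as a founder haplotype.

    ``line_a_freq`` / ``line_b_freq`` are the frequencies of the all-1
    haplotype among founder chromosomes of each line; (1, 0) means the lines
    are fixed for alternative haplotypes.  ``effects`` maps trait name to
    the total additive effect of one copy of the haplotype, split evenly
    over ``n_causal`` markers inside the cluster.
    """

    name: str
    chrom: str
    start_cm: float
    n_markers: int
    line_a_freq: float = 1.0
    line_b_freq: float = 0.0
    n_causal: int = 0
    effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_markers < 1:
            raise ConfigError(f"cluster {self.name}: n_markers must be positive")
        if not (0.0 <= self.line_a_freq <= 1.0 and 0.0 <= self.line_b_freq <= 1.0):
            raise ConfigError(f"cluster {self.name}: haplotype frequencies must be in [0,1]")
        if self.n_causal > self.n_markers:
            raise ConfigError(f"cluster {self.name}: n_causal exceeds n_markers")

    @property
    def fixed(self) -> bool:
        return self.line_a_freq == 1.0 and self.line_b_freq == 0.0


def default_clusters() -> tuple:
    """Planted genetic architecture of the default cohort.

    * ``oi_qtl`` — a fixed-divergent 60-marker block on chromosome 1 whose
      haplotype carries a major-QTL effect on the fat traits.  Divergent
      intercrosses are constructed so that such major QTL segregate; the
      effect is sized to explain roughly a quarter of the index genetic
      variance, in line with major fatness QTL reported for pig crosses.
    * ``dw_qtl`` — a rare obese-line haplotype (frequency 0.3 among line-A
      founder chromosomes, absent from line B) of very large effect.  Lean
      index extremes carry essentially no copy, so the block is monomorphic
      (zero connectivity) in the lean subnetwork while remaining polymorphic
      and tightly linked in the obese subnetwork: the differential-wiring
      signature.
    """
    # Effects point along the index-efficient direction (traits carrying
    # large index coefficients under the default P, G and weights).
    direction = {"DXApctfat": 0.70, "SLfat_om": 0.67, "DXAfat": 0.39,
                 "ADG": 0.30, "WT7m": 0.12}
    return (
        QtlCluster(
            name="oi_qtl", chrom="1", start_cm=20.0, n_markers=60,
            line_a_freq=1.0, line_b_freq=0.0, n_causal=12,
            effects={t: 0.8 * w for t, w in direction.items()},
        ),
        QtlCluster(
            name="dw_qtl", chrom="3", start_cm=40.0, n_markers=20,
            line_a_freq=0.3, line_b_freq=0.0, n_causal=10,
            effects={t: 2.4 * w for t, w in direction.items()},
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of the simulated cohort.

    Defaults mirror the emulated resource population (24 founders, 78 F1,
    454 F2) at desk scale: 10 chromosomes of 100 cM carrying 500 evenly
    spaced markers each (1 cM ~ 1 Mb).
    """

    n_founders_per_line: int = 12
    n_f1: int = 78
    n_f2: int = 454
    n_chromosomes: int = 10
    markers_per_chrom: int = 500
    chrom_length_cm: float = 100.0
    divergence: float = 0.3
    clusters: tuple = field(default_factory=default_clusters)
    traits: TraitSpec = field(default_factory=default_trait_spec)
    missing_rate: float = 0.01
    ebv_accuracy: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders_per_line", "n_f1", "n_f2",
                     "n_chromosomes", "markers_per_chrom"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.chrom_length_cm <= 0:
            raise ConfigError("chrom_length_cm must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigError("divergence must be in [0, 1]")
        if not 0.0 < self.ebv_accuracy <= 1.0:
            raise ConfigError("ebv_accuracy must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = {
            "names": list(self.traits.names),
            "index_traits": list(self.traits.index_traits),
        }
        d["clusters"] = [dataclasses.asdict(c) for c in self.clusters]
        return d


default_config = SimConfig


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame
    traits: pd.DataFrame
    causal: pd.DataFrame
    config: SimConfig
    true_dosages: np.ndarray  # pre-masking dosages (animals x markers)

    def cluster_marker_indices(self, name: str) -> np.ndarray:
        sub = self.causal[self.causal["cluster"] == name]
        return np.unique(sub["marker_index"].to_numpy())


# ---------------------------------------------------------------------------
# map and founders
# ---------------------------------------------------------------------------

def build_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced markers; bp position = cM * 1e6 (1 cM ~ 1 Mb)."""
    chroms, markers, bps, cms = [], [], [], []
    spacing = config.chrom_length_cm / config.markers_per_chrom
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.markers_per_chrom):
            cm = spacing * (j + 1)
            chroms.append(str(c))
            markers.append(f"snp_{c}_{j + 1}")
            cms.append(cm)
            bps.append(int(round(cm * 1e6)))
    return GeneticMap(
        np.array(chroms, dtype=object), np.array(markers, dtype=object),
        np.array(bps), np.array(cms),
    )


def cluster_marker_indices(gmap: GeneticMap, cluster: QtlCluster) -> np.ndarray:
    idx = gmap.chrom_indices(cluster.chrom)
    if len(idx) == 0:
        raise ConfigError(f"cluster {cluster.name}: chromosome {cluster.chrom} not in map")
    start = np.searchsorted(gmap.cm[idx], cluster.start_cm)
    sel = idx[start:start + cluster.n_markers]
    if len(sel) < cluster.n_markers:
        raise ConfigError(
            f"cluster {cluster.name}: only {len(sel)} markers available from "
            f"{cluster.start_cm} cM on chromosome {cluster.chrom}"
        )
    return sel


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> dict:
    """Phased founder haplotype pools, one (2*n_founders, M) array per line.

    Neutral loci: a shared base frequency drawn U(0.1, 0.9) per marker is
    shifted by +/- divergence/2 per line (clipped to [0.02, 0.98]) and
    haplotype alleles drawn independently.  Cluster loci: each founder
    chromosome carries the full all-1 haplotype with the line's configured
    haplotype frequency, all-0 otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    gmap = build_map(config)
    m = len(gmap)
    n_hap = 2 * config.n_founders_per_line
    base = rng.uniform(0.1, 0.9, size=m)
    pools = {}
    freqs = {}
    for line, shift in (("A", +0.5), ("B", -0.5)):
        p = np.clip(base + shift * config.divergence, 0.02, 0.98)
        pools[line] = (rng.random((n_hap, m)) < p).astype(np.int8)
        freqs[line] = p
    for cl in config.clusters:
        idx = cluster_marker_indices(gmap, cl)
        for line, f in (("A", cl.line_a_freq), ("B", cl.line_b_freq)):
            carrier = rng.random(n_hap) < f
            pools[line][:, idx] = 0
            pools[line][np.flatnonzero(carrier)[:, None], idx] = 1
            freqs[line][idx] = f
    return {"haplotypes": pools, "map": gmap, "line_freqs": freqs}


# ---------------------------------------------------------------------------
# meiosis and the cross
# ---------------------------------------------------------------------------

def meiosis(haplopair: np.ndarray, gmap: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete from a phased haplotype pair under a Haldane model.

    Crossover points form a Poisson process with rate 1 per Morgan along
    each chromosome; chromosomes assort independently.
    """
    haplopair = np.asarray(haplopair)
    if haplopair.shape != (2, len(gmap)):
        raise ValueError(
            f"haplotype pair shape {haplopair.shape} does not cover the "
            f"{len(gmap)}-marker map"
        )
    gamete = np.empty(len(gmap), dtype=np.int8)
    for c in gmap.chromosomes:
        idx = gmap.chrom_indices(c)
        cm = gmap.cm[idx]
        length = cm[-1] - cm[0]
        n_x = rng.poisson(length / 100.0)
        if n_x:
            points = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
            phase = (rng.integers(2) + np.searchsorted(points, cm, side="right")) % 2
        else:
            phase = np.full(len(idx), rng.integers(2))
        gamete[idx] = haplopair[phase, idx]
    return gamete


def _mate(parents: list, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    sire, dam = parents
    return np.stack([meiosis(sire, gmap, rng), meiosis(dam, gmap, rng)])


def simulate_cross(config: SimConfig) -> SimOutput:
    """Run the full three-generation cross and trait simulation."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_founder = np.random.default_rng(ss[0])
    rng_meiosis = np.random.default_rng(ss[1])
    rng_traits = np.random.default_rng(ss[2])
    rng_missing = np.random.default_rng(ss[3])

    founders = simulate_founders(config, rng_founder)
    gmap = founders["map"]
    pools = founders["haplotypes"]
    n_found = config.n_founders_per_line

    animals, haplos, pedigree = [], [], []
    for line in ("A", "B"):
        for i in range(n_found):
            aid = f"{line}{i + 1:02d}"
            animals.append(aid)
            haplos.append(pools[line][2 * i:2 * i + 2])
            pedigree.append((aid, "", "", "F0"))
    a_ids = [a for a, *_ in pedigree if a.startswith("A")]
    b_ids = [a for a, *_ in pedigree if a.startswith("B")]
    by_id = dict(zip(animals, haplos))

    f1_ids = []
    for i in range(config.n_f1):
        sire, dam = a_ids[i % n_found], b_ids[(i // n_found) % n_found]
        aid = f"F1_{i + 1:03d}"
        hp = _mate([by_id[sire], by_id[dam]], gmap, rng_meiosis)
        animals.append(aid)
        haplos.append(hp)
        by_id[aid] = hp
        pedigree.append((aid, sire, dam, "F1"))
        f1_ids.append(aid)

    for i in range(config.n_f2):
        si, di = rng_meiosis.integers(len(f1_ids)), rng_meiosis.integers(len(f1_ids))
        if di == si:
            di = (di + 1) % len(f1_ids)
        sire, dam = f1_ids[si], f1_ids[di]
        aid = f"F2_{i + 1:03d}"
        hp = _mate([by_id[sire], by_id[dam]], gmap, rng_meiosis)
        animals.append(aid)
        haplos.append(hp)
        pedigree.append((aid, sire, dam, "F2"))

    true_dosages = np.array([h.sum(axis=0) for h in haplos], dtype=float)
    ped = pd.DataFrame(pedigree, columns=["animal_id", "sire", "dam", "generation"])

    traits, causal = simulate_traits(true_dosages, ped, gmap, config, rng_traits)

    dosages = true_dosages.copy()
    if config.missing_rate > 0:
        mask = rng_missing.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    genotypes = GenotypeMatrix(animals, dosages, gmap)
    return SimOutput(genotypes, ped, traits, causal, config, true_dosages)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def simulate_traits(dosages: np.ndarray, pedigree: pd.DataFrame, gmap: GeneticMap,
                    config: SimConfig, rng: np.random.Generator):
    """Breeding values and phenotypes for every animal.

    BV = centered QTL contributions + polygenic deviate ~ N(0, G - Cov_qtl);
    phenotype = BV + environmental deviate ~ N(0, P - G).  If the planted
    QTL explain more (co)variance than G allows, the residual genetic
    covariance is clipped to the nearest PSD matrix.
    """
    spec = config.traits
    names = list(spec.names)
    n = dosages.shape[0]
    effects = np.zeros((len(gmap), len(names)))
    rows = []
    for cl in config.clusters:
        idx = cluster_marker_indices(gmap, cl)
        if cl.n_causal and cl.effects:
            causal_idx = idx[np.linspace(0, len(idx) - 1, cl.n_causal).round().astype(int)]
            for t, a in cl.effects.items():
                if t not in names:
                    raise ConfigError(f"cluster {cl.name}: unknown trait {t}")
                effects[causal_idx, names.index(t)] += a / cl.n_causal
        else:
            causal_idx = np.array([], dtype=int)
        for j in idx:
            rows.append({
                "marker_index": j, "marker": gmap.marker[j], "chrom": gmap.chrom[j],
                "cluster": cl.name, "causal": j in set(causal_idx),
            })
    causal = pd.DataFrame(rows, columns=["marker_index", "marker", "chrom",
                                         "cluster", "causal"])

    active = np.flatnonzero(np.any(effects != 0.0, axis=1))
    qtl_bv = np.zeros((n, len(names)))
    if len(active):
        centered = dosages[:, active] - dosages[:, active].mean(axis=0)
        qtl_bv = centered @ effects[active]
    cov_qtl = np.cov(qtl_bv, rowvar=False) if len(active) else np.zeros_like(spec.G)
    g_resid = _nearest_psd(spec.G - cov_qtl)

    emin = np.linalg.eigvalsh(spec.P - spec.G).min()
    if emin < -1e-10:
        raise ConfigError(
            f"P - G not positive semi-definite (smallest eigenvalue {emin:.3e})"
        )
    env_cov = _nearest_psd(spec.P - spec.G)

    poly = rng.multivariate_normal(np.zeros(len(names)), g_resid, size=n,
                                   method="eigh")
    bv = qtl_bv + poly
    env = rng.multivariate_normal(np.zeros(len(names)), env_cov, size=n,
                                  method="eigh")
    pheno = bv + env

    if config.ebv_accuracy < 1.0:
        r = config.ebv_accuracy
        noise = rng.multivariate_normal(np.zeros(len(names)), spec.G, size=n,
                                        method="eigh")
        ebv = r * bv + np.sqrt(1 - r * r) * noise
    else:
        ebv = bv

    table = pd.DataFrame({"animal_id": pedigree["animal_id"].to_numpy(),
                          "generation": pedigree["generation"].to_numpy()})
    for k, t in enumerate(names):
        table[t] = pheno[:, k]
    for k, t in enumerate(names):
        table[f"{t}_ebv"] = ebv[:, k]
    return table, causal


# ---------------------------------------------------------------------------
# synthetic annotation (genes + gene sets) for the enrichment stage
# ---------------------------------------------------------------------------

def synthetic_annotation(gmap: GeneticMap, causal: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         gene_size_bp: int = 30_000, gene_spacing_bp: int = 1_000_000,
                         n_random_sets: int = 20, set_size: int = 25):
    """Synthetic gene annotation (BED-style) and gene sets (GMT-style).

    Genes of 30 kb are tiled every megabase; one gene set collects the genes
    overlapping each planted cluster, plus random sets as enrichment
    background.  Purely an artifact of the simulation: real annotation is a
    user-supplied BED/GMT input.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for c in gmap.chromosomes:
        idx = gmap.chrom_indices(c)
        end = int(gmap.bp[idx].max())
        g = 0
        for start in range(0, end, gene_spacing_bp):
            rows.append({"chrom": c, "start": start, "end": start + gene_size_bp,
                         "gene": f"gene_{c}_{g + 1}"})
            g += 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])

    sets = {}
    for name in causal["cluster"].unique():
        sub = causal[causal["cluster"] == name]
        lo = gmap.bp[sub["marker_index"].min()]
        hi = gmap.bp[sub["marker_index"].max()]
        chrom = sub["chrom"].iloc[0]
        sel = genes[(genes["chrom"] == chrom)
                    & (genes["end"] > lo - 20_000) & (genes["start"] < hi + 20_000)]
        if len(sel):
            sets[f"set_{name}"] = sorted(sel["gene"].tolist())
    all_genes = genes["gene"].to_numpy()
    for i in range(n_random_sets):
        sets[f"set_random_{i + 1}"] = sorted(
            rng.choice(all_genes, size=min(set_size, len(all_genes)),
                       replace=False).tolist()
        )
    return genes, sets
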