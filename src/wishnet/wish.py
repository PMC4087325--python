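"""Weighted Interaction SNP Hub (WISH) network construction.

Nodes are SNPs, edges derive from genotype correlations over a set of
index-extreme animals: adjacency a_ij = |cor(d_i, d_j)|^gamma with a soft
threshold gamma chosen so that the connectivity distribution approximates a
scale-free form; similarity is the topological overlap measure (TOM), which
rewards shared neighborhoods, and 1 - TOM is clustered by average linkage
with a height-quantile tree cut into modules of a minimum size.  Each
module is summarized by its eigenSNP (first principal component over
animals) and correlated with the index and the other recorded traits to
form the genome-wide module association matrix (GMAT).

Unsigned adjacency is used throughout: with an odd power a signed
correlation would leave [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix
from .gwas import GwasResult

__all__ = ["nan_corr", "preselect_snps", "scale_free_fit", "adjacency", "tom",
           "detect_modules", "eigensnp", "gmat", "select_modules",
           "ModuleSet", "Gmat"]


# ---------------------------------------------------------------------------
# correlation with missing data
# ---------------------------------------------------------------------------

def nan_corr(X: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Pairwise-complete Pearson correlation between columns of X.

    Pairs with no shared observations or zero variance get correlation 0
    (their absence from the network is the intended behavior).
    """
    X = np.asarray(X, dtype=dtype)
    if not np.isnan(X).any():
        sd = X.std(axis=0)
        ok = sd > 0
        Z = np.zeros_like(X)
        Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
        r = (Z.T @ Z) / X.shape[0]
        np.clip(r, -1.0, 1.0, out=r)
        return r
    obs = ~np.isnan(X)
    W = obs.astype(dtype)
    X0 = np.where(obs, X, 0.0).astype(dtype)
    n = W.T @ W
    s = X0.T @ W          # s[i, j] = sum of x_i over animals shared with j
    ss = (X0 * X0).T @ W
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        cov = sxy / n - mean * mean.T
        var = ss / n - mean ** 2
        denom = np.sqrt(var * var.T)
        r = cov / denom
    r[~np.isfinite(r)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return r


# ---------------------------------------------------------------------------
# SNP pre-selection
# ---------------------------------------------------------------------------

def preselect_snps(res: GwasResult, g: GenotypeMatrix, animals,
                   p_max: float = 0.05, top_n: int = 2500,
                   k_norm_min: float = 0.12) -> tuple[GenotypeMatrix, dict]:
    """Two-stage data reduction before network construction.

    Stage 1 keeps markers with scan p < ``p_max``.  Stage 2 restricts to
    the extreme-animal rows and ranks markers by normalized connectivity
    k_i = sum_{j != i} |r_ij| / (m - 1) — the correlation itself (gamma = 1),
    since the ranking precedes the soft-threshold choice — keeping the top
    ``top_n`` (ties at the cut resolved toward the lower marker index).
    ``k_norm_min`` is recorded for audit alongside the realized k range.
    """
    animals = list(animals)
    if not animals:
        raise ValueError("empty extreme-animal subset")
    pvals = res.table["p"].to_numpy()
    stage1 = np.flatnonzero(pvals < p_max)
    meta = {"n_input": res.n_markers, "p_max": p_max,
            "n_p_selected": int(len(stage1)), "top_n": top_n,
            "k_norm_min": k_norm_min}
    keep_markers = res.table["marker"].to_numpy()[stage1]
    pos = {m: j for j, m in enumerate(g.marker_ids)}
    idx = np.array([pos[m] for m in keep_markers], dtype=int)
    sub = g.take_animals(animals).take_markers(idx)

    m = sub.n_markers
    if m > top_n:
        absr = np.abs(nan_corr(sub.dosages))
        np.fill_diagonal(absr, 0.0)
        k = absr.sum(axis=0) / (m - 1)
        order = np.lexsort((np.arange(m), -k))
        chosen = np.sort(order[:top_n])
        meta["k_norm_cut"] = float(k[order[top_n - 1]])
        sub = sub.take_markers(chosen)
    else:
        meta["warning"] = (f"only {m} markers survive p < {p_max}; "
                           f"top-{top_n} reduction skipped")
    meta["n_selected"] = sub.n_markers
    return sub, meta


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Log-log fit of the binned connectivity distribution.

    Returns (R^2, slope) of log10 p(k) on log10 mean k over equal-width
    bins; (nan, nan) when the fit is degenerate (all k equal, or fewer
    than three usable bins).
    """
    k = np.asarray(k, dtype=float)
    if k.max() - k.min() <= 1e-15:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            mk = k[sel].mean()
            if mk > 0:
                dk.append(mk)
                pk.append(sel.mean())
    if len(dk) < 3:
        return float("nan"), float("nan")
    x, y = np.log10(dk), np.log10(pk)
    if np.ptp(x) <= 1e-15:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - yhat) ** 2).sum() / sst if sst > 0 else float("nan")
    return float(r2), float(slope)


def scale_free_fit(g: GenotypeMatrix | np.ndarray, powers=tuple(range(1, 11)),
                   n_bins: int = 10, r2_target: float = 0.85,
                   ) -> tuple[pd.DataFrame, int | None]:
    """Scale-free topology index per candidate power and the chosen power.

    The fit index is R^2 of the log-log connectivity distribution, counted
    only when the slope is negative (hub-like decay).  Chosen gamma is the
    smallest power reaching ``r2_target``, else the argmax of the index;
    None when every fit is degenerate.
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if X.shape[1] < 50:
        raise ValueError("scale-free fit needs at least 50 SNPs")
    absr = np.abs(nan_corr(X))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for gamma in powers:
        k = (absr ** gamma).sum(axis=0)
        r2, slope = _scale_free_r2(k, n_bins)
        fit = r2 if np.isfinite(r2) and slope < 0 else (
            float("nan") if not np.isfinite(r2) else 0.0)
        rows.append({"power": gamma, "r2": r2, "slope": slope, "fit_index": fit,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["fit_index"])
    if usable.empty:
        return table, None
    good = usable[usable["fit_index"] >= r2_target]
    chosen = int(good["power"].iloc[0]) if len(good) else \
        int(usable.loc[usable["fit_index"].idxmax(), "power"])
    return table, chosen


# ---------------------------------------------------------------------------
# adjacency and TOM
# ---------------------------------------------------------------------------

def adjacency(g: GenotypeMatrix | np.ndarray, gamma: float = 5.0) -> np.ndarray:
    """Unsigned adjacency |cor|^gamma with zero diagonal."""
    if gamma < 1:
        raise ValueError("soft-threshold power must be >= 1")
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    a = np.abs(nan_corr(X)) ** gamma
    np.fill_diagonal(a, 0.0)
    return a


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap t_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbor adjacency products, k is node connectivity;
    the diagonal is 1 and 1 - t is the clustering dissimilarity.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = np.array(a)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    # (a @ a)_ij = sum_u a_iu a_uj already excludes u = i, j since diag(a) = 0
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 1e-12, (l + a) / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    np.clip(t, 0.0, 1.0, out=t)
    return t


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

@dataclass
class ModuleSet:
    """SNP-to-module assignment (label 0 = unassigned) plus eigenSNPs."""

    marker_ids: np.ndarray
    labels: np.ndarray
    min_size: int
    metadata: dict = field(default_factory=dict)
    eigensnps: pd.DataFrame | None = None
    var_explained: dict = field(default_factory=dict)

    @property
    def module_labels(self) -> list:
        return sorted(l for l in np.unique(self.labels) if l != 0)

    def sizes(self) -> dict:
        return {int(l): int((self.labels == l).sum()) for l in self.module_labels}

    def members(self, label: int) -> np.ndarray:
        return self.marker_ids[self.labels == label]

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.marker_ids, "module": self.labels})


def detect_modules(dissimilarity: np.ndarray, marker_ids=None, min_size: int = 50,
                   cut_quantile: float = 0.99) -> ModuleSet:
    """Average-linkage tree cut of a TOM dissimilarity into modules.

    The tree is cut statically at the ``cut_quantile`` of the merge
    heights; branches below ``min_size`` are merged into the nearest
    retained branch when their mean dissimilarity to it stays below the cut
    height, otherwise labeled 0.  Final labels are ordered by decreasing
    module size.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    m = d.shape[0]
    if marker_ids is None:
        marker_ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    marker_ids = np.asarray(marker_ids, dtype=object)
    meta = {"min_size": min_size, "cut_quantile": cut_quantile,
            "variant": "static-height tree cut with minimum-size merge"}
    if m < min_size:
        meta["note"] = "fewer SNPs than the minimum module size"
        return ModuleSet(marker_ids, np.zeros(m, dtype=int), min_size, meta)

    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    if np.ptp(dsym[np.triu_indices(m, 1)]) <= 1e-15:
        # degenerate: every pair equally (dis)similar -> one module
        meta["note"] = "degenerate dissimilarity (all pairs equal); single module"
        return ModuleSet(marker_ids, np.ones(m, dtype=int), min_size, meta)
    link = linkage(squareform(dsym, checks=False), method="average")
    heights = link[:, 2]
    cut_h = float(np.quantile(heights, cut_quantile))
    meta["cut_height"] = cut_h
    raw = fcluster(link, t=cut_h, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sorted(sizes[sizes >= min_size].index)
    if not big:
        meta["note"] = "no branch reached the minimum module size"
        return ModuleSet(marker_ids, np.zeros(m, dtype=int), min_size, meta)
    labels = np.zeros(m, dtype=int)
    tmp = {b: i + 1 for i, b in enumerate(big)}
    for b in big:
        labels[raw == b] = tmp[b]
    # merge small branches into the nearest big branch when still coherent
    for b in sizes[sizes < min_size].index:
        members = np.flatnonzero(raw == b)
        mean_d = {lb: dsym[np.ix_(members, np.flatnonzero(labels == lb))].mean()
                  for lb in tmp.values()}
        nearest = min(sorted(mean_d), key=lambda lb: (mean_d[lb], lb))
        if mean_d[nearest] <= cut_h:
            labels[members] = nearest
    # relabel by decreasing size (ties by first occurrence)
    final_sizes = pd.Series(labels[labels != 0]).value_counts()
    order = sorted(final_sizes.index, key=lambda lb: (-final_sizes[lb], lb))
    remap = {lb: i + 1 for i, lb in enumerate(order)}
    labels = np.array([remap.get(lb, 0) for lb in labels], dtype=int)
    return ModuleSet(marker_ids, labels, min_size, meta)


# ---------------------------------------------------------------------------
# eigenSNPs and module-trait associations
# ---------------------------------------------------------------------------

def eigensnp(g: GenotypeMatrix, modules: ModuleSet) -> ModuleSet:
    """First principal component of each module's standardized dosages.

    Missing dosages are mean-imputed within SNP before standardization; the
    eigenSNP sign is fixed to correlate positively with the module's mean
    standardized dosage.  Variance explained is lambda_1 / sum(lambda).
    """
    pos = {m: j for j, m in enumerate(g.marker_ids)}
    scores = {}
    varexp = {}
    for label in modules.module_labels:
        members = modules.members(label)
        idx = [pos[m] for m in members]
        if len(idx) < 2:
            raise ValueError(f"module {label} has fewer than 2 SNPs")
        X = g.dosages[:, idx].copy()
        col_mean = np.nanmean(X, axis=0)
        nan_at = np.isnan(X)
        X[nan_at] = np.take(col_mean, np.where(nan_at)[1])
        sd = X.std(axis=0)
        if not np.any(sd > 0):
            raise ValueError(f"module {label} has zero dosage variance")
        Z = np.zeros_like(X)
        ok = sd > 0
        Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        score = u[:, 0] * s[0]
        ref = Z.mean(axis=1)
        if np.dot(score, ref) < 0:
            score = -score
        scores[f"M{label}"] = score
        varexp[f"M{label}"] = float(s[0] ** 2 / (s ** 2).sum())
    modules.eigensnps = pd.DataFrame(scores, index=g.animal_ids)
    modules.var_explained = varexp
    return modules


@dataclass
class Gmat:
    """Module x trait correlation matrix (MTR) with asymptotic p-values."""

    mtr: pd.DataFrame
    p: pd.DataFrame
    n: int

    def to_frame(self) -> pd.DataFrame:
        out = {}
        for t in self.mtr.columns:
            out[f"{t}_mtr"] = self.mtr[t]
            out[f"{t}_p"] = self.p[t]
        return pd.DataFrame(out, index=self.mtr.index)


def gmat(eigensnps: pd.DataFrame, traits: pd.DataFrame, oi_col: str = "OI") -> Gmat:
    """Correlate each module eigenSNP with each trait.

    p-values are the Student asymptotic form: t = r sqrt(n-2) / sqrt(1-r^2)
    on n - 2 df, two-sided.  The index column is placed first.
    """
    common = eigensnps.index.intersection(traits.index)
    n = len(common)
    if n < 4:
        raise ValueError(f"only {n} shared animals; need at least 4")
    E = eigensnps.loc[common]
    T = traits.loc[common]
    cols = ([oi_col] if oi_col in T.columns else []) + \
        [c for c in T.columns if c != oi_col]
    mtr = pd.DataFrame(index=E.columns, columns=cols, dtype=float)
    pmat = pd.DataFrame(index=E.columns, columns=cols, dtype=float)
    for mod in E.columns:
        e = E[mod].to_numpy(dtype=float)
        for c in cols:
            y = T[c].to_numpy(dtype=float)
            ok = np.isfinite(e) & np.isfinite(y)
            if ok.sum() < 4 or np.std(e[ok]) == 0 or np.std(y[ok]) == 0:
                mtr.loc[mod, c] = np.nan
                pmat.loc[mod, c] = np.nan
                continue
            r = float(np.corrcoef(e[ok], y[ok])[0, 1])
            r = min(1.0, max(-1.0, r))
            nn = int(ok.sum())
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(nn - 2) / np.sqrt(1 - r * r)
                p = float(2 * stats.t.sf(abs(tstat), nn - 2))
            mtr.loc[mod, c] = r
            pmat.loc[mod, c] = p
    return Gmat(mtr=mtr, p=pmat, n=n)


def select_modules(gm: Gmat, p_oi_max: float = 0.001, mtr_other_min: float = 0.4,
                   oi_col: str = "OI") -> list:
    """Modules significantly tied to the index and strongly to another trait.

    Selection requires p(index) < ``p_oi_max`` and |MTR| > ``mtr_other_min``
    with at least one other trait (the absolute value is used: an eigenSNP's
    sign is arbitrary).
    """
    if oi_col not in gm.mtr.columns:
        raise ValueError(f"GMAT lacks the index column {oi_col!r}")
    others = [c for c in gm.mtr.columns if c != oi_col]
    out = []
    for mod in gm.mtr.index:
        if not np.isfinite(gm.p.loc[mod, oi_col]):
            continue
        if gm.p.loc[mod, oi_col] < p_oi_max and \
                (gm.mtr.loc[mod, others].abs() > mtr_other_min).any():
            out.append(mod)
    return out
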