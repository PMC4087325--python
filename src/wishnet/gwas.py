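"""Single-SNP genome-wide association of the index on allele dosage.

Model per marker: OI = mu + beta * dosage + e, ordinary least squares with
missing genotypes dropped pairwise and two-sided p-values from the t
distribution with n - 2 degrees of freedom.  The index is a pre-corrected
genetic value, so no structure covariates are fitted by default (fitting
them again would over-correct); a covariate hook exists for other uses.

Significance control is Bonferroni over the markers actually scanned:
suggestive = 0.05 / M, highly significant = 0.001 / M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["GwasResult", "scan", "bonferroni", "significant_markers"]

SUGGESTIVE_ALPHA = 0.05
HIGH_ALPHA = 0.001


@dataclass
class GwasResult:
    """Per-marker OLS results plus the scan-level Bonferroni thresholds."""

    table: pd.DataFrame  # marker, chrom, bp, effect, se, t, p, n, reason
    n_markers: int = 0
    thresholds: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def threshold(self, level: str) -> float:
        return self.thresholds[level]

    def manhattan_frame(self) -> pd.DataFrame:
        """Scan table sorted by genomic position for plotting/export."""
        df = self.table.copy()
        df["_c"] = pd.to_numeric(df["chrom"], errors="coerce")
        df = df.sort_values(["_c", "chrom", "bp"], kind="mergesort").drop(columns="_c")
        return df.reset_index(drop=True)


def bonferroni(n_markers: int, alphas=(SUGGESTIVE_ALPHA, HIGH_ALPHA)) -> dict:
    """Per-test thresholds alpha / M for each family-wise level."""
    if n_markers < 1:
        raise ValueError("marker count must be >= 1")
    names = {SUGGESTIVE_ALPHA: "suggestive", HIGH_ALPHA: "high"}
    return {names.get(a, f"alpha_{a:g}"): a / n_markers for a in alphas}


def scan(oi: pd.Series, g: GenotypeMatrix, covariates: pd.DataFrame | None = None,
         min_n: int = 3) -> GwasResult:
    """OLS of the index on dosage at every marker.

    Monomorphic markers and markers with fewer than ``min_n`` informative
    animals are reported as NA with a reason code.  With covariates, the
    index is residualized on them (with intercept) before the per-marker
    regressions.
    """
    common = [a for a in g.animal_ids if a in oi.index]
    if not common:
        raise ValueError("no animals shared between index table and genotypes")
    gg = g.take_animals(common)
    y = oi.loc[common].to_numpy(dtype=float)
    if covariates is not None and len(covariates.columns):
        Z = covariates.loc[common].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(y)), Z])
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]

    X = gg.dosages
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    W = obs.astype(float)
    n = W.sum(axis=0)
    sx = X0.sum(axis=0)
    sxx = (X0 * X0).sum(axis=0)
    sy = y @ W
    syy = (y * y) @ W
    sxy = y @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        mean_y = sy / n
        ssx = sxx - n * mean_x ** 2
        ssy = syy - n * mean_y ** 2
        sxy_c = sxy - n * mean_x * mean_y
        beta = sxy_c / ssx
        dof = n - 2
        rss = np.maximum(ssy - beta * sxy_c, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / ssx)
        tval = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tval), dof)

    reason = np.array([""] * gg.n_markers, dtype=object)
    bad_n = n < min_n
    # zero dosage variance (tolerance scaled to dosage magnitude)
    zero_var = ~bad_n & (ssx <= 1e-12 * np.maximum(n, 1))
    degen = ~bad_n & ~zero_var & (sigma2 <= 1e-24)
    reason[bad_n] = "too_few_animals"
    reason[zero_var] = "zero_variance"
    reason[degen] = "perfect_fit"
    invalid = bad_n | zero_var
    for arr in (beta, se, tval, pval):
        arr[invalid] = np.nan
    pval[degen] = 0.0

    gmap = gg.gmap
    table = pd.DataFrame({
        "marker": gg.marker_ids,
        "chrom": gmap.chrom if gmap is not None else "",
        "bp": gmap.bp if gmap is not None else -1,
        "effect": beta, "se": se, "t": tval, "p": pval,
        "n": n.astype(int), "reason": reason,
    })
    res = GwasResult(table=table, n_markers=gg.n_markers,
                     thresholds=bonferroni(gg.n_markers),
                     settings={"n_animals": len(common), "min_n": min_n,
                               "covariates": list(covariates.columns)
                               if covariates is not None else []})
    if np.all(invalid):
        res.settings["warning"] = "no marker could be tested"
    return res


def significant_markers(res: GwasResult, level: str = "suggestive") -> pd.DataFrame:
    """Markers with p below the requested Bonferroni threshold, best first."""
    thr = res.threshold(level)
    hits = res.table[res.table["p"] < thr]
    return hits.sort_values("p", kind="mergesort").reset_index(drop=True)
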