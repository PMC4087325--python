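"""Differential wiring of SNPs between lean and obese index extremes.

A SNP's connectivity within a subgroup is the sum of its absolute genotype
correlations with every other SNP, max-normalized within the subgroup so
k lies in [0, 1].  The differential connectivity k_diff = k_lean - k_obese
is positive for lean hubs and negative for obese hubs; a SNP monomorphic in
one subgroup contributes zero correlations there, which is how the extreme
values +/-1 arise.  SNPs with |k_diff| above a fixed cutoff (default 0.6)
are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .wish import nan_corr

__all__ = ["DwResult", "subgroup_connectivity", "k_diff", "run_dwire"]


@dataclass
class DwResult:
    table: pd.DataFrame  # marker, chrom, bp, k_lean, k_obese, k_diff, selected
    threshold: float
    n_lean: int
    n_obese: int
    metadata: dict = field(default_factory=dict)

    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]].reset_index(drop=True)


def subgroup_connectivity(g: GenotypeMatrix, animals, min_subset: int = 10,
                          dtype=np.float32) -> pd.Series:
    """Max-normalized connectivity of every SNP within an animal subset.

    raw_k_i = sum_{j != i} |r_ij| over the subgroup; k_i = raw_k_i / max raw_k.
    SNPs with zero dosage variance within the subgroup have all their
    correlations treated as 0 (``nan_corr`` convention) and are flagged in
    the series attrs.
    """
    animals = list(animals)
    if len(animals) < min_subset:
        raise ValueError(f"subgroup of {len(animals)} animals; need >= {min_subset}")
    sub = g.take_animals(animals)
    absr = np.abs(nan_corr(sub.dosages, dtype=dtype))
    np.fill_diagonal(absr, 0.0)
    raw = absr.sum(axis=0, dtype=np.float64)
    top = raw.max()
    k = raw / top if top > 0 else raw
    out = pd.Series(k, index=sub.marker_ids, name="k")
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(sub.dosages, axis=0)
    out.attrs["zero_variance"] = list(np.asarray(sub.marker_ids)[~(sd > 0)])
    out.attrs["max_raw_k"] = float(top)
    return out


def k_diff(k_lean: pd.Series, k_obese: pd.Series,
           threshold: float = 0.6) -> pd.DataFrame:
    """k_lean - k_obese per SNP with the selection flag |k_diff| > threshold."""
    if list(k_lean.index) != list(k_obese.index):
        only_lean = set(k_lean.index) - set(k_obese.index)
        only_obese = set(k_obese.index) - set(k_lean.index)
        raise ValueError(
            f"SNP sets differ between subgroups (lean-only {sorted(only_lean)[:5]}, "
            f"obese-only {sorted(only_obese)[:5]})"
        )
    diff = k_lean.to_numpy() - k_obese.to_numpy()
    return pd.DataFrame({
        "marker": k_lean.index,
        "k_lean": k_lean.to_numpy(),
        "k_obese": k_obese.to_numpy(),
        "k_diff": diff,
        "selected": np.abs(diff) > threshold,
    })


def run_dwire(g: GenotypeMatrix, lean_animals, obese_animals,
              threshold: float = 0.6, dtype=np.float32) -> DwResult:
    """Full differential-wiring analysis on a fixed SNP set."""
    kl = subgroup_connectivity(g, lean_animals, dtype=dtype)
    ko = subgroup_connectivity(g, obese_animals, dtype=dtype)
    table = k_diff(kl, ko, threshold)
    if g.gmap is not None:
        table.insert(1, "chrom", g.gmap.chrom)
        table.insert(2, "bp", g.gmap.bp)
    meta = {
        "threshold": threshold,
        "zero_variance_lean": kl.attrs["zero_variance"],
        "zero_variance_obese": ko.attrs["zero_variance"],
        "n_selected": int(table["selected"].sum()),
    }
    return DwResult(table=table, threshold=threshold,
                    n_lean=len(list(lean_animals)),
                    n_obese=len(list(obese_animals)), metadata=meta)
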