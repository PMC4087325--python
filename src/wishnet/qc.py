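"""Genotype quality control: call rate, IBS duplicates, MAF, exact HWE.

Rules and thresholds follow chip-era GWAS practice for an intercross cohort:
animals are dropped for low call rate and for near-duplicate identity by
state (IBS >= 0.95); markers are filtered in fixed order call rate -> minor
allele frequency -> Hardy-Weinberg, each rule applied to the survivors of
the previous one.  MAF uses an inclusive boundary (MAF <= threshold is
removed); HWE uses the exact conditional test (Wigginton et al. 2005), the
default of GenABEL-era pipelines, with a chi-square option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = ["QcReport", "hwe_exact_p", "hwe_chisq_p", "pairwise_ibs",
           "sample_filters", "marker_filters", "run_qc"]


@dataclass
class QcReport:
    """Per-rule record of exclusions with the triggering statistic."""

    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "kind", "rule", "statistic", "threshold"]))
    thresholds: dict = field(default_factory=dict)
    n_animals_before: int = 0
    n_animals_after: int = 0
    n_markers_before: int = 0
    n_markers_after: int = 0
    notes: list = field(default_factory=list)

    def counts_by_rule(self) -> pd.Series:
        return self.exclusions.groupby("rule").size()

    def append(self, other: "QcReport") -> "QcReport":
        merged = QcReport(
            exclusions=pd.concat(
                [df for df in (self.exclusions, other.exclusions) if len(df)],
                ignore_index=True) if (len(self.exclusions) or len(other.exclusions))
            else self.exclusions,
            thresholds={**self.thresholds, **other.thresholds},
            n_animals_before=self.n_animals_before,
            n_animals_after=other.n_animals_after or self.n_animals_after,
            n_markers_before=self.n_markers_before or other.n_markers_before,
            n_markers_after=other.n_markers_after,
            notes=self.notes + other.notes,
        )
        return merged

    def to_tsv(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided HWE p-value conditional on the allele counts.

    Sums the conditional probabilities of all heterozygote counts (same
    parity as observed, fixed allele counts) that are no more probable than
    the observed one; no mid-p correction.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # all heterozygote counts compatible with the allele counts (parity fixed)
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het | allele counts) up to a shared constant
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (no continuity correction)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    exp = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(x2, df=1))


# ---------------------------------------------------------------------------
# sample filters
# ---------------------------------------------------------------------------

def pairwise_ibs(g: GenotypeMatrix) -> np.ndarray:
    """Mean identity by state over shared non-missing markers.

    IBS between animals i, j = mean over shared markers of
    1 - |d_i - d_j| / 2.  NaN where two animals share no marker.
    """
    X = g.dosages
    obs = ~np.isnan(X)
    shared = obs.astype(float) @ obs.astype(float).T
    # |d_i - d_j| decomposed over genotype-indicator products
    ind = [(X == v) & obs for v in (0.0, 1.0, 2.0)]
    diff = np.zeros_like(shared)
    for a in range(3):
        for b in range(3):
            if a != b:
                fa = ind[a].astype(float)
                fb = ind[b].astype(float)
                diff += abs(a - b) * (fa @ fb.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - diff / (2.0 * shared)
    ibs[shared == 0] = np.nan
    return ibs


def sample_filters(g: GenotypeMatrix, max_missing: float = 0.05,
                   ibs_max: float = 0.95) -> tuple[GenotypeMatrix, QcReport]:
    """Drop animals with high missingness, then one of each near-duplicate pair."""
    if not (0 <= max_missing <= 1 and 0 <= ibs_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if g.n_animals == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(thresholds={"sample_max_missing": max_missing,
                                  "ibs_max": ibs_max},
                      n_animals_before=g.n_animals,
                      n_markers_before=g.n_markers)
    rows = []
    miss = g.sample_missing_rate()
    drop = miss > max_missing
    for i in np.flatnonzero(drop):
        rows.append({"id": g.animal_ids[i], "kind": "animal", "rule": "call_rate",
                     "statistic": miss[i], "threshold": max_missing})
    kept = [a for a, d in zip(g.animal_ids, drop) if not d]
    g2 = g.take_animals(kept)

    ibs = pairwise_ibs(g2)
    miss2 = g2.sample_missing_rate()
    iu, ju = np.triu_indices(g2.n_animals, k=1)
    flagged = [(i, j) for i, j in zip(iu, ju)
               if np.isfinite(ibs[i, j]) and ibs[i, j] >= ibs_max]
    removed: set = set()
    for i, j in flagged:
        if i in removed or j in removed:
            continue
        if miss2[i] != miss2[j]:
            victim = i if miss2[i] > miss2[j] else j
        else:  # tie: remove the lexicographically larger id
            victim = i if g2.animal_ids[i] > g2.animal_ids[j] else j
        keeper = j if victim == i else i
        removed.add(victim)
        rows.append({"id": g2.animal_ids[victim], "kind": "animal", "rule": "ibs",
                     "statistic": ibs[i, j], "threshold": ibs_max})
        report.notes.append(
            f"IBS pair ({g2.animal_ids[i]}, {g2.animal_ids[j]}) = {ibs[i, j]:.4f}; "
            f"removed {g2.animal_ids[victim]}, kept {g2.animal_ids[keeper]}"
        )
    kept2 = [a for k, a in enumerate(g2.animal_ids) if k not in removed]
    out = g2.take_animals(kept2)
    report.exclusions = pd.DataFrame(rows, columns=report.exclusions.columns)
    report.n_animals_after = out.n_animals
    report.n_markers_after = out.n_markers
    return out, report


# ---------------------------------------------------------------------------
# marker filters
# ---------------------------------------------------------------------------

def marker_filters(g: GenotypeMatrix, max_missing: float = 0.05,
                   min_maf: float = 0.05, hwe_alpha: float = 1e-5,
                   hwe_test: str = "exact") -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers by call rate, then MAF (inclusive), then HWE."""
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 0.5 and 0 <= hwe_alpha <= 1):
        raise ValueError("invalid marker-filter thresholds")
    if g.n_animals == 0 or g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    hwe_fn = {"exact": hwe_exact_p, "chisq": hwe_chisq_p}[hwe_test]
    report = QcReport(thresholds={"marker_max_missing": max_missing,
                                  "min_maf": min_maf, "hwe_alpha": hwe_alpha,
                                  "hwe_test": hwe_test},
                      n_animals_before=g.n_animals,
                      n_markers_before=g.n_markers)
    rows = []
    marker_ids = g.marker_ids

    miss = g.marker_missing_rate()
    fail_cr = miss > max_missing
    for j in np.flatnonzero(fail_cr):
        rows.append({"id": marker_ids[j], "kind": "marker", "rule": "call_rate",
                     "statistic": miss[j], "threshold": max_missing})
    keep = ~fail_cr

    maf = g.maf()
    fail_maf = keep & (np.nan_to_num(maf) <= min_maf)
    for j in np.flatnonzero(fail_maf):
        rows.append({"id": marker_ids[j], "kind": "marker", "rule": "maf",
                     "statistic": np.nan_to_num(maf[j]), "threshold": min_maf})
    keep &= ~fail_maf

    counts = g.genotype_counts()
    for j in np.flatnonzero(keep):
        p = hwe_fn(counts[j, 0], counts[j, 1], counts[j, 2])
        if np.isfinite(p) and p < hwe_alpha:
            rows.append({"id": marker_ids[j], "kind": "marker", "rule": "hwe",
                         "statistic": p, "threshold": hwe_alpha})
            keep[j] = False

    out = g.take_markers(keep)
    report.exclusions = pd.DataFrame(rows, columns=report.exclusions.columns)
    report.n_animals_after = out.n_animals
    report.n_markers_after = out.n_markers
    return out, report


def run_qc(g: GenotypeMatrix, sample_max_missing: float = 0.05,
           ibs_max: float = 0.95, marker_max_missing: float = 0.05,
           min_maf: float = 0.05, hwe_alpha: float = 1e-5,
           hwe_test: str = "exact") -> tuple[GenotypeMatrix, QcReport]:
    """Sample filters followed by marker filters; combined report."""
    g1, rep1 = sample_filters(g, sample_max_missing, ibs_max)
    g2, rep2 = marker_filters(g1, marker_max_missing, min_maf, hwe_alpha, hwe_test)
    return g2, rep1.append(rep2)
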