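"""SNP-to-gene mapping within a flanking window and Fisher enrichment.

Genes arrive as BED intervals (0-based, half-open); marker bp positions are
1-based (map convention) and converted internally.  A SNP maps to every
gene whose interval, extended by the flank (default 20 kb, covering
promoter regions), contains its position — many-to-many by design.
Gene-set enrichment is the two-sided Fisher exact test on the 2x2 table of
query membership vs set membership over a background gene universe, with
Bonferroni correction over the sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GeneticMap

__all__ = ["GeneAnnotation", "read_bed", "read_gmt", "map_snps_to_genes",
           "fisher_enrichment"]

DEFAULT_FLANK_BP = 20_000


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, with normalized chromosome names."""

    table: pd.DataFrame  # chrom, start, end, gene, (strand)

    def __post_init__(self):
        req = {"chrom", "start", "end", "gene"}
        if not req <= set(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(req)}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].map(normalize_chrom)
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if (t["start"] < 0).any():
            raise ValueError("negative gene coordinates")
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]]["gene"].iloc[0]
            raise ValueError(f"gene {bad}: start must be < end")
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()


def normalize_chrom(c) -> str:
    s = str(c).strip()
    low = s.lower()
    for prefix in ("chromosome", "chrom", "chr"):
        if low.startswith(prefix):
            s = s[len(prefix):]
            break
    return s.lstrip("_").lstrip() or s


def read_bed(path) -> GeneAnnotation:
    """Read a BED file of genes: chrom, start, end, name[, score, strand]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            row = {"chrom": parts[0], "start": start, "end": end, "gene": parts[3]}
            if len(parts) >= 6:
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no gene intervals found")
    return GeneAnnotation(pd.DataFrame(rows))


def read_gmt(path) -> dict:
    """Read gene sets from GMT: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def map_snps_to_genes(markers: pd.DataFrame | GeneticMap,
                      annotation: GeneAnnotation,
                      flank_bp: int = DEFAULT_FLANK_BP) -> pd.DataFrame:
    """Assign each SNP to all genes within the flanked gene interval.

    ``markers`` needs columns marker, chrom, bp (1-based).  A SNP at 1-based
    position b (0-based b-1) maps to a gene [start, end) iff
    start - flank <= b - 1 < end + flank.  Distance is 0 inside the gene
    body, else the gap to the nearest gene edge.  Unmapped SNPs appear with
    gene NA so the unannotated list is preserved.
    """
    if isinstance(markers, GeneticMap):
        markers = markers.to_frame()
    need = {"marker", "chrom", "bp"}
    if not need <= set(markers.columns):
        raise ValueError(f"marker table needs columns {sorted(need)}")
    mk = markers.copy()
    mk["chrom"] = mk["chrom"].map(normalize_chrom)
    rows = []
    ann = annotation.table
    for chrom, sub in mk.groupby("chrom", sort=False):
        genes = ann[ann["chrom"] == chrom]
        pos0 = sub["bp"].to_numpy(dtype=np.int64) - 1  # to 0-based
        if len(genes) == 0:
            for m in sub["marker"]:
                rows.append({"marker": m, "chrom": chrom, "gene": pd.NA,
                             "distance": pd.NA})
            continue
        start = genes["start"].to_numpy() - flank_bp
        end = genes["end"].to_numpy() + flank_bp
        hit = (pos0[:, None] >= start[None, :]) & (pos0[:, None] < end[None, :])
        for i, m in enumerate(sub["marker"]):
            js = np.flatnonzero(hit[i])
            if len(js) == 0:
                rows.append({"marker": m, "chrom": chrom, "gene": pd.NA,
                             "distance": pd.NA})
                continue
            for j in js:
                g0, g1 = genes["start"].iat[j], genes["end"].iat[j]
                if g0 <= pos0[i] < g1:
                    dist = 0
                else:
                    dist = int(min(abs(pos0[i] - g0), abs(pos0[i] - (g1 - 1))))
                rows.append({"marker": m, "chrom": chrom,
                             "gene": genes["gene"].iat[j], "distance": dist})
    return pd.DataFrame(rows, columns=["marker", "chrom", "gene", "distance"])


def fisher_enrichment(query_genes, gene_sets: dict, background_genes) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of gene sets in a query list.

    The query must be a subset of the background; each set is intersected
    with the background before testing.  Bonferroni-adjusted p-values
    multiply by the number of sets actually tested (sets empty after
    intersection are skipped).
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene universe")
    query = set(query_genes)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background: {extra}")
    rows = []
    for name in gene_sets:
        members = set(gene_sets[name]) & background
        if not members:
            continue
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(background) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"gene_set": name, "overlap": a, "set_size": len(members),
                     "query_size": len(query), "background_size": len(background),
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                      "query_size", "background_size",
                                      "odds_ratio", "p"])
    n_tested = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * n_tested)
    return out.sort_values(["p_bonferroni", "p", "gene_set"],
                           kind="mergesort").reset_index(drop=True)
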