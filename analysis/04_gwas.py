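"""Genome-wide association of the Obesity Index.

Per-marker OLS of OI on allele dosage with Bonferroni control
(suggestive = 0.05/M, highly significant = 0.001/M).  Prints the threshold
values, hit counts, and how many hits fall inside the planted QTL block.
"""

import argparse
import pathlib

import pandas as pd

from wishnet import io
from wishnet.gwas import scan, significant_markers

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(qcdir=None, indexdir=None, simdir=None, outdir=None):
    qcd = pathlib.Path(qcdir) if qcdir else ROOT / "results" / "qc"
    idd = pathlib.Path(indexdir) if indexdir else ROOT / "results" / "index"
    smd = pathlib.Path(simdir) if simdir else ROOT / "results" / "sim"
    out = pathlib.Path(outdir) if outdir else ROOT / "results" / "gwas"
    out.mkdir(parents=True, exist_ok=True)

    g = io.read_genotypes(qcd / "genotypes_qc.tsv", "dosage_tsv",
                          qcd / "markers_qc.map")
    oi = io.read_oi(idd / "oi.tsv")
    res = scan(oi, g)
    res.manhattan_frame().to_csv(out / "gwas.tsv", sep="\t", index=False,
                                 float_format="%.6e")

    sugg = significant_markers(res, "suggestive")
    high = significant_markers(res, "high")
    print(f"scanned {res.n_markers} markers on {res.settings['n_animals']} "
          f"animals")
    print(f"  suggestive threshold 0.05/M  = {res.threshold('suggestive'):.3e}"
          f" -> {len(sugg)} markers")
    print(f"  high threshold     0.001/M  = {res.threshold('high'):.3e}"
          f" -> {len(high)} markers")
    causal = pd.read_csv(smd / "causal_markers.tsv", sep="\t")
    planted = set(causal[causal["cluster"] == "oi_qtl"]["marker"])
    n_in = len(planted & set(high["marker"]))
    print(f"  planted oi_qtl block: {n_in}/{len(planted)} markers among the "
          f"highly significant hits")
    top = high.head(3)[["marker", "chrom", "bp", "effect", "p"]]
    print("  top hits:")
    print(top.to_string(index=False))
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--qc", default=None)
    ap.add_argument("--index", default=None)
    ap.add_argument("--sim", default=None)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    main(args.qc, args.index, args.sim, args.out)
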