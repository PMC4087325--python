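"""Differential wiring of SNPs between lean and obese extremes.

Takes the 50 leanest and 50 most obese animals by OI, computes each SNP's
max-normalized connectivity within each subgroup over the full post-QC
marker set, and flags |k_diff| > 0.6.  Prints how many SNPs rewire and
whether the planted rare-haplotype cluster is among them.
"""

import argparse
import pathlib

import pandas as pd

from wishnet import io
from wishnet.dwire import run_dwire
from wishnet.index import select_extremes

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(qcdir=None, indexdir=None, simdir=None, outdir=None, n_extreme=50,
         threshold=0.6):
    qcd = pathlib.Path(qcdir) if qcdir else ROOT / "results" / "qc"
    idd = pathlib.Path(indexdir) if indexdir else ROOT / "results" / "index"
    smd = pathlib.Path(simdir) if simdir else ROOT / "results" / "sim"
    out = pathlib.Path(outdir) if outdir else ROOT / "results" / "dwire"
    out.mkdir(parents=True, exist_ok=True)

    g = io.read_genotypes(qcd / "genotypes_qc.tsv", "dosage_tsv",
                          qcd / "markers_qc.map")
    oi = io.read_oi(idd / "oi.tsv")
    grp = select_extremes(oi, {"lean": n_extreme, "obese": n_extreme})
    dw = run_dwire(g, grp["lean"], grp["obese"], threshold)
    dw.table.to_csv(out / "dwire.tsv", sep="\t", index=False,
                    float_format="%.6g")

    selected = dw.selected()
    print(f"connectivity over {len(dw.table)} SNPs in {dw.n_lean} lean vs "
          f"{dw.n_obese} obese animals")
    print(f"  {len(selected)} SNPs with |k_diff| > {threshold} "
          f"({(selected['k_diff'] > 0).sum()} lean hubs, "
          f"{(selected['k_diff'] < 0).sum()} obese hubs)")
    causal = pd.read_csv(smd / "causal_markers.tsv", sep="\t")
    planted = set(causal[causal["cluster"] == "dw_qtl"]["marker"])
    n_planted = len(planted & set(selected["marker"]))
    print(f"  planted dw_qtl cluster: {n_planted}/{len(planted)} markers "
          f"selected (expected obese hubs, k_diff < 0)")
    if len(selected):
        ext = selected.reindex(selected["k_diff"].abs()
                               .sort_values(ascending=False).index)
        print("  strongest rewiring:")
        print(ext.head(5)[["marker", "k_lean", "k_obese", "k_diff"]]
              .to_string(index=False))
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--qc", default=None)
    ap.add_argument("--index", default=None)
    ap.add_argument("--sim", default=None)
    ap.add_argument("--out", default=None)
    ap.add_argument("--n-extreme", type=int, default=50)
    ap.add_argument("--threshold", type=float, default=0.6)
    args = ap.parse_args()
    main(args.qc, args.index, args.sim, args.out, args.n_extreme,
         args.threshold)
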