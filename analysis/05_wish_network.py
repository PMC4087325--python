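"""WISH co-association network and module-trait associations.

Selects SNPs (scan p < 0.05, then top connectivity) over 75 index-extreme
animals (25 low / 25 intermediate / 25 high OI), builds the |r|^gamma
adjacency (gamma = 5) and TOM, cuts modules of >= 50 SNPs, summarizes each
by its eigenSNP, and correlates eigenSNPs with the OI and the non-index
trait EBVs (the GMAT).  Prints the modules, their variance explained and
their strongest trait relations.
"""

import argparse
import pathlib

from wishnet import io
from wishnet.gwas import scan
from wishnet.index import select_extremes
from wishnet.wish import (adjacency, detect_modules, eigensnp, gmat,
                          preselect_snps, scale_free_fit, select_modules, tom)
from wishnet.simdata import INDEX_TRAITS

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(qcdir=None, indexdir=None, outdir=None, gamma=5, fit_gamma=False):
    qcd = pathlib.Path(qcdir) if qcdir else ROOT / "results" / "qc"
    idd = pathlib.Path(indexdir) if indexdir else ROOT / "results" / "index"
    out = pathlib.Path(outdir) if outdir else ROOT / "results" / "wish"
    out.mkdir(parents=True, exist_ok=True)

    g = io.read_genotypes(qcd / "genotypes_qc.tsv", "dosage_tsv",
                          qcd / "markers_qc.map")
    oi = io.read_oi(idd / "oi.tsv")
    traits = io.read_traits(ROOT / "results" / "sim" / "traits.tsv")

    res = scan(oi, g)
    groups = select_extremes(oi, {"low": 25, "mid": 25, "high": 25})
    animals = [a for grp in groups.values() for a in grp]
    net_g, meta = preselect_snps(res, g, animals)
    print(f"SNP selection: {meta['n_input']} -> {meta['n_p_selected']} at "
          f"p < {meta['p_max']} -> {meta['n_selected']} after connectivity "
          f"ranking")

    if fit_gamma:
        sf, fitted = scale_free_fit(net_g)
        sf.to_csv(out / "scale_free_fit.tsv", sep="\t", index=False,
                  float_format="%.6g")
        if fitted is not None:
            gamma = fitted
        print(f"scale-free fit chose gamma = {gamma}")

    t = tom(adjacency(net_g, gamma))
    modules = detect_modules(1.0 - t, net_g.marker_ids, min_size=50)
    modules.assignment_frame().to_csv(out / "modules.tsv", sep="\t",
                                      index=False)
    print(f"{len(modules.module_labels)} modules of >= 50 SNPs "
          f"(sizes {modules.sizes()}); {int((modules.labels == 0).sum())} "
          f"SNPs unassigned")

    if modules.module_labels:
        modules = eigensnp(net_g, modules)
        modules.eigensnps.to_csv(out / "eigensnps.tsv", sep="\t",
                                 float_format="%.6g")
        tdf = traits.set_index("animal_id")
        other = [c for c in tdf.columns
                 if c.endswith("_ebv") and c[:-4] not in INDEX_TRAITS]
        tdf = tdf[other].copy()
        tdf.insert(0, "OI", oi)
        gm = gmat(modules.eigensnps, tdf)
        gm.to_frame().to_csv(out / "gmat.tsv", sep="\t", float_format="%.6e")
        chosen = select_modules(gm)
        for mod in gm.mtr.index:
            ve = modules.var_explained[mod]
            mtr_oi = gm.mtr.loc[mod, "OI"]
            p_oi = gm.p.loc[mod, "OI"]
            best_other = gm.mtr.loc[mod].drop("OI").abs().idxmax()
            print(f"  {mod}: var explained {ve:.2f}, MTR_OI {mtr_oi:+.2f} "
                  f"(p {p_oi:.2e}), strongest other trait {best_other} "
                  f"({gm.mtr.loc[mod, best_other]:+.2f})")
        print(f"modules passing the selection rule "
              f"(p_OI < 0.001 and |MTR| > 0.4 with another trait): {chosen}")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--qc", default=None)
    ap.add_argument("--index", default=None)
    ap.add_argument("--out", default=None)
    ap.add_argument("--gamma", type=int, default=5)
    ap.add_argument("--fit-gamma", action="store_true")
    args = ap.parse_args()
    main(args.qc, args.index, args.out, args.gamma, args.fit_gamma)
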